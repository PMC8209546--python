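import numpy as np
import pandas as pd
import pytest

from itf import methylation as me
from itf.synthetic import MethylSpec, generate_methylation_dataset


class TestDmProportion:
    def test_basic(self):
        assert me.dm_proportion(35, 1000) == 3.5

    def test_invalid(self):
        with pytest.raises(ValueError):
            me.dm_proportion(1, 0)


class TestQuantileNormalize:
    def test_shifted_columns(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = me.quantile_normalize(df)
        assert out["s1"].tolist() == [2.5, 3.5, 4.5]
        assert out["s2"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_multisets_unchanged(self):
        df = pd.DataFrame({"s1": [0.1, 0.5, 0.9], "s2": [0.9, 0.1, 0.5]})
        out = me.quantile_normalize(df)
        assert out.to_numpy() == pytest.approx(df.to_numpy())

    def test_constant_matrix_unchanged(self):
        df = pd.DataFrame(np.full((4, 3), 0.3), columns=list("abc"))
        out = me.quantile_normalize(df)
        assert out.to_numpy() == pytest.approx(0.3)

    def test_non_numeric_rejected(self):
        df = pd.DataFrame({"s1": [0.1, np.nan], "s2": [0.2, 0.3]})
        with pytest.raises(me.SchemaError):
            me.quantile_normalize(df)


class TestFilterProbes:
    def _toy(self):
        idx = [f"cg{i}" for i in range(5)]
        beta = pd.DataFrame(np.full((5, 3), 0.5), index=idx, columns=["A1", "A2", "B1"])
        detp = pd.DataFrame(np.full((5, 3), 0.001), index=idx, columns=beta.columns)
        detp.loc["cg2", "B1"] = 0.02
        annot = pd.DataFrame(
            {
                "cpg_id": idx,
                "cpg_context": ["island"] * 5,
                "gene_region": ["body"] * 5,
                "gene_symbol": [""] * 5,
                "snp_flag": [True, False, False, False, False],
            }
        )
        return beta, detp, annot

    def test_manual_enumeration(self):
        beta, detp, annot = self._toy()
        out = me.filter_probes(beta, detp, annot)
        assert set(out.index) == {"cg1", "cg3", "cg4"}

    def test_pmax_one_no_snp_identity(self):
        beta, detp, annot = self._toy()
        annot["snp_flag"] = False
        out = me.filter_probes(beta, detp, annot, p_max=1.0)
        assert out.equals(beta)

    def test_missing_annotation_raises(self):
        beta, detp, annot = self._toy()
        with pytest.raises(me.SchemaError):
            me.filter_probes(beta, detp, annot.iloc[:3])

    def test_expected_retention_over_seeds(self):
        rates = []
        for seed in range(5):
            spec = MethylSpec(n_cpgs=2000, snp_fraction=0.05, detp_fail_fraction=0.003, seed=seed)
            beta, detp, annot, _ = generate_methylation_dataset(spec)
            kept = me.filter_probes(beta, detp, annot)
            rates.append(len(kept) / len(beta))
        expected = (1 - 0.05) * (1 - 0.003) ** 20
        assert np.mean(rates) == pytest.approx(expected, abs=0.02)


class TestDmcpgTest:
    def test_exact_separation_p(self):
        beta = pd.DataFrame(
            [[0.1, 0.15, 0.2, 0.8, 0.85, 0.9]],
            index=["cg1"],
            columns=["A1", "A2", "A3", "B1", "B2", "B3"],
        )
        groups = pd.Series({c: c[0] for c in beta.columns})
        dm = me.dmcpg_test(beta, groups)
        assert dm.loc[0, "wilcoxon_p"] == pytest.approx(0.1, abs=1e-12)
        assert dm.loc[0, "delta_beta"] == pytest.approx(0.15 - 0.85)

    def test_constant_row_p_one(self):
        beta = pd.DataFrame(
            [[0.5] * 6, [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]],
            index=["cg1", "cg2"],
            columns=["A1", "A2", "A3", "B1", "B2", "B3"],
        )
        groups = pd.Series({c: c[0] for c in beta.columns})
        dm = me.dmcpg_test(beta, groups)
        assert dm.loc[0, "wilcoxon_p"] == 1.0

    def test_significant_iff_q_below_fdr(self, methyl_dataset, methyl_groups):
        beta = methyl_dataset[0]
        dm = me.dmcpg_test(beta.iloc[:300], methyl_groups)
        assert (dm["significant"] == (dm["fdr_q"] < 0.05)).all()
        assert dm["delta_beta"].between(-1, 1).all()

    def test_bad_grouping(self):
        beta = pd.DataFrame(np.random.default_rng(0).random((3, 4)),
                            columns=["A1", "A2", "A3", "A4"])
        with pytest.raises(me.InvalidGroupingError):
            me.dmcpg_test(beta, pd.Series({c: "A" for c in beta.columns}))

    def test_null_fdr_control(self):
        rng = np.random.default_rng(11)
        beta = pd.DataFrame(
            rng.random((2000, 12)),
            index=[f"cg{i}" for i in range(2000)],
            columns=[f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)],
        )
        groups = pd.Series({c: c[0] for c in beta.columns})
        dm = me.dmcpg_test(beta, groups)
        assert dm["significant"].mean() <= 0.05


class TestRecovery:
    def test_sensitivity_and_fdr_against_truth(self, methyl_dataset, methyl_groups):
        beta, detp, annot, truth = methyl_dataset
        filtered = me.filter_probes(beta, detp, annot)
        dm = me.dmcpg_test(filtered, methyl_groups)
        called = set(dm.loc[dm["significant"], "cpg_id"])
        planted = set(truth.cpg_ids) & set(filtered.index)
        sens = len(called & planted) / len(planted)
        fdr_obs = len(called - planted) / max(len(called), 1)
        assert sens >= 0.9
        assert fdr_obs <= 0.1


class TestGenomicDistribution:
    def test_total_matches_significant(self, methyl_dataset, methyl_groups):
        beta, detp, annot, _ = methyl_dataset
        dm = me.dmcpg_test(me.filter_probes(beta, detp, annot), methyl_groups)
        dist = me.genomic_distribution(dm, annot)
        assert dist["count"].sum() == dm["significant"].sum()
        assert dist["pct_of_total"].sum() == pytest.approx(100.0)

    def test_all_island_share(self):
        dm = pd.DataFrame(
            {"cpg_id": ["cg1", "cg2"], "significant": [True, True]}
        )
        annot = pd.DataFrame(
            {
                "cpg_id": ["cg1", "cg2"],
                "cpg_context": ["island", "island"],
                "gene_region": ["body", "TSS200"],
                "gene_symbol": ["G1", "G2"],
                "snp_flag": [False, False],
            }
        )
        dist = me.genomic_distribution(dm, annot)
        assert (dist.loc[dist["count"] > 0, "cpg_context"] == "island").all()

    def test_context_proportions_recovered(self):
        spec = MethylSpec(n_cpgs=4000, dm_fraction=0.0, n_signature_genes=0, seed=3)
        _, _, annot, _ = generate_methylation_dataset(spec)
        props = annot["cpg_context"].value_counts(normalize=True)
        for ctx, p in {"island": 0.30, "shore": 0.25, "shelf": 0.10, "open_sea": 0.35}.items():
            se = np.sqrt(p * (1 - p) / 4000)
            assert abs(props[ctx] - p) < 4 * se


class TestPromoterSignature:
    def test_empty_when_nothing_significant(self, methyl_dataset):
        _, _, annot, _ = methyl_dataset
        dm = pd.DataFrame({"cpg_id": annot["cpg_id"], "significant": False})
        cpgs, gene_map = me.promoter_cgi_signature(dm, annot)
        assert cpgs == []
        assert gene_map == {}

    def test_gene_count_from_map(self):
        annot = pd.DataFrame(
            {
                "cpg_id": ["cg1", "cg2", "cg3"],
                "cpg_context": ["island"] * 3,
                "gene_region": ["TSS200", "TSS1500", "TSS200"],
                "gene_symbol": ["G1", "G1", "G2"],
                "snp_flag": [False] * 3,
            }
        )
        dm = pd.DataFrame({"cpg_id": annot["cpg_id"], "significant": True})
        cpgs, gene_map = me.promoter_cgi_signature(dm, annot)
        assert len(cpgs) == 3
        assert len(set(gene_map.values())) == 2

    def test_signature_subset_of_significant(self, methyl_dataset, methyl_groups):
        beta, detp, annot, _ = methyl_dataset
        dm = me.dmcpg_test(me.filter_probes(beta, detp, annot), methyl_groups)
        cpgs, _ = me.promoter_cgi_signature(dm, annot)
        sig_set = set(dm.loc[dm["significant"], "cpg_id"])
        assert set(cpgs) <= sig_set


class TestClustering:
    def test_planted_shift_recovers_labels(self, methyl_dataset, methyl_groups):
        beta, detp, annot, truth = methyl_dataset
        filtered = me.filter_probes(beta, detp, annot)
        dm = me.dmcpg_test(filtered, methyl_groups)
        cpgs, _ = me.promoter_cgi_signature(dm, annot)
        _, _, labels = me.cluster_samples(filtered, cpgs)
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(methyl_groups.loc[filtered.columns], labels)
        assert ari == 1.0

    def test_dendrogram_merge_count(self, methyl_dataset):
        beta = methyl_dataset[0]
        _, z, _ = me.cluster_samples(beta, list(beta.index[:50]))
        assert z.shape[0] == beta.shape[1] - 1

    def test_too_few_cpgs(self, methyl_dataset):
        beta = methyl_dataset[0]
        with pytest.raises(me.InsufficientSignatureError):
            me.cluster_samples(beta, [beta.index[0]])


class TestConcordance:
    def test_r2_tends_to_one_with_low_noise(self):
        spec = MethylSpec(n_cpgs=1000, dm_fraction=0.0, precision=5000.0,
                          n_signature_genes=0, seed=2)
        beta, _, _, _ = generate_methylation_dataset(spec)
        groups = pd.Series({c: c[0] for c in beta.columns})
        assert me.group_mean_concordance(beta, groups) > 0.99

    def test_r2_high_on_default_dataset(self, methyl_dataset, methyl_groups):
        beta = methyl_dataset[0]
        r2 = me.group_mean_concordance(beta, methyl_groups)
        assert 0.9 < r2 < 1.0
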