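import numpy as np
import pandas as pd
import pytest

from itf.synthetic import (
    CellFieldSpec,
    FiberImageSpec,
    MethylSpec,
    generate_fiber_image,
    generate_methylation_dataset,
)


@pytest.fixture(scope="session")
def small_fiber_spec():
    return FiberImageSpec(width_px=400, height_px=400, n_fibers=12, seed=11)


@pytest.fixture(scope="session")
def small_fiber_image(small_fiber_spec):
    return generate_fiber_image(small_fiber_spec)


@pytest.fixture(scope="session")
def methyl_dataset():
    return generate_methylation_dataset(MethylSpec(seed=7))


@pytest.fixture(scope="session")
def methyl_groups(methyl_dataset):
    beta = methyl_dataset[0]
    return pd.Series({c: ("A" if c.startswith("A") else "B") for c in beta.columns})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cell_spec(**kw):
    """Spec with zero densities except the given category/phenotype pairs."""
    densities = {
        cat: {p: 0.0 for p in ("CD68", "CD3", "CD8", "CD20", "CK", "other")}
        for cat in ("tumor", "myometrium", "itf")
    }
    for (cat, ph), d in kw.pop("set_densities", {}).items():
        densities[cat][ph] = d
    return CellFieldSpec(densities=densities, **kw)
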