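"""Pipeline configuration: nested defaults, schema validation, YAML I/O.

Every stage parameter has a default; unknown keys are rejected so typos
fail loudly.  The seed is mandatory in user configs -- there is no silent
nondeterminism.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "itf_run",
    "simulate": {
        "fibers": {
            "n_images": 3,
            "width_px": 512,
            "height_px": 512,
            "resolution": 0.46,
            "n_fibers": 20,
            "mean_fiber_width": 5.0,
            "noise_sd": 8.0,
            "hole_fraction": 0.0,
        },
        "cells": {
            "roi_size_mm": [1.0, 1.0],
            "clustering": 0.0,
        },
        "methyl": {
            "n_cpgs": 2000,
            "n_samples_a": 10,
            "n_samples_b": 10,
            "dm_fraction": 0.035,
            "delta_beta": 0.2,
        },
        "expression": {
            "n_genes": 1392,
            "n_samples_a": 10,
            "n_samples_b": 10,
            "log2fc": 2.0,
            "n_coupled_hyper_down": 9,
            "n_coupled_hypo_up": 11,
        },
    },
    "segment": {
        "threshold": 0.5,
        "min_area_um2": 10.0,
        "n_iter": 2,
        "n_sample": 50000,
    },
    "morphometry": {
        "od_min": 0.08,
    },
    "compare": {
        "alpha_var": 0.05,
        "bh_correct": False,
    },
    "immune": {
        "margin_um": 20.0,
    },
    "methyl": {
        "p_max": 0.01,
        "fdr": 0.05,
        "quantile_normalize": False,
    },
    "integrate": {
        "q_max": 0.05,
        "min_delta": 0.05,
    },
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config (and/or overrides) over the defaults."""
    user: dict = {}
    if path is not None:
        with open(Path(path)) as fh:
            user = yaml.safe_load(fh) or {}
        if "seed" not in user:
            raise ConfigError("config missing required key: seed")
    cfg = _merge(DEFAULTS, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)
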