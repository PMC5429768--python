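"""Shared fixtures: a calibrated exemplar population and class renderers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from golgiq import (
    calibrate_gate_config,
    compute_feature_table,
    get_preset,
    sample_population,
)
from golgiq.synthcells import (
    GolgiClass,
    NucleusClass,
    PopulationPreset,
    _NUC_CYCLING,
    _product_mixture,
)

EXEMPLAR_SEED = 2


@pytest.fixture(scope="session")
def exemplars():
    """300 balanced labeled exemplar cells (the gate-calibration sample)."""
    return sample_population(get_preset("exemplars"), 300, EXEMPLAR_SEED)


@pytest.fixture(scope="session")
def exemplar_table(exemplars):
    cells, _ = exemplars
    return compute_feature_table(cells)


@pytest.fixture(scope="session")
def gate_config(exemplars, exemplar_table):
    """GateConfig calibrated on the exemplar population."""
    _, truth = exemplars
    return calibrate_gate_config(exemplar_table, truth)


def class_preset(
    golgi: str = "intact",
    nucleus: str | None = None,
    doublet_rate: float = 0.0,
    out_of_focus_rate: float = 0.0,
) -> PopulationPreset:
    """Single-class population preset for targeted per-class tests."""
    if nucleus is None:
        nuc_mix = _NUC_CYCLING
    else:
        nuc_mix = {NucleusClass(nucleus): 1.0}
    return PopulationPreset(
        "testpop",
        _product_mixture({GolgiClass(golgi): 1.0}, nuc_mix),
        doublet_rate=doublet_rate,
        out_of_focus_rate=out_of_focus_rate,
    )


def render_class_population(n: int, seed: int, **kwargs):
    """(cells, truth) for a single-class population."""
    return sample_population(class_preset(**kwargs), n, seed)
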