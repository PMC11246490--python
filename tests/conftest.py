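"""Shared fixtures: small synthetic screens and gate sets."""

import numpy as np
import pandas as pd
import pytest

from cytostitch import ExpressionTable, PanelDesign
from cytostitch.synth import (
    MarkerModel,
    SynthConfig,
    simulate_screen,
    well_separated_screen_config,
)


@pytest.fixture(scope="session")
def small_design() -> PanelDesign:
    return PanelDesign(
        conserved_markers=["c0", "c1", "c2"],
        panels={"pA": ["sA0", "sA1"], "pB": ["sB0", "sB1"]},
    )


def three_pop_config(n_cells: int = 6000, seed: int = 1) -> SynthConfig:
    """Three populations separated by >= 6 component-SDs on 3 conserved markers."""
    design = PanelDesign(
        conserved_markers=["c0", "c1", "c2"],
        panels={"pA": ["sA0"], "pB": ["sB0"]},
    )
    models = {}
    for i, pop in enumerate(["P0", "P1", "P2"]):
        per = {}
        for j, m in enumerate(design.conserved_markers):
            # population i is positive on conserved marker i only
            per[m] = MarkerModel(
                positive_fraction=1.0 if i == j else 0.0,
                pos_mean=6.0,
                pos_sd=0.5,
                neg_mean=0.5,
                neg_sd=0.5,
            )
        for m in ["sA0", "sB0"]:
            per[m] = MarkerModel(0.3, pos_mean=3.0, pos_sd=0.5, neg_mean=0.3, neg_sd=0.2)
        models[pop] = per
    return SynthConfig(
        n_populations=3,
        population_proportions=[0.4, 0.35, 0.25],
        n_cells=n_cells,
        n_donors=2,
        panel_design=design,
        marker_models=models,
        donor_shift_sd=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def three_pop_screen():
    return simulate_screen(three_pop_config())


@pytest.fixture(scope="session")
def medium_screen():
    """A 4-panel, 4-population well-separated screen for integration tests."""
    cfg = well_separated_screen_config(
        n_populations=4,
        n_cells=8000,
        n_panels=4,
        n_conserved=9,
        screen_per_panel=3,
        n_donors=2,
        seed=3,
    )
    return cfg, *simulate_screen(cfg)


def single_marker_table(values, marker: str = "m0") -> ExpressionTable:
    """One conserved marker, one panel — scaffolding for transform tests."""
    design = PanelDesign(conserved_markers=[marker], panels={"p0": []})
    n = len(values)
    df = pd.DataFrame(
        {
            "donor_id": ["d1"] * n,
            "panel_id": ["p0"] * n,
            marker: np.asarray(values, dtype=float),
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )
    return ExpressionTable(df, design)


HSPC_MARKERS = ["Lin", "CD34", "CD38", "CD90", "CD45RA", "CD10", "CD123"]


def hspc_gating_table(values: np.ndarray) -> ExpressionTable:
    """Cells x 7 conserved-marker matrix for immunophenotype gate tests."""
    design = PanelDesign(conserved_markers=HSPC_MARKERS, panels={"p0": []})
    df = pd.DataFrame(values, columns=HSPC_MARKERS)
    df.insert(0, "donor_id", "d1")
    df.insert(1, "panel_id", "p0")
    df.index = pd.Index([f"c{i}" for i in range(len(df))], name="cell_id")
    return ExpressionTable(df, design)
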