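"""Synthetic split-panel screen data with known ground truth.

The generator emulates the structure of a multi-panel mass-cytometry
screen of a progenitor compartment: several latent populations in fixed
proportions, multiple donors, and K staining panels that share a conserved
marker core while each adding disjoint screen markers.  Marker intensities
are drawn directly on the asinh scale from a two-component (negative /
positive) normal mixture whose positive fraction, means and SDs are
population-specific, with an additive per-(donor, marker) shift.  It also
simulates limiting-dilution well plates under the single-hit Poisson model
so the estimator downstream can be validated against a known frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, ExpressionTable, PanelDesign
from .lda import LDAGroup

__all__ = [
    "MarkerModel",
    "SynthConfig",
    "GroundTruth",
    "simulate_screen",
    "simulate_lda_wells",
    "well_separated_screen_config",
]


@dataclass(frozen=True)
class MarkerModel:
    """Two-component asinh-scale mixture for one (population, marker) pair.

    ``positive_fraction`` is the probability a cell of the population
    expresses the marker; positive cells draw from N(pos_mean, pos_sd),
    negative cells from N(neg_mean, neg_sd).  Draws are clipped at zero to
    mimic non-negative transformed intensities.
    """

    positive_fraction: float
    pos_mean: float
    pos_sd: float
    neg_mean: float = 0.0
    neg_sd: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigurationError(
                f"positive_fraction must be in [0,1], got {self.positive_fraction}"
            )
        if self.pos_sd <= 0 or self.neg_sd <= 0:
            raise ConfigurationError("component SDs must be > 0")


@dataclass
class SynthConfig:
    """Full specification of a synthetic screen.

    marker_models maps population -> marker -> MarkerModel and must cover
    every marker in the panel design for every population.
    """

    n_populations: int
    population_proportions: Sequence[float]
    n_cells: int
    n_donors: int
    panel_design: PanelDesign
    marker_models: Mapping[str, Mapping[str, MarkerModel]]
    donor_shift_sd: float = 0.0
    seed: int = 0
    panel_probs: Sequence[float] | None = None  # uniform when None

    def __post_init__(self) -> None:
        props = np.asarray(self.population_proportions, dtype=float)
        if len(props) != self.n_populations:
            raise ConfigurationError(
                "population_proportions length must equal n_populations"
            )
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "population_proportions must be a simplex vector (sum 1 +/- 1e-9)"
            )
        if self.n_donors < 1:
            raise ConfigurationError("n_donors must be >= 1")
        if self.donor_shift_sd < 0:
            raise ConfigurationError("donor_shift_sd must be >= 0")
        pops = self.populations
        if len(self.marker_models) != self.n_populations or set(
            self.marker_models
        ) != set(pops):
            raise ConfigurationError(
                "marker_models must have one entry per population"
            )
        for pop in pops:
            models = self.marker_models[pop]
            for marker in self.panel_design.all_markers:
                if marker not in models:
                    raise ConfigurationError(
                        f"no marker model for (population {pop!r}, marker {marker!r})"
                    )
        if self.panel_probs is not None:
            pp = np.asarray(self.panel_probs, dtype=float)
            if len(pp) != len(self.panel_design.panel_ids) or abs(
                pp.sum() - 1.0
            ) > 1e-9 or np.any(pp < 0):
                raise ConfigurationError("panel_probs must be a simplex over panels")

    @property
    def populations(self) -> list[str]:
        return sorted(self.marker_models)


@dataclass
class GroundTruth:
    """True population label per generated cell plus the generating config."""

    labels: pd.Series  # index cell_id -> population label
    config: SynthConfig

    def __post_init__(self) -> None:
        if self.labels.isna().any():
            raise ConfigurationError("every cell must carry one true label")


def simulate_screen(config: SynthConfig) -> tuple[ExpressionTable, GroundTruth]:
    """Generate a split-panel screen table and its ground truth.

    Each cell gets a population (multinomial on the configured
    proportions), a donor (uniform) and a staining panel (uniform unless
    ``panel_probs`` given).  Conserved markers are measured for every
    cell; a panel's screen markers only for its cells, all other screen
    entries are NaN (unmeasured).  Fixed seed gives bit-identical output.
    """
    if config.n_cells < config.n_populations * 10:
        raise ConfigurationError("n_cells must be >= n_populations * 10")
    rng = np.random.default_rng(config.seed)
    design = config.panel_design
    pops = np.array(config.populations)
    n = config.n_cells

    pop_idx = rng.choice(
        len(pops), size=n, p=np.asarray(config.population_proportions, dtype=float)
    )
    donor_idx = rng.integers(0, config.n_donors, size=n)
    panel_ids = np.array(design.panel_ids)
    panel_idx = rng.choice(
        len(panel_ids),
        size=n,
        p=None if config.panel_probs is None else np.asarray(config.panel_probs),
    )

    donors = np.array([f"donor{i + 1}" for i in range(config.n_donors)])
    cell_ids = pd.Index([f"cell{i:07d}" for i in range(n)], name="cell_id")

    markers = list(design.all_markers)
    # per-(donor, marker) additive shift, shared across populations
    shifts = (
        rng.normal(0.0, config.donor_shift_sd, size=(config.n_donors, len(markers)))
        if config.donor_shift_sd > 0
        else np.zeros((config.n_donors, len(markers)))
    )

    values = np.full((n, len(markers)), np.nan)
    for j, marker in enumerate(markers):
        owner = design.panel_of(marker)
        measured = (
            np.ones(n, dtype=bool)
            if owner is None
            else panel_idx == np.where(panel_ids == owner)[0][0]
        )
        idx = np.where(measured)[0]
        if idx.size == 0:
            continue
        col = np.empty(idx.size)
        for p, pop in enumerate(pops):
            model = config.marker_models[pop][marker]
            sel = pop_idx[idx] == p
            m = int(sel.sum())
            if m == 0:
                continue
            is_pos = rng.random(m) < model.positive_fraction
            draws = np.where(
                is_pos,
                rng.normal(model.pos_mean, model.pos_sd, size=m),
                rng.normal(model.neg_mean, model.neg_sd, size=m),
            )
            col[sel] = draws
        col += shifts[donor_idx[idx], j]
        values[idx, j] = np.clip(col, 0.0, None)

    data = pd.DataFrame(values, index=cell_ids, columns=markers)
    data.insert(0, "donor_id", donors[donor_idx])
    data.insert(1, "panel_id", panel_ids[panel_idx])
    table = ExpressionTable(data, design)
    truth = GroundTruth(
        labels=pd.Series(pops[pop_idx], index=cell_ids, name="population"),
        config=config,
    )
    return table, truth


def well_separated_screen_config(
    n_populations: int = 5,
    n_cells: int = 50_000,
    n_panels: int = 15,
    n_conserved: int = 11,
    screen_per_panel: int = 5,
    n_donors: int = 3,
    informative_per_population: int = 2,
    donor_shift_sd: float = 0.05,
    seed: int = 0,
) -> SynthConfig:
    """Canonical well-separated screen scenario.

    Mirrors the structure of a split-panel HSPC screen: an 11-marker
    conserved core shared by 15 panels, several donors, and latent
    populations in decreasing proportions.  Each population carries a
    distinct binary signature on the conserved core (positive fraction
    0.95 on its signature markers vs 0.02 elsewhere, positive mode at
    asinh 4.5 vs negative mode 0.3 — modes roughly 8 component-SDs
    apart, i.e. well separated) plus ``informative_per_population``
    population-specific screen markers; the remaining screen markers are
    unstructured noise (positive fraction 0.3 in every population).
    """
    if n_conserved < 2 * n_populations + 1:
        raise ConfigurationError(
            "need n_conserved >= 2*n_populations + 1 for distinct signatures"
        )
    conserved = [f"core{i:02d}" for i in range(n_conserved)]
    panels = {
        f"panel{p:02d}": tuple(
            f"scr{p:02d}_{i}" for i in range(screen_per_panel)
        )
        for p in range(n_panels)
    }
    design = PanelDesign(conserved, panels)
    screen = list(design.screen_markers)
    pops = [f"pop{i}" for i in range(n_populations)]

    # proportions decay geometrically then renormalize: unequal but none tiny
    raw = np.array([0.85**i for i in range(n_populations)])
    proportions = raw / raw.sum()

    hot = MarkerModel(0.95, pos_mean=4.5, pos_sd=0.5, neg_mean=0.3, neg_sd=0.2)
    cold = MarkerModel(0.02, pos_mean=4.5, pos_sd=0.5, neg_mean=0.3, neg_sd=0.2)
    noise = MarkerModel(0.3, pos_mean=3.0, pos_sd=0.6, neg_mean=0.3, neg_sd=0.25)

    models: dict[str, dict[str, MarkerModel]] = {}
    for pi, pop in enumerate(pops):
        per: dict[str, MarkerModel] = {}
        # conserved signature: markers 2i, 2i+1 hot; the last marker hot
        # for everyone (a CD34-like compartment marker)
        signature = {conserved[2 * pi], conserved[2 * pi + 1], conserved[-1]}
        for m in conserved:
            per[m] = hot if m in signature else cold
        own = {
            screen[(pi * informative_per_population + j) % len(screen)]
            for j in range(informative_per_population)
        }
        for m in screen:
            per[m] = hot if m in own else noise
        models[pop] = per
    return SynthConfig(
        n_populations=n_populations,
        population_proportions=proportions,
        n_cells=n_cells,
        n_donors=n_donors,
        panel_design=design,
        marker_models=models,
        donor_shift_sd=donor_shift_sd,
        seed=seed,
    )


def simulate_lda_wells(
    f: float,
    doses: Sequence[float],
    wells_per_dose: int,
    seed: int,
    label: str = "simulated",
) -> LDAGroup:
    """Simulate limiting-dilution well plates under the single-hit model.

    Each well at dose d (cells plated) responds independently with
    probability 1 - exp(-f * d), the single-hit Poisson dose-response for
    active-progenitor frequency ``f`` per plated cell.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(f"frequency must be in [0,1], got {f}")
    doses = [float(d) for d in doses]
    if any(d <= 0 for d in doses):
        raise ConfigurationError("doses must be positive")
    if wells_per_dose < 1:
        raise ConfigurationError("wells_per_dose must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        p_respond = -np.expm1(-f * d)
        responding = int(rng.binomial(wells_per_dose, p_respond))
        rows.append((d, wells_per_dose, responding))
    return LDAGroup(label=label, rows=rows)
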