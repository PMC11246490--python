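"""Synthetic validation experiments for the full pipeline.

Each function simulates data with known ground truth, runs the relevant
pipeline stages, and returns the measured figures of merit.  They are
used both by the acceptance test suite and by ``scripts/acceptance.py``;
every source of randomness flows from the ``seed`` argument.

Scenario sizing notes (all deliberate, not incidental):

* The recovery scenario uses 50,000 cells over 15 panels with 5
  populations and 200 micro-clusters, i.e. ~250 cells per cluster and
  ~17 measured cells per cluster for each screen marker.  The published
  analysis this emulates had ~1288 cells per micro-cluster (~86 per
  panel); 200 keeps the per-panel bridging support adequate at this
  smaller simulation size, whereas 400 clusters would leave ~8 cells per
  panel and mixture-valued medians start flipping between modes.
* The stitching-consistency experiment uses 50 micro-clusters so that
  typical per-panel support is ~60-70 and entries down to the support-30
  floor exist and are exercised.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import PanelDesign
from .integrate import aggregate_medians, confusion_matrix, meta_cluster, micro_cluster
from .lda import _log_likelihood, fit_single_hit, frequency_ratio, lr_test, summarize_cloning
from .markers import cluster_level_correlation, ks_differential, nominate_minimal_panel, validate_recapitulation
from .preprocess import percentile_normalize
from .surrogate import evaluate_surrogate_gate
from .synth import (
    MarkerModel,
    SynthConfig,
    simulate_lda_wells,
    simulate_screen,
    well_separated_screen_config,
)

__all__ = [
    "printed_arithmetic",
    "pipeline_recovery",
    "stitching_consistency",
    "ks_null_calibration",
    "lda_estimator_checks",
    "lr_test_type_i",
    "surrogate_gate_identities",
]


def _spawn(seed: int, n: int) -> list[int]:
    """Derive independent sub-seeds (< 2^31) from one root seed."""
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# Worked arithmetic on published summary numbers


def printed_arithmetic() -> dict:
    """Deterministic ratio/summary arithmetic on published frequencies.

    Inputs are the published cross-donor mean frequencies (TdT+ GMP 3.20%,
    LMPP 0.28%, CLP 1.82% of CD34+ HSPCs), the fitted T-progenitor
    frequencies (CD84lo GMP 0.194, CD10+ CLP 1.11e-2, LMPP 0.263) and the
    single-cell cloning counts (58 positive wells of 312).
    """
    ratio_lmpp, _ = frequency_ratio(3.20, 0.28)
    ratio_clp, _ = frequency_ratio(3.20, 1.82)
    ratio_lda_clp, _ = frequency_ratio(0.194, 1.11e-2)
    ratio_lda_lmpp, _ = frequency_ratio(0.263, 0.194)
    wells = ["both"] * 25 + ["lymphoid"] * 20 + ["myeloid"] * 13 + ["none"] * 254
    cloning = summarize_cloning(wells)
    return {
        "freq_ratio_tdt_gmp_vs_lmpp": round(ratio_lmpp, 2),
        "freq_ratio_tdt_gmp_vs_clp": round(ratio_clp, 2),
        "lda_ratio_cd84lo_vs_clp": round(ratio_lda_clp, 2),
        "lda_ratio_lmpp_vs_cd84lo": round(ratio_lda_lmpp, 3),
        "cloning_efficiency_pct": round(float(cloning.efficiency) * 100, 1),
    }


# ---------------------------------------------------------------------------
# Pipeline recovery on the well-separated screen


def pipeline_recovery(
    seed: int,
    n_cells: int = 50_000,
    k_micro: int = 200,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    n_subsample_cap: int = 2000,
) -> dict:
    """Stitch-cluster-select on a 5-population, 15-panel simulation.

    Returns the meta-clustering ARI against ground truth and the
    recapitulation ARI of re-clustering on the nominated minimal panel
    (conventional conserved markers forced, per the panel-composition
    scheme) against the full-marker clustering.
    """
    s = _spawn(seed, 6)
    cfg = well_separated_screen_config(n_cells=n_cells, seed=s[0])
    table, truth = simulate_screen(cfg)
    norm, _ = percentile_normalize(table)
    conserved = list(cfg.panel_design.conserved_markers)
    micro = micro_cluster(norm, conserved, k=k_micro, algorithm="som", seed=s[1])
    profile = aggregate_medians(micro, norm, min_support=5)
    meta = meta_cluster(
        profile, k_neighbors=k_neighbors, resolution=resolution, seed=s[2]
    )
    cell_meta = meta.cell_labels(micro)
    _, ari_truth = confusion_matrix(cell_meta, truth.labels)

    screen = list(cfg.panel_design.screen_markers)
    groups = sorted(cell_meta.unique())
    diffs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                n_sub = n_subsample_cap
                for g in (a, b):
                    cells = cell_meta.index[cell_meta == g]
                    n_sub = min(
                        n_sub, int(norm.data.loc[cells, screen].notna().sum().min())
                    )
                diffs.append(
                    ks_differential(
                        norm, cell_meta, a, b, n_subsample=n_sub,
                        seed=s[3], markers=screen,
                    )
                )
        corr = cluster_level_correlation(profile)
    selection = nominate_minimal_panel(diffs, corr, forced_markers=conserved)
    _, ari_recap, _ = validate_recapitulation(
        profile, selection, meta,
        k_neighbors=k_neighbors, resolution=resolution, seed=s[4],
    )
    return {
        "n_meta_clusters": meta.n_meta,
        "meta_ari_vs_truth": ari_truth,
        "n_selected_markers": len(selection.selected),
        "minimal_panel_recap_ari": ari_recap,
        "n": n_cells,
    }


# ---------------------------------------------------------------------------
# Stitching consistency


def _true_mixture_median(model: MarkerModel) -> float:
    """Median of the (clip-at-zero) two-component normal mixture."""

    def cdf_minus_half(x: float) -> float:
        return (
            model.positive_fraction * stats.norm.cdf(x, model.pos_mean, model.pos_sd)
            + (1 - model.positive_fraction)
            * stats.norm.cdf(x, model.neg_mean, model.neg_sd)
        ) - 0.5

    med = optimize.brentq(cdf_minus_half, -10.0, 20.0, xtol=1e-12)
    return max(med, 0.0)


def stitching_consistency(
    seed: int,
    n_cells: int = 50_000,
    k_micro: int = 50,
    purity_floor: float = 0.95,
    support_floor: int = 30,
) -> dict:
    """Bridged cluster medians vs. the dominant population's true median.

    For every (micro-cluster, screen marker) entry with per-panel support
    at or above ``support_floor`` in a cluster dominated (>= purity_floor)
    by one population, measures |stitched median - true mixture median|
    in normalized units.  Reports the max and the deviation quantiles.
    """
    s = _spawn(seed, 3)
    cfg = well_separated_screen_config(n_cells=n_cells, seed=s[0])
    table, truth = simulate_screen(cfg)
    norm, divisors = percentile_normalize(table)
    conserved = list(cfg.panel_design.conserved_markers)
    micro = micro_cluster(norm, conserved, k=k_micro, algorithm="som", seed=s[1])
    profile = aggregate_medians(micro, norm, min_support=5)
    purity = truth.labels.groupby(micro.assignments).agg(
        lambda x: x.value_counts(normalize=True).iloc[0]
    )
    dominant = truth.labels.groupby(micro.assignments).agg(
        lambda x: x.value_counts().idxmax()
    )
    devs = []
    for cluster in profile.medians.index:
        if purity[cluster] < purity_floor:
            continue
        pop = dominant[cluster]
        for marker in cfg.panel_design.screen_markers:
            if profile.support.loc[cluster, marker] < support_floor:
                continue
            truth_med = min(
                _true_mixture_median(cfg.marker_models[pop][marker])
                / divisors[marker],
                1.0,
            )
            devs.append(abs(profile.medians.loc[cluster, marker] - truth_med))
    devs = np.asarray(devs)
    return {
        "n_entries": int(devs.size),
        "max_abs_deviation": float(devs.max()),
        "q99_abs_deviation": float(np.quantile(devs, 0.99)),
        "median_abs_deviation": float(np.median(devs)),
        "n": n_cells,
    }


# ---------------------------------------------------------------------------
# KS differential calibration


def ks_null_calibration(
    seed: int,
    n_replicates: int = 2000,
    n_markers: int = 81,
    n_per_group: int = 150,
    n_subsample: int = 100,
    alpha: float = 0.05,
) -> dict:
    """Family-wise false-positive rate of the Bonferroni-corrected KS screen.

    Both "populations" are draws from one distribution; a replicate counts
    as a family-wise false positive if any of the markers is flagged
    significant at alpha after Bonferroni correction.
    """
    s = _spawn(seed, 1)[0]
    design = PanelDesign([f"m{i:02d}" for i in range(n_markers)], {"p0": []})
    noise = MarkerModel(0.3, 3.0, 0.6, 0.3, 0.25)
    models = {"P0": {m: noise for m in design.all_markers}}
    cfg = SynthConfig(
        n_populations=1, population_proportions=[1.0],
        n_cells=2 * n_per_group, n_donors=1,
        panel_design=design, marker_models=models, seed=0,
    )
    false_positives = 0
    for rep in range(n_replicates):
        cfg.seed = (s + rep) % (2**31)
        table, _ = simulate_screen(cfg)
        labels = pd.Series(
            ["a"] * n_per_group + ["b"] * n_per_group, index=table.cell_ids
        )
        res = ks_differential(
            table, labels, "a", "b",
            n_subsample=n_subsample, alpha=alpha, n_tests=n_markers, seed=rep,
        )
        false_positives += bool(res.table["significant"].any())
    return {
        "family_wise_error_rate": false_positives / n_replicates,
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# Limiting-dilution estimator checks


def _grid_search_mle(group) -> float:
    """Independent dense-grid maximizer of the single-hit likelihood."""
    logf = np.linspace(-12.0, 3.0, 2001)
    for _ in range(4):
        ll = np.array([_log_likelihood(math.exp(t), group) for t in logf])
        best = logf[int(np.argmax(ll))]
        width = logf[1] - logf[0]
        logf = np.linspace(best - 2 * width, best + 2 * width, 201)
    return math.exp(best)


def lda_estimator_checks(
    seed: int,
    n_replicates: int = 500,
    f_true: float = 0.2,
    doses: tuple = (1, 3, 10, 30),
    wells_per_dose: int = 96,
) -> dict:
    """Monte-Carlo recovery of a known frequency plus grid-oracle agreement.

    Every fitted instance is compared with a dense grid-search maximizer
    of the same likelihood; reports the worst relative disagreement, the
    median estimate and the 95% Wald CI coverage.
    """
    s = _spawn(seed, 1)[0]
    f_hats, covered = [], 0
    worst_rel = 0.0
    for rep in range(n_replicates):
        group = simulate_lda_wells(
            f_true, list(doses), wells_per_dose, seed=(s + rep) % (2**31)
        )
        fit = fit_single_hit(group)
        f_hats.append(fit.f_hat)
        covered += fit.ci_lower <= f_true <= fit.ci_upper
        worst_rel = max(
            worst_rel, abs(fit.f_hat - _grid_search_mle(group)) / fit.f_hat
        )
    return {
        "median_f_hat": float(np.median(f_hats)),
        "ci_coverage": covered / n_replicates,
        "max_rel_dev_vs_grid_oracle": worst_rel,
        "n": n_replicates,
    }


def lr_test_type_i(
    seed: int,
    n_replicates: int = 1000,
    f_true: float = 0.1,
    doses: tuple = (1, 3, 10),
    wells_per_dose: int = 96,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the pairwise LR test under equal frequencies."""
    s = _spawn(seed, 1)[0]
    rejections = 0
    for rep in range(n_replicates):
        a = simulate_lda_wells(
            f_true, list(doses), wells_per_dose, seed=(s + 2 * rep) % (2**31)
        )
        b = simulate_lda_wells(
            f_true, list(doses), wells_per_dose, seed=(s + 2 * rep + 1) % (2**31)
        )
        _, p = lr_test(a, b)
        rejections += p < alpha
    return {"type_i_error_rate": rejections / n_replicates, "n": n_replicates}


# ---------------------------------------------------------------------------
# Surrogate-gate identities


def surrogate_gate_identities(
    seed: int, n_masks: int = 1000, n_cells: int = 200
) -> dict:
    """Exact count identities of fold / capture / contamination.

    On random target/gate/parent masks, verifies capture * |target+| ==
    |gate & target+| and fold * P(target+|parent) == P(target+|gate),
    exactly (rational arithmetic).  Returns the number of violations.
    """
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    idx = pd.Index([f"c{i}" for i in range(n_cells)])
    violations = 0
    checked = 0
    for _ in range(n_masks):
        tpos = pd.Series(rng.random(n_cells) < rng.uniform(0.05, 0.7), index=idx)
        gate = pd.Series(rng.random(n_cells) < rng.uniform(0.1, 0.9), index=idx)
        parent = pd.Series(rng.random(n_cells) < rng.uniform(0.5, 1.0), index=idx)
        if not parent.any() or not (gate & parent).any():
            continue
        perf = evaluate_surrogate_gate(tpos, gate, parent)
        checked += 1
        ok = perf.capture * perf.n_target_pos == perf.n_gate_target_pos
        if perf.n_target_pos:
            ok &= perf.fold * Fraction(perf.n_target_pos, perf.n_parent) == Fraction(
                perf.n_gate_target_pos, perf.n_gate
            )
        comp = perf.n_parent - perf.n_gate
        if perf.contamination is not None:
            ok &= perf.contamination == Fraction(
                perf.n_target_pos - perf.n_gate_target_pos, comp
            )
        violations += not ok
    return {"n_checked": checked, "n_violations": violations}
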