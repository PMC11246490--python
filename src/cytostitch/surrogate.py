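"""Surrogate surface-marker discovery and population-frequency statistics.

An informative intracellular target (e.g. the lymphoid enzyme TdT) cannot
be stained on live cells, so sorting its positive subset requires a
surface surrogate: a marker whose expression correlates with the target
within the gated parent population and whose own distribution is bimodal
enough to draw a clean sort gate (for TdT+ GMPs this is low CD84).
Candidates are scored by cell-level Pearson correlation with the target
and by mixture-model bimodality; a derived gate is then quantified by its
enrichment fold, capture fraction and contamination, all exact count
ratios.  Cross-donor frequency comparisons use paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionTable, InputError, InsufficientDataError
from .preprocess import BimodalThreshold, PopulationCall, derive_bimodal_threshold

__all__ = [
    "SurrogateReport",
    "FrequencyStats",
    "GatePerformance",
    "cell_level_correlation",
    "evaluate_surrogate_gate",
    "rank_candidates",
    "population_frequencies",
]

_MIN_PAIRS = 30


@dataclass(frozen=True)
class GatePerformance:
    """Exact count-based performance of a surrogate gate within a parent.

    fold          = P(target+ | gate & parent) / P(target+ | parent)
    capture       = P(gate | target+ & parent)
    contamination = P(target+ | ~gate & parent)
    """

    fold: Fraction
    capture: Fraction
    contamination: Fraction | None  # None when the complement gate is empty
    n_parent: int
    n_target_pos: int
    n_gate: int
    n_gate_target_pos: int


@dataclass
class SurrogateReport:
    """Ranked candidate table for one target within one parent gate.

    Columns: marker, r, separation, cutoff, orientation, fold, capture,
    contamination, low_confidence.  Orientation says which side of the
    cutoff ("lo" or "hi") enriches target-positive cells.
    """

    target: str
    parent: str
    table: pd.DataFrame


@dataclass
class FrequencyStats:
    """Cross-donor population frequencies within a parent compartment."""

    frequencies: pd.DataFrame  # donor x population, fractions of parent
    mean: pd.Series
    sd: pd.Series
    paired_tests: pd.DataFrame  # population_a, population_b, t, p, n_donors
    ratios: pd.DataFrame  # population_a, population_b, mean_ratio


def cell_level_correlation(
    table: ExpressionTable,
    parent_mask: pd.Series,
    target: str,
    candidates: Sequence[str],
) -> pd.Series:
    """Pearson r between the target and each candidate over parent cells.

    Only cells with both markers measured contribute (pairwise complete);
    a candidate with fewer than 30 complete pairs raises.
    """
    cells = parent_mask.index[parent_mask]
    sub = table.data.loc[cells]
    tv = sub[target] if target in sub.columns else None
    if tv is None:
        raise InputError(f"target {target!r} not in table")
    out = {}
    for cand in candidates:
        if cand not in sub.columns:
            raise InputError(f"candidate {cand!r} not in table")
        both = tv.notna() & sub[cand].notna()
        n = int(both.sum())
        if n < _MIN_PAIRS:
            raise InsufficientDataError(
                f"only {n} complete (target, {cand}) pairs within the parent "
                f"gate; need >= {_MIN_PAIRS}"
            )
        r = float(np.corrcoef(tv[both], sub.loc[both, cand])[0, 1])
        out[cand] = r
    return pd.Series(out, name=f"r_vs_{target}")


def evaluate_surrogate_gate(
    target_positive: pd.Series,
    gate_mask: pd.Series,
    parent_mask: pd.Series,
) -> GatePerformance:
    """Enrichment fold, capture and contamination of a gate, as exact ratios.

    All three masks must be boolean over the same cells.  Arithmetic is
    exact (Fractions on counts) so printed figures are rounding of true
    ratios, never floating-point artifacts.
    """
    idx = parent_mask.index
    if not (target_positive.index.equals(idx) and gate_mask.index.equals(idx)):
        raise InputError("masks must share one cell universe")
    parent = parent_mask.to_numpy(dtype=bool)
    if not parent.any():
        raise InputError("empty parent population")
    tpos = target_positive.to_numpy(dtype=bool) & parent
    gate = gate_mask.to_numpy(dtype=bool) & parent

    n_parent = int(parent.sum())
    n_tpos = int(tpos.sum())
    n_gate = int(gate.sum())
    n_gate_tpos = int((gate & tpos).sum())
    if n_gate == 0:
        raise InputError("gate does not intersect the parent population")

    base_rate = Fraction(n_tpos, n_parent)
    gate_rate = Fraction(n_gate_tpos, n_gate)
    fold = gate_rate / base_rate if base_rate else Fraction(0)
    capture = Fraction(n_gate_tpos, n_tpos) if n_tpos else Fraction(0)
    n_comp = n_parent - n_gate
    contamination = (
        Fraction(n_tpos - n_gate_tpos, n_comp) if n_comp else None
    )
    return GatePerformance(
        fold=fold,
        capture=capture,
        contamination=contamination,
        n_parent=n_parent,
        n_target_pos=n_tpos,
        n_gate=n_gate,
        n_gate_target_pos=n_gate_tpos,
    )


def rank_candidates(
    table: ExpressionTable,
    parent_mask: pd.Series,
    target: str,
    candidates: Sequence[str],
    target_cutoff: float | None = None,
    seed: int = 0,
) -> SurrogateReport:
    """Score candidate surrogates for a target within a parent gate.

    The target's positive/negative split comes from its bimodal mixture
    cutoff on parent-gated cells (or a manual ``target_cutoff``).  Each
    candidate gets: cell-level r with the target, its own bimodal cutoff
    and separation score, the gate orientation (side of the cutoff that
    enriches target-positives), and that gate's fold / capture /
    contamination.  Ranking is lexicographic — bimodal candidates
    (separation >= 1) first, then by |r| descending — because a high-|r|
    candidate without a clean positive/negative split cannot be sorted
    reliably.
    """
    cells = parent_mask.index[parent_mask]
    sub = table.data.loc[cells]
    tvals = sub[target].dropna()
    if target_cutoff is None:
        target_cutoff = derive_bimodal_threshold(tvals, seed=seed).cutoff
    tpos_parent = sub[target] > target_cutoff

    r = cell_level_correlation(table, parent_mask, target, candidates)
    rows = []
    for cand in candidates:
        cvals = sub[cand].dropna()
        thr: BimodalThreshold = derive_bimodal_threshold(cvals, seed=seed)
        both = sub[target].notna() & sub[cand].notna()
        universe = sub.index[both]
        tpos = tpos_parent.loc[universe]
        parent_all = pd.Series(True, index=universe)
        lo_gate = sub.loc[universe, cand] <= thr.cutoff
        perf_lo = evaluate_surrogate_gate(tpos, lo_gate, parent_all)
        perf_hi = evaluate_surrogate_gate(tpos, ~lo_gate, parent_all) if (
            (~lo_gate).any()
        ) else None
        if perf_hi is not None and perf_hi.fold > perf_lo.fold:
            orientation, perf = "hi", perf_hi
        else:
            orientation, perf = "lo", perf_lo
        rows.append(
            {
                "marker": cand,
                "r": r[cand],
                "separation": thr.separation,
                "cutoff": thr.cutoff,
                "orientation": orientation,
                "fold": float(perf.fold),
                "capture": float(perf.capture),
                "contamination": (
                    float(perf.contamination)
                    if perf.contamination is not None
                    else np.nan
                ),
                "low_confidence": thr.low_confidence,
            }
        )
    out = pd.DataFrame(rows)
    out["_bimodal"] = (~out["low_confidence"]).astype(int)
    out = (
        out.sort_values(
            by=["_bimodal", "r"],
            key=lambda s: s.abs() if s.name == "r" else s,
            ascending=[False, False],
        )
        .drop(columns="_bimodal")
        .reset_index(drop=True)
    )
    return SurrogateReport(target=target, parent="parent", table=out)


def population_frequencies(
    calls_by_donor: Mapping[str, PopulationCall],
    parent: Sequence[str] | None,
    populations: Sequence[str],
) -> FrequencyStats:
    """Per-donor population frequencies within a parent compartment.

    ``parent`` names the labels forming the denominator compartment
    (None = all cells of the donor).  Means and SDs use the n-1
    denominator; between-population comparisons are two-sided paired
    t-tests over donors carrying both populations.  With a single donor
    only descriptives are returned.  Also reports mean-frequency ratios,
    which are invariant to percent-vs-proportion scaling.
    """
    if not calls_by_donor:
        raise InputError("no donors supplied")
    freq_rows = {}
    for donor, call in calls_by_donor.items():
        labels = call.labels if hasattr(call, "labels") else call
        in_parent = (
            labels.isin(parent) if parent is not None else pd.Series(True, index=labels.index)
        )
        n_parent = int(in_parent.sum())
        if n_parent == 0:
            raise InputError(f"donor {donor!r} has no cells in the parent compartment")
        freq_rows[donor] = {
            pop: float((labels[in_parent] == pop).sum() / n_parent)
            for pop in populations
        }
    freq = pd.DataFrame(freq_rows).T
    freq.index.name = "donor"
    mean = freq.mean()
    sd = freq.std(ddof=1) if len(freq) > 1 else pd.Series(np.nan, index=freq.columns)

    tests = []
    ratios = []
    pops = list(populations)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            ratios.append(
                {
                    "population_a": a,
                    "population_b": b,
                    "mean_ratio": float(mean[a] / mean[b]) if mean[b] else np.nan,
                }
            )
            if len(freq) < 2:
                continue
            diffs = freq[a] - freq[b]
            if np.allclose(diffs, 0):
                tests.append(
                    {"population_a": a, "population_b": b, "t": 0.0, "p": 1.0,
                     "n_donors": len(freq), "zero_variance": True}
                )
                continue
            t, p = stats.ttest_rel(freq[a], freq[b])
            tests.append(
                {"population_a": a, "population_b": b, "t": float(t),
                 "p": float(p), "n_donors": len(freq), "zero_variance": False}
            )
    return FrequencyStats(
        frequencies=freq,
        mean=mean,
        sd=sd,
        paired_tests=pd.DataFrame(
            tests,
            columns=["population_a", "population_b", "t", "p", "n_donors", "zero_variance"],
        ),
        ratios=pd.DataFrame(ratios, columns=["population_a", "population_b", "mean_ratio"]),
    )
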