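"""Marker redundancy, differential power, and minimal-panel nomination.

A screen of ~80 antigens is highly redundant: lineage programs drive
blocks of correlated markers.  Redundancy is quantified by Pearson
correlation at the micro-cluster level (medians, not cells, so each
panel's markers are comparable), and discriminative power by two-sample
Kolmogorov-Smirnov tests between equally subsampled populations with
Bonferroni correction.  A greedy set-cover over (cluster-pair, marker)
significance then nominates a minimal panel: markers are added by how
many still-unseparated cluster pairs they separate, subject to a cap on
their absolute correlation with already-selected markers, optionally
seeded with forced conventional-gating markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionTable, InputError, InsufficientDataError
from .integrate import ClusterProfile, MetaClustering, MicroClustering, confusion_matrix, meta_cluster

__all__ = [
    "DifferentialResult",
    "MarkerPanelSelection",
    "cluster_level_correlation",
    "ks_differential",
    "nominate_minimal_panel",
    "validate_recapitulation",
]


@dataclass
class DifferentialResult:
    """KS differential statistics for one cluster pair.

    ``table`` columns: marker, D, p, p_adj, significant.  ``p_adj`` is
    the Bonferroni-adjusted p-value min(1, p * n_tests).
    """

    group_a: object
    group_b: object
    table: pd.DataFrame
    n_subsample: int
    n_tests: int
    alpha: float

    def __post_init__(self) -> None:
        t = self.table
        if ((t["D"] < 0) | (t["D"] > 1)).any():
            raise InputError("KS statistic must lie in [0, 1]")

    @property
    def significant_markers(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "marker"])


@dataclass
class MarkerPanelSelection:
    """Outcome of greedy minimal-panel nomination."""

    selected: list[str]
    records: pd.DataFrame  # marker, n_new_pairs, max_abs_r, forced
    params: dict


def cluster_level_correlation(
    profile: ClusterProfile, markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between markers over micro-cluster medians.

    Pairwise-complete over non-missing stitched entries; requires at
    least 3 complete observations per pair.  Constant markers have
    undefined correlation and are recorded as NaN with a warning.
    """
    med = profile.medians if markers is None else profile.medians[list(markers)]
    cols = list(med.columns)
    constant = [
        c for c in cols if med[c].dropna().nunique() <= 1 and med[c].notna().any()
    ]
    if constant:
        warnings.warn(
            f"constant markers have undefined correlation: {constant}", stacklevel=2
        )
    n_complete = med.notna().astype(int).T @ med.notna().astype(int)
    if (np.asarray(n_complete) < 3).any():
        thin = [
            (a, b)
            for a in cols
            for b in cols
            if a < b and n_complete.loc[a, b] < 3
        ]
        if thin:
            raise InsufficientDataError(
                f"fewer than 3 complete micro-clusters for pairs: {thin[:5]}"
            )
    corr = med.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    return corr


def ks_differential(
    table: ExpressionTable,
    calls,
    group_a,
    group_b,
    n_subsample: int,
    alpha: float = 0.05,
    n_tests: int | None = None,
    seed: int = 0,
    markers: Sequence[str] | None = None,
) -> DifferentialResult:
    """Two-sample KS tests between equally subsampled populations.

    From each group, ``n_subsample`` cells measured for the marker are
    drawn without replacement (seeded); markers with fewer measured
    cells in either group are skipped with a warning.  P-values are
    Bonferroni-multiplied by ``n_tests`` (default: the number of markers
    actually tested for this pair) and capped at 1.
    """
    labels = calls.labels if hasattr(calls, "labels") else calls
    if hasattr(calls, "assignments"):
        labels = calls.assignments
    for g in (group_a, group_b):
        if g not in set(labels.unique()):
            raise InputError(f"group {g!r} not present in the labeling")
    cells_a = labels.index[labels == group_a]
    cells_b = labels.index[labels == group_b]
    marker_list = list(markers) if markers is not None else table.markers
    rng = np.random.default_rng(seed)

    rows = []
    skipped = []
    for marker in marker_list:
        va = table.data.loc[cells_a, marker].dropna().to_numpy()
        vb = table.data.loc[cells_b, marker].dropna().to_numpy()
        if len(va) < n_subsample or len(vb) < n_subsample:
            skipped.append(marker)
            continue
        sa = rng.choice(va, size=n_subsample, replace=False)
        sb = rng.choice(vb, size=n_subsample, replace=False)
        # exact null distribution up to n=200: the asymptotic tail is
        # anticonservative there, which would defeat Bonferroni control
        method = "exact" if n_subsample <= 200 else "asymp"
        res = stats.ks_2samp(sa, sb, method=method)
        rows.append((marker, float(res.statistic), float(res.pvalue)))
    if skipped:
        warnings.warn(
            f"markers skipped (fewer than {n_subsample} measured cells in a "
            f"group): {skipped}",
            stacklevel=2,
        )
    out = pd.DataFrame(rows, columns=["marker", "D", "p"])
    family = n_tests if n_tests is not None else len(out)
    out["p_adj"] = np.minimum(1.0, out["p"] * family)
    out["significant"] = out["p_adj"] < alpha
    return DifferentialResult(
        group_a=group_a,
        group_b=group_b,
        table=out,
        n_subsample=n_subsample,
        n_tests=family,
        alpha=alpha,
    )


def nominate_minimal_panel(
    diff: Sequence[DifferentialResult],
    corr: pd.DataFrame,
    forced_markers: Sequence[str] = (),
    redundancy_cap: float = 0.8,
    max_size: int | None = None,
) -> MarkerPanelSelection:
    """Greedy set-cover nomination of a minimal informative marker panel.

    Starts from the forced (conventional-gating) markers; repeatedly adds
    the marker that separates the most not-yet-separated cluster pairs
    (a pair counts as separated once any selected marker is significant
    for it), skipping candidates whose max |r| against the selected set
    exceeds ``redundancy_cap``.  Stops when all pairs are covered, no
    admissible candidate remains, or ``max_size`` is reached.  Ties break
    by (coverage gain desc, max |r| asc, marker name asc) so the result
    is order-invariant.
    """
    if not diff:
        raise InputError("no differential results supplied")
    # pair -> set of markers significant for it
    sig_by_marker: dict[str, set] = {}
    all_pairs: set = set()
    universe: set[str] = set()
    for d in diff:
        pair = (d.group_a, d.group_b)
        all_pairs.add(pair)
        universe.update(d.table["marker"])
        for m in d.significant_markers:
            sig_by_marker.setdefault(m, set()).add(pair)
    missing = universe - set(corr.columns)
    if missing:
        raise InputError(f"correlation matrix missing markers: {sorted(missing)}")

    selected: list[str] = []
    records = []
    covered: set = set()

    def max_abs_r(m: str) -> float:
        if not selected:
            return 0.0
        vals = corr.loc[m, selected].abs().to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(vals.max()) if vals.size else 0.0

    for m in forced_markers:
        selected.append(m)
        gained = sig_by_marker.get(m, set()) - covered
        covered |= gained
        records.append((m, len(gained), max_abs_r(m), True))

    while covered != all_pairs:
        if max_size is not None and len(selected) >= max_size:
            break
        best: tuple | None = None
        for m in sorted(universe - set(selected)):
            gain = len(sig_by_marker.get(m, set()) - covered)
            if gain == 0:
                continue
            r = max_abs_r(m)
            if r > redundancy_cap:
                continue
            key = (-gain, r, m)
            if best is None or key < best[0]:
                best = (key, m, gain, r)
        if best is None:
            break
        _, m, gain, r = best
        selected.append(m)
        covered |= sig_by_marker.get(m, set())
        records.append((m, gain, r, False))

    return MarkerPanelSelection(
        selected=selected,
        records=pd.DataFrame(
            records, columns=["marker", "n_new_pairs", "max_abs_r", "forced"]
        ),
        params={
            "redundancy_cap": redundancy_cap,
            "max_size": max_size,
            "forced_markers": list(forced_markers),
            "n_pairs_total": len(all_pairs),
            "n_pairs_covered": len(covered),
        },
    )


def validate_recapitulation(
    profile_full: ClusterProfile,
    selection: MarkerPanelSelection | Sequence[str],
    reference: MetaClustering,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, MetaClustering]:
    """Re-cluster on the selected markers and compare with the full run.

    Returns the confusion matrix (full vs. reduced meta labels), the
    adjusted Rand index between the two partitions, and the reduced-panel
    meta-clustering itself.
    """
    markers = (
        selection.selected
        if isinstance(selection, MarkerPanelSelection)
        else list(selection)
    )
    absent = [m for m in markers if m not in profile_full.medians.columns]
    if absent:
        raise InputError(f"selected markers absent from profile: {absent}")
    reduced = meta_cluster(
        profile_full,
        markers=markers,
        k_neighbors=k_neighbors,
        resolution=resolution,
        seed=seed,
    )
    cm, ari = confusion_matrix(reference.labels, reduced.labels)
    return cm, ari, reduced
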