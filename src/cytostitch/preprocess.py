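"""Transformations, normalization, positivity and boolean-gate phenotyping.

Mass-cytometry ion counts are variance-stabilized with the standard
inverse hyperbolic sine transform, asinh(x / cofactor) with cofactor 5.
Downstream displays and clustering work on per-marker intensities scaled
to the 99.9th percentile (clipped at 1), which puts all markers on a
comparable [0, 1]-ish scale while being robust to the extreme tail.

Immunophenotypes are conjunctions of threshold predicates on marker
intensities (e.g. Lin- CD34+ CD38hi CD10- CD123med CD45RA+ for GMPs),
evaluated in a declared precedence order so each cell gets exactly one
label.  Bimodal markers (TdT, CD84) get data-driven cutoffs from a
two-component Gaussian mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .core import (
    ConfigurationError,
    ExpressionTable,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "GatePredicate",
    "GateDef",
    "PopulationCall",
    "BimodalThreshold",
    "asinh_transform",
    "percentile_normalize",
    "detect_expressed_markers",
    "apply_gates",
    "derive_bimodal_threshold",
    "UNGATED",
]

UNGATED = "ungated"
_RELATIONS = ("pos", "neg", "hi", "lo", "med")


def asinh_transform(x, cofactor: float = 5.0):
    """asinh(x / cofactor), elementwise; the standard CyTOF transform."""
    if cofactor <= 0:
        raise ConfigurationError(f"cofactor must be > 0, got {cofactor}")
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr) | np.isnan(arr)):
        raise InputError("raw intensities must be finite")
    out = np.arcsinh(arr / cofactor)
    return out if out.ndim else float(out)


def percentile_normalize(
    table: ExpressionTable, q: float = 99.9
) -> tuple[ExpressionTable, pd.Series]:
    """Scale each marker to its q-th percentile over measured cells.

    Values above 1 after division are clipped to 1.  Percentiles use
    linear interpolation between order statistics.  An all-zero marker is
    left at zero with a warning.  Returns the normalized table and the
    per-marker divisors (recorded in run metadata for auditability).
    """
    if table.n_cells == 0:
        raise InputError("empty expression table")
    data = table.data.copy()
    divisors = {}
    for marker in table.markers:
        vals = table.marker_values(marker)
        if vals.empty:
            raise InputError(f"marker {marker!r} has no measured values")
        div = float(np.percentile(vals.to_numpy(), q, method="linear"))
        divisors[marker] = div
        if div == 0.0:
            warnings.warn(
                f"marker {marker!r} is all-zero at the {q}th percentile; left as zeros",
                stacklevel=2,
            )
            continue
        data[marker] = np.clip(data[marker] / div, None, 1.0)
    return table.copy_with(data), pd.Series(divisors, name=f"p{q}_divisor")


def detect_expressed_markers(
    table: ExpressionTable,
    positivity_thresholds: Mapping[str, float],
    min_fraction: float = 0.001,
) -> tuple[set[str], pd.Series]:
    """Markers detected in at least ``min_fraction`` of measured cells.

    A cell is positive for a marker when its measured value exceeds the
    marker's cutoff; the positive fraction is computed only over cells on
    panels that measure the marker.  The boundary is inclusive: exactly
    min_fraction counts as detected.
    """
    missing = [m for m in table.markers if m not in positivity_thresholds]
    if missing:
        raise ConfigurationError(f"no positivity threshold for markers: {missing}")
    fractions = {}
    detected: set[str] = set()
    for marker in table.markers:
        vals = table.marker_values(marker)
        if vals.empty:
            warnings.warn(
                f"marker {marker!r} has zero measured cells; excluded", stacklevel=2
            )
            continue
        frac = float((vals.to_numpy() > positivity_thresholds[marker]).mean())
        fractions[marker] = frac
        if frac >= min_fraction:
            detected.add(marker)
    return detected, pd.Series(fractions, name="positive_fraction")


def default_positivity_thresholds(
    table: ExpressionTable,
    negative_control_cells,
    q: float = 99.5,
    overrides: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-marker cutoffs from a designated negative-control cell set.

    Each marker's cutoff is the q-th percentile of its values among the
    control cells — a stringent rule that limits false-positive detection
    calls.  ``overrides`` replaces individual cutoffs.
    """
    ctrl = table.subset(negative_control_cells)
    cuts: dict[str, float] = {}
    for marker in table.markers:
        vals = ctrl.marker_values(marker)
        if vals.empty:
            continue
        cuts[marker] = float(np.percentile(vals.to_numpy(), q, method="linear"))
    if overrides:
        cuts.update(overrides)
    return cuts


# ---------------------------------------------------------------------------
# Boolean immunophenotype gates


@dataclass(frozen=True)
class GatePredicate:
    """One threshold condition on one marker.

    Relations (asinh-scale thresholds; ties fixed so counts are
    bit-stable): pos/hi -> value > threshold; neg/lo -> value <=
    threshold; med -> low < value <= high.
    """

    marker: str
    relation: str
    threshold: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise ConfigurationError(f"unknown relation {self.relation!r}")
        if self.relation == "med":
            if (
                not isinstance(self.threshold, (tuple, list))
                or len(self.threshold) != 2
            ):
                raise ConfigurationError("'med' needs exactly two thresholds")
            lo, hi = self.threshold
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError("'med' thresholds must be finite with low < high")
            object.__setattr__(self, "threshold", (float(lo), float(hi)))
        else:
            if isinstance(self.threshold, (tuple, list)):
                raise ConfigurationError(
                    f"relation {self.relation!r} takes a single threshold"
                )
            if not np.isfinite(self.threshold):
                raise ConfigurationError("threshold must be finite")
            object.__setattr__(self, "threshold", float(self.threshold))

    def evaluate(self, values: pd.Series) -> pd.Series:
        v = values
        if self.relation in ("pos", "hi"):
            return v > self.threshold
        if self.relation in ("neg", "lo"):
            return v <= self.threshold
        lo, hi = self.threshold  # med
        return (v > lo) & (v <= hi)


@dataclass(frozen=True)
class GateDef:
    """Named conjunction of predicates, optionally nested under a parent."""

    name: str
    predicates: tuple[GatePredicate, ...]
    parent: str | None = None

    def __init__(
        self,
        name: str,
        predicates: Iterable[GatePredicate | tuple],
        parent: str | None = None,
    ) -> None:
        preds = tuple(
            p if isinstance(p, GatePredicate) else GatePredicate(*p)
            for p in predicates
        )
        seen = [p.marker for p in preds]
        if len(set(seen)) != len(seen):
            raise ConfigurationError(f"gate {name!r} repeats a marker")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "predicates", preds)
        object.__setattr__(self, "parent", parent)

    @property
    def markers(self) -> list[str]:
        return [p.marker for p in self.predicates]


@dataclass
class PopulationCall:
    """Per-cell population label from precedence-ordered gate evaluation."""

    labels: pd.Series  # index cell_id -> gate name or UNGATED
    gate_names: tuple[str, ...]

    def __post_init__(self) -> None:
        allowed = set(self.gate_names) | {UNGATED}
        bad = set(self.labels.unique()) - allowed
        if bad:
            raise InputError(f"labels outside the declared gate set: {sorted(bad)}")

    def mask(self, label: str) -> pd.Series:
        return self.labels == label

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def apply_gates(
    table: ExpressionTable,
    gates: Sequence[GateDef],
    parent_gates: Sequence[GateDef] = (),
) -> PopulationCall:
    """Label each cell with the first matching gate in precedence order.

    A gate's effective condition is the conjunction of its own predicates
    and (recursively) its parent gate's.  ``parent_gates`` are resolvable
    as parents (e.g. a shared Lin- CD34+ pre-gate) without being labels
    themselves.  Gates may only reference markers measured for every cell
    (i.e. conserved markers); cells matching no gate are labeled
    "ungated".  The declared order resolves overlaps.
    """
    by_name = {g.name: g for g in list(parent_gates) + list(gates)}
    if len(by_name) != len(gates) + len(parent_gates):
        raise ConfigurationError("duplicate gate names")

    def effective_predicates(g: GateDef) -> list[GatePredicate]:
        chain: list[GatePredicate] = []
        seen: set[str] = set()
        node: GateDef | None = g
        while node is not None:
            if node.name in seen:
                raise ConfigurationError(f"gate parent cycle at {node.name!r}")
            seen.add(node.name)
            chain = list(node.predicates) + chain
            if node.parent is None:
                node = None
            elif node.parent not in by_name:
                raise ConfigurationError(
                    f"gate {g.name!r} references unknown parent {node.parent!r}"
                )
            else:
                node = by_name[node.parent]
        return chain

    mask_all = table.measured_mask
    labels = pd.Series(UNGATED, index=table.cell_ids, dtype=object)
    unassigned = pd.Series(True, index=table.cell_ids)
    for gate in gates:
        match = pd.Series(True, index=table.cell_ids)
        for pred in effective_predicates(gate):
            if pred.marker not in table.data.columns:
                raise ConfigurationError(
                    f"gate {gate.name!r} references unknown marker {pred.marker!r}"
                )
            if not mask_all[pred.marker].all():
                raise ConfigurationError(
                    f"gate {gate.name!r} references marker {pred.marker!r} "
                    "that is unmeasured for some cells"
                )
            match &= pred.evaluate(table.data[pred.marker])
        take = match & unassigned
        labels[take] = gate.name
        unassigned &= ~take
    return PopulationCall(labels=labels, gate_names=tuple(g.name for g in gates))


# ---------------------------------------------------------------------------
# Data-driven bimodal cutoffs


@dataclass(frozen=True)
class BimodalThreshold:
    """Two-component mixture cutoff for a bimodal marker."""

    cutoff: float
    separation: float  # |mu2-mu1| / sqrt((s1^2+s2^2)/2)
    low_confidence: bool
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]


def derive_bimodal_threshold(
    values, *, seed: int = 0, min_n: int = 50
) -> BimodalThreshold:
    """Cutoff separating the negative and positive modes of one marker.

    Fits a two-component univariate Gaussian mixture and returns the
    intensity between the component means where the posterior
    responsibility crosses 0.5 (i.e. the weighted component densities are
    equal).  The separation score |mu2 - mu1| / sqrt((s1^2 + s2^2)/2) is a
    d-prime-style distance; the cutoff is flagged low-confidence when the
    score is below 1 or when the fitted mixture density has no real
    valley at the cutoff (a two-component fit of unimodal data splits it
    into heavily overlapping halves whose "cutoff" sits in a region as
    dense as the modes).
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < min_n:
        raise InsufficientDataError(
            f"need >= {min_n} values for a bimodal fit, got {v.size}"
        )
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=5, random_state=seed
    ).fit(v.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    separation = abs(m2 - m1) / np.sqrt((s1**2 + s2**2) / 2.0)

    def logdiff(x: float) -> float:
        return (np.log(w1) + stats.norm.logpdf(x, m1, s1)) - (
            np.log(w2) + stats.norm.logpdf(x, m2, s2)
        )

    if m2 - m1 < 1e-12 or logdiff(m1) * logdiff(m2) > 0:
        cutoff = float((m1 + m2) / 2.0)  # degenerate: midpoint fallback
    else:
        cutoff = float(optimize.brentq(logdiff, m1, m2, xtol=1e-10))

    def mix_pdf(x: float) -> float:
        return w1 * stats.norm.pdf(x, m1, s1) + w2 * stats.norm.pdf(x, m2, s2)

    valley_ratio = mix_pdf(cutoff) / min(mix_pdf(m1), mix_pdf(m2))
    return BimodalThreshold(
        cutoff=cutoff,
        separation=float(separation),
        low_confidence=bool(separation < 1.0 or valley_ratio > 0.8),
        means=(float(m1), float(m2)),
        sds=(float(s1), float(s2)),
        weights=(float(w1), float(w2)),
    )
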