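"""Single-hit Poisson limiting-dilution statistics and cloning summaries.

In a limiting dilution assay, graded doses of d cells are plated into
replicate wells and each well is scored responding / non-responding.
Under the single-hit model one active progenitor suffices to make a well
respond, so with active-cell frequency f per plated cell

    P(well responds | dose d) = 1 - exp(-f * d),

a binomial GLM with complementary log-log link, offset log d and slope
fixed at 1.  The MLE of f maximizes

    l(f) = sum_d [ r_d * log(1 - e^{-f d}) - (n_d - r_d) * f * d ],

which is strictly concave in log f for non-boundary data.  Group
comparisons use the likelihood-ratio test against a pooled single-f fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .core import InputError, ParameterError

__all__ = [
    "LDAGroup",
    "LDAFit",
    "CloningSummary",
    "fit_single_hit",
    "lr_test",
    "frequency_ratio",
    "summarize_cloning",
]

_Z95 = stats.norm.ppf(0.975)
_LOGF_TOL = 1e-10


@dataclass(frozen=True)
class LDAGroup:
    """Dose/response well counts for one sorted population.

    rows: (dose = cells per well, n_wells tested, n_responding).
    """

    label: str
    rows: Sequence[tuple[float, int, int]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("LDAGroup needs at least one dose row")
        for d, n, r in self.rows:
            if d <= 0:
                raise InputError(f"dose must be positive, got {d}")
            if n < 1:
                raise InputError(f"n_wells must be >= 1, got {n}")
            if not 0 <= r <= n:
                raise InputError(f"n_responding must be in [0, n_wells], got {r}/{n}")

    @property
    def doses(self) -> np.ndarray:
        return np.array([row[0] for row in self.rows], dtype=float)

    @property
    def n_wells(self) -> np.ndarray:
        return np.array([row[1] for row in self.rows], dtype=float)

    @property
    def n_responding(self) -> np.ndarray:
        return np.array([row[2] for row in self.rows], dtype=float)

    def pooled(self, other: "LDAGroup") -> "LDAGroup":
        return LDAGroup(
            label=f"{self.label}+{other.label}",
            rows=tuple(self.rows) + tuple(other.rows),
        )


@dataclass(frozen=True)
class LDAFit:
    """Fitted single-hit frequency with Wald interval on the log scale."""

    label: str
    f_hat: float
    se_log_f: float | None
    ci_lower: float | None
    ci_upper: float | None
    log_likelihood: float
    boundary: str | None = None  # "all_negative" | "all_positive" | None

    @property
    def is_boundary(self) -> bool:
        return self.boundary is not None


@dataclass(frozen=True)
class CloningSummary:
    """Outcome counts of a single-cell cloning assay."""

    n_wells_total: int
    n_positive: int
    n_lymphoid_only: int
    n_myeloid_only: int
    n_bipotent: int
    efficiency: Fraction
    bipotent_fraction: Fraction | None  # None when no positive wells


def _log_likelihood(f: float, group: LDAGroup) -> float:
    d, n, r = group.doses, group.n_wells, group.n_responding
    if f <= 0:
        return 0.0 if r.sum() == 0 else -np.inf
    p = -np.expm1(-f * d)  # 1 - e^{-fd}, stable for small f*d
    with np.errstate(divide="ignore"):
        term_pos = np.where(r > 0, r * np.log(p), 0.0)
    return float(np.sum(term_pos - (n - r) * f * d))


def _score(f: float, group: LDAGroup) -> float:
    """dl/df; strictly decreasing in f for non-boundary data."""
    d, n, r = group.doses, group.n_wells, group.n_responding
    e = np.exp(-f * d)
    return float(np.sum(r * d * e / (1.0 - e) - (n - r) * d))


def fit_single_hit(group: LDAGroup) -> LDAFit:
    """Maximum-likelihood single-hit frequency for one dose/response group.

    Boundary data (no responding wells anywhere, or every well responding)
    have no finite interior MLE; they are flagged and given a one-sided
    95% bound from the exact all-or-nothing probability instead of a
    Wald interval.
    """
    d, n, r = group.doses, group.n_wells, group.n_responding
    total_nd = float(np.sum(n * d))
    if r.sum() == 0:
        # P(all negative | f) = exp(-f * sum n_d d) = 0.05 at the bound
        upper = -math.log(0.05) / total_nd
        return LDAFit(group.label, 0.0, None, None, upper, 0.0, "all_negative")
    if np.all(r == n):
        # one-sided lower bound: P(all respond | f) = 0.05
        def all_pos(logf: float) -> float:
            p = -np.expm1(-math.exp(logf) * d)
            return float(np.sum(n * np.log(p))) - math.log(0.05)

        lo = optimize.brentq(all_pos, -40.0, 40.0, xtol=1e-12)
        return LDAFit(
            group.label,
            math.inf,
            None,
            math.exp(lo),
            None,
            float(np.sum(n * 0.0)),
            "all_positive",
        )

    # bracket log f from single-dose closed forms f = -ln(1 - r/n)/d
    informative = (r > 0) & (r < n)
    if informative.any():
        singles = -np.log(1.0 - r[informative] / n[informative]) / d[informative]
        lo = math.log(singles.min()) - 5.0
        hi = math.log(singles.max()) + 5.0
    else:  # mixture of all-0 and all-n doses
        lo, hi = -30.0, 10.0
    while _score(math.exp(lo), group) < 0:
        lo -= 5.0
    while _score(math.exp(hi), group) > 0:
        hi += 5.0
    logf = optimize.brentq(
        lambda t: _score(math.exp(t), group), lo, hi, xtol=_LOGF_TOL
    )
    f_hat = math.exp(logf)

    # observed information on the log f scale; at the MLE the score term
    # vanishes so I = -f^2 * l''(f)
    e = np.exp(-f_hat * d)
    ell2 = -float(np.sum(r * d**2 * e / (1.0 - e) ** 2))
    info = -(f_hat**2) * ell2
    se = 1.0 / math.sqrt(info)
    return LDAFit(
        label=group.label,
        f_hat=f_hat,
        se_log_f=se,
        ci_lower=math.exp(logf - _Z95 * se),
        ci_upper=math.exp(logf + _Z95 * se),
        log_likelihood=_log_likelihood(f_hat, group),
    )


def lr_test(group_a: LDAGroup, group_b: LDAGroup) -> tuple[float, float]:
    """Likelihood-ratio test of equal single-hit frequency (df = 1)."""
    fit_a = fit_single_hit(group_a)
    fit_b = fit_single_hit(group_b)
    if fit_a.is_boundary or fit_b.is_boundary:
        raise ParameterError(
            "boundary group (all wells positive or negative) has no finite MLE; "
            "use a one-sided exact comparison instead"
        )
    pooled = fit_single_hit(group_a.pooled(group_b))
    stat = 2.0 * (
        fit_a.log_likelihood + fit_b.log_likelihood - pooled.log_likelihood
    )
    stat = max(stat, 0.0)  # guard tiny negative from optimizer tolerance
    return stat, float(stats.chi2.sf(stat, df=1))


def frequency_ratio(
    fit_a: LDAFit | float, fit_b: LDAFit | float
) -> tuple[float, tuple[float, float] | None]:
    """Ratio f_a / f_b with an approximate CI when SEs are available.

    Accepts fitted objects or plain frequencies; the ratio of two
    frequencies is scale-invariant so percent inputs work too.
    """
    f_a = fit_a.f_hat if isinstance(fit_a, LDAFit) else float(fit_a)
    f_b = fit_b.f_hat if isinstance(fit_b, LDAFit) else float(fit_b)
    if f_b == 0:
        raise ParameterError("denominator frequency is zero; ratio undefined")
    ratio = f_a / f_b
    ci = None
    if (
        isinstance(fit_a, LDAFit)
        and isinstance(fit_b, LDAFit)
        and fit_a.se_log_f is not None
        and fit_b.se_log_f is not None
    ):
        se = math.hypot(fit_a.se_log_f, fit_b.se_log_f)
        ci = (ratio * math.exp(-_Z95 * se), ratio * math.exp(_Z95 * se))
    return ratio, ci


_OUTCOMES = ("none", "lymphoid", "myeloid", "both")


def summarize_cloning(wells: Iterable[str]) -> CloningSummary:
    """Summarize per-well lineage readouts of a single-cell cloning assay.

    ``wells`` holds one outcome per well: "none", "lymphoid", "myeloid"
    or "both".  Fractions are exact rationals; round only for display.
    """
    wells = list(wells)
    if not wells:
        raise InputError("at least one well required")
    bad = sorted({w for w in wells if w not in _OUTCOMES})
    if bad:
        raise InputError(f"unknown well outcomes: {bad}")
    n_total = len(wells)
    n_l = wells.count("lymphoid")
    n_m = wells.count("myeloid")
    n_b = wells.count("both")
    n_pos = n_l + n_m + n_b
    return CloningSummary(
        n_wells_total=n_total,
        n_positive=n_pos,
        n_lymphoid_only=n_l,
        n_myeloid_only=n_m,
        n_bipotent=n_b,
        efficiency=Fraction(n_pos, n_total),
        bipotent_fraction=Fraction(n_b, n_pos) if n_pos else None,
    )


def summarize_cloning_by_replicate(
    wells: Iterable[str], replicates: Iterable
) -> dict:
    """Per-replicate cloning summaries plus mean +/- SD of the fractions."""
    import pandas as pd

    df = pd.DataFrame({"well": list(wells), "rep": list(replicates)})
    per = {rep: summarize_cloning(sub["well"]) for rep, sub in df.groupby("rep")}
    eff = np.array([float(s.efficiency) for s in per.values()])
    bip = np.array(
        [float(s.bipotent_fraction) for s in per.values() if s.bipotent_fraction is not None]
    )
    return {
        "per_replicate": per,
        "efficiency_mean": float(eff.mean()),
        "efficiency_sd": float(eff.std(ddof=1)) if len(eff) > 1 else float("nan"),
        "bipotent_mean": float(bip.mean()) if bip.size else float("nan"),
        "bipotent_sd": float(bip.std(ddof=1)) if len(bip) > 1 else float("nan"),
    }
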