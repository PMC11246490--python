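"""Transform, normalization, positivity, gating and bimodal-cutoff checks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from cytostitch import (
    ConfigurationError,
    GateDef,
    GatePredicate,
    InsufficientDataError,
    UNGATED,
    apply_gates,
    asinh_transform,
    derive_bimodal_threshold,
    detect_expressed_markers,
    percentile_normalize,
)

from conftest import HSPC_MARKERS, hspc_gating_table, single_marker_table


class TestAsinh:
    @pytest.mark.parametrize(
        "x, cofactor, expected",
        [
            (0.0, 5.0, 0.0),
            (5.0, 5.0, math.log(1 + math.sqrt(2))),  # asinh(1)
            (50.0, 5.0, math.log(10 + math.sqrt(101))),  # asinh(10)
        ],
    )
    def test_closed_form(self, x, cofactor, expected):
        assert asinh_transform(x, cofactor) == pytest.approx(expected, abs=1e-9)

    def test_elementwise_over_matrices(self):
        x = np.array([[0.0, 5.0], [50.0, 500.0]])
        out = asinh_transform(x)
        assert out.shape == x.shape
        assert out[0, 1] == pytest.approx(math.asinh(1.0))

    def test_bad_cofactor(self):
        with pytest.raises(ConfigurationError):
            asinh_transform(1.0, cofactor=0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        x=st.floats(min_value=0.0, max_value=1e4),
        c=st.floats(min_value=0.1, max_value=100.0),
    )
    def test_sinh_inverse_identity(self, x, c):
        assert math.sinh(asinh_transform(x, c)) * c == pytest.approx(x, abs=1e-9, rel=1e-9)


class TestPercentileNormalize:
    def test_max_self_normalizes(self):
        table = single_marker_table([0.0] * 99 + [10.0])
        normed, div = percentile_normalize(table, q=99.9)
        assert normed.data["m0"].max() == pytest.approx(1.0)

    def test_constant_marker_all_ones(self):
        table = single_marker_table([3.5] * 50)
        normed, _ = percentile_normalize(table)
        assert np.allclose(normed.data["m0"], 1.0)

    def test_linear_interpolation_divisor(self):
        # 0..999: the 99.9th percentile under linear interpolation between
        # order statistics is 998.001 (oracle computed from the rule itself)
        values = np.arange(1000, dtype=float)
        rank = 99.9 / 100 * 999  # = 997.001 -> between v[997] and v[998]
        oracle = 997 + (rank - 997) * 1.0
        assert oracle == pytest.approx(998.001)
        table = single_marker_table(values)
        normed, div = percentile_normalize(table, q=99.9)
        assert div["m0"] == pytest.approx(998.001)
        assert normed.data["m0"].iloc[500] == pytest.approx(500 / 998.001)

    def test_values_clipped_at_one(self):
        table = single_marker_table(np.arange(1000, dtype=float))
        normed, _ = percentile_normalize(table)
        assert normed.data["m0"].max() == 1.0

    def test_all_zero_marker_left_with_warning(self):
        table = single_marker_table([0.0] * 60)
        with pytest.warns(UserWarning, match="all-zero"):
            normed, _ = percentile_normalize(table)
        assert (normed.data["m0"] == 0).all()

    def test_idempotent_up_to_clipping(self):
        table = single_marker_table(np.arange(1000, dtype=float))
        once, _ = percentile_normalize(table)
        twice, _ = percentile_normalize(once)
        assert np.allclose(once.data["m0"], twice.data["m0"], atol=1e-6)


class TestDetectExpressed:
    def test_boundary_is_inclusive(self):
        # 1 positive among 1000 measured cells is exactly 0.1% -> detected
        table = single_marker_table([0.0] * 999 + [5.0])
        detected, frac = detect_expressed_markers(table, {"m0": 1.0}, min_fraction=0.001)
        assert "m0" in detected
        assert frac["m0"] == pytest.approx(0.001)

    def test_zero_positives_not_detected(self):
        table = single_marker_table([0.0] * 1000)
        detected, _ = detect_expressed_markers(table, {"m0": 1.0})
        assert "m0" not in detected

    def test_rare_population_marker_detected(self):
        # positive in 5% of a population comprising 10% of cells -> ~0.5%
        rng = np.random.default_rng(0)
        n = 20_000
        in_pop = rng.random(n) < 0.10
        pos = in_pop & (rng.random(n) < 0.05)
        values = np.where(pos, rng.normal(5, 0.3, n), np.abs(rng.normal(0.2, 0.1, n)))
        table = single_marker_table(values)
        detected, frac = detect_expressed_markers(table, {"m0": 2.0})
        assert "m0" in detected
        se = math.sqrt(0.005 * 0.995 / n)
        assert abs(frac["m0"] - 0.005) < 4 * se

    def test_monotone_in_min_fraction(self):
        rng = np.random.default_rng(1)
        table = single_marker_table(rng.exponential(0.5, size=2000))
        cuts = {"m0": 2.0}
        prev: set | None = None
        for mf in (0.0005, 0.001, 0.005, 0.05, 0.5):
            detected, _ = detect_expressed_markers(table, cuts, min_fraction=mf)
            if prev is not None:
                assert detected <= prev
            prev = detected

    def test_missing_threshold_rejected(self):
        table = single_marker_table([1.0] * 10)
        with pytest.raises(ConfigurationError):
            detect_expressed_markers(table, {})


def hspc_gates(t_pos: float = 1.0, t_hi: float = 2.5):
    """Conventional HSPC gate set (thresholds on the asinh scale).

    All gates descend from a Lin- CD34+ parent; the CD38lo compartment
    splits into HSC / MPP / LMPP by CD90 x CD45RA and the CD38hi
    compartment into CLP / GMP / CMP / MEP / pDC by CD10, CD123, CD45RA.
    """
    parent = GateDef("CD34pos", [("Lin", "neg", t_pos), ("CD34", "pos", t_pos)])
    med = (t_pos, t_hi)
    defs = [
        parent,
        GateDef("CLP", [("CD38", "hi", t_hi), ("CD10", "pos", t_pos)], parent="CD34pos"),
        GateDef(
            "GMP",
            [("CD38", "hi", t_hi), ("CD10", "neg", t_pos), ("CD123", "med", med),
             ("CD45RA", "pos", t_pos)],
            parent="CD34pos",
        ),
        GateDef(
            "CMP",
            [("CD38", "hi", t_hi), ("CD10", "neg", t_pos), ("CD123", "med", med),
             ("CD45RA", "neg", t_pos)],
            parent="CD34pos",
        ),
        GateDef(
            "MEP",
            [("CD38", "hi", t_hi), ("CD10", "neg", t_pos), ("CD123", "neg", t_pos),
             ("CD45RA", "neg", t_pos)],
            parent="CD34pos",
        ),
        GateDef(
            "HSC",
            [("CD38", "lo", t_hi), ("CD90", "pos", t_pos), ("CD45RA", "neg", t_pos)],
            parent="CD34pos",
        ),
        GateDef(
            "MPP",
            [("CD38", "lo", t_hi), ("CD90", "neg", t_pos), ("CD45RA", "neg", t_pos)],
            parent="CD34pos",
        ),
        GateDef(
            "LMPP",
            [("CD38", "lo", t_hi), ("CD90", "neg", t_pos), ("CD45RA", "pos", t_pos)],
            parent="CD34pos",
        ),
    ]
    return defs[1:], [parent]  # the parent is referenced, not itself a label


class TestApplyGates:
    def test_clp_call(self):
        # Lin- CD34+ CD38hi CD10+ -> CLP
        row = {"Lin": 0.1, "CD34": 4.0, "CD38": 4.0, "CD90": 0.2,
               "CD45RA": 0.3, "CD10": 3.0, "CD123": 0.0}
        table = hspc_gating_table(np.array([[row[m] for m in HSPC_MARKERS]]))
        gates, parents = hspc_gates()
        calls = apply_gates(table, gates, parent_gates=parents)
        assert calls.labels.iloc[0] == "CLP"

    def test_cd34_negative_is_ungated(self):
        row = {"Lin": 0.1, "CD34": 0.2, "CD38": 4.0, "CD90": 0.2,
               "CD45RA": 0.3, "CD10": 3.0, "CD123": 0.0}
        table = hspc_gating_table(np.array([[row[m] for m in HSPC_MARKERS]]))
        gates, parents = hspc_gates()
        calls = apply_gates(table, gates, parent_gates=parents)
        assert calls.labels.iloc[0] == UNGATED

    def test_gmp_count_matches_direct_predicate_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 5, size=(200, len(HSPC_MARKERS)))
        table = hspc_gating_table(values)
        gates, parents = hspc_gates()
        calls = apply_gates(table, gates, parent_gates=parents)
        # oracle: direct evaluation of the GMP conjunction; GMP precedes
        # every other gate a GMP-conjunction cell could match
        m = {name: values[:, i] for i, name in enumerate(HSPC_MARKERS)}
        gmp = (
            (m["Lin"] <= 1.0) & (m["CD34"] > 1.0) & (m["CD38"] > 2.5)
            & (m["CD10"] <= 1.0) & (m["CD123"] > 1.0) & (m["CD123"] <= 2.5)
            & (m["CD45RA"] > 1.0)
        )
        assert (calls.labels == "GMP").sum() == int(gmp.sum())

    def test_partition_every_cell_one_label(self):
        rng = np.random.default_rng(6)
        table = hspc_gating_table(rng.uniform(0, 5, size=(500, len(HSPC_MARKERS))))
        gates, parents = hspc_gates()
        calls = apply_gates(table, gates, parent_gates=parents)
        assert len(calls.labels) == 500
        assert calls.labels.notna().all()
        assert set(calls.labels.unique()) <= set(calls.gate_names) | {UNGATED}

    def test_precedence_resolves_overlap(self):
        # a cell matching both CLP and GMP conjunctions takes the first gate
        row = {"Lin": 0.1, "CD34": 4.0, "CD38": 4.0, "CD90": 0.2,
               "CD45RA": 2.0, "CD10": 3.0, "CD123": 2.0}
        table = hspc_gating_table(np.array([[row[m] for m in HSPC_MARKERS]]))
        gates, parents = hspc_gates()
        overlap_gmp = GateDef(
            "GMPlike",
            [("CD38", "hi", 2.5), ("CD123", "med", (1.0, 2.5)), ("CD45RA", "pos", 1.0)],
            parent="CD34pos",
        )
        calls = apply_gates(
            table, gates[:1] + [overlap_gmp] + gates[1:], parent_gates=parents
        )
        assert calls.labels.iloc[0] == "CLP"

    def test_unknown_marker_rejected(self):
        table = hspc_gating_table(np.zeros((3, len(HSPC_MARKERS))))
        with pytest.raises(ConfigurationError, match="unknown marker"):
            apply_gates(table, [GateDef("bad", [("CD999", "pos", 1.0)])])


class TestBimodalThreshold:
    def test_symmetric_mixture_midpoint(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 1, 1500), rng.normal(6, 1, 1500)])
        thr = derive_bimodal_threshold(v, seed=0)
        assert thr.cutoff == pytest.approx(3.0, abs=0.3)
        assert thr.separation == pytest.approx(6.0, abs=0.8)
        assert not thr.low_confidence

    def test_unimodal_flagged(self):
        rng = np.random.default_rng(1)
        thr = derive_bimodal_threshold(rng.normal(2, 1, 1000), seed=0)
        assert thr.low_confidence

    def test_unbalanced_mixture_cutoff_shifts_toward_minor_mode(self):
        # oracle: solve the posterior-crossing equation at the true
        # parameters (w=0.9/0.1, means 0/6, sd 1)
        def logdiff(x):
            return (math.log(0.9) + stats.norm.logpdf(x, 0, 1)) - (
                math.log(0.1) + stats.norm.logpdf(x, 6, 1)
            )

        oracle = optimize.brentq(logdiff, 0, 6)
        assert oracle == pytest.approx(3 + math.log(9) / 6)
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(0, 1, 4500), rng.normal(6, 1, 500)])
        thr = derive_bimodal_threshold(v, seed=0)
        assert thr.cutoff > 3.1
        assert thr.cutoff == pytest.approx(oracle, abs=0.35)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            derive_bimodal_threshold(np.arange(49, dtype=float))
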