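"""Micro-clustering, median bridging and meta-clustering checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cytostitch import (
    ExpressionTable,
    InputError,
    PanelDesign,
    ParameterError,
    aggregate_medians,
    confusion_matrix,
    meta_cluster,
    micro_cluster,
)
from cytostitch.integrate import ClusterProfile, _lower_median
from cytostitch.synth import simulate_screen, well_separated_screen_config


def point_mass_table(centers, n_per: int = 30) -> tuple[ExpressionTable, np.ndarray]:
    design = PanelDesign(conserved_markers=["x", "y"], panels={"p0": []})
    rows, truth = [], []
    for ci, (cx, cy) in enumerate(centers):
        for _ in range(n_per):
            rows.append((cx, cy))
            truth.append(ci)
    df = pd.DataFrame(rows, columns=["x", "y"])
    df.insert(0, "donor_id", "d1")
    df.insert(1, "panel_id", "p0")
    df.index = pd.Index([f"c{i}" for i in range(len(df))], name="cell_id")
    return ExpressionTable(df, design), np.array(truth)


class TestMicroCluster:
    @pytest.mark.parametrize("algorithm", ["som", "kmeans"])
    def test_point_masses_perfectly_separated(self, algorithm):
        table, truth = point_mass_table([(0, 0), (10, 0), (0, 10)])
        mc = micro_cluster(table, ["x", "y"], k=3, algorithm=algorithm, seed=0)
        assert adjusted_rand_score(truth, mc.assignments.to_numpy()) == 1.0

    @pytest.mark.parametrize("algorithm", ["som", "kmeans"])
    def test_identical_cells_identical_assignment(self, algorithm):
        table, _ = point_mass_table([(0, 0), (8, 8)], n_per=40)
        mc = micro_cluster(table, ["x", "y"], k=2, algorithm=algorithm, seed=1)
        coords = table.data[["x", "y"]].apply(tuple, axis=1)
        for _, idx in coords.groupby(coords).groups.items():
            assert mc.assignments.loc[idx].nunique() == 1

    def test_order_invariance(self):
        cfg = well_separated_screen_config(
            n_populations=3, n_cells=1500, n_panels=3, n_conserved=7,
            screen_per_panel=2, seed=4,
        )
        table, _ = simulate_screen(cfg)
        shuffled = ExpressionTable(
            table.data.sample(frac=1.0, random_state=0), cfg.panel_design
        )
        a = micro_cluster(table, cfg.panel_design.conserved_markers, k=20, seed=2)
        b = micro_cluster(shuffled, cfg.panel_design.conserved_markers, k=20, seed=2)
        pd.testing.assert_series_equal(
            a.assignments.sort_index(), b.assignments.sort_index()
        )

    def test_majority_purity_on_separated_populations(self):
        cfg = well_separated_screen_config(
            n_populations=4, n_cells=8000, n_panels=4, n_conserved=9,
            screen_per_panel=3, seed=3,
        )
        table, truth = simulate_screen(cfg)
        mc = micro_cluster(table, cfg.panel_design.conserved_markers, k=60, seed=5)
        purity = truth.labels.groupby(mc.assignments).agg(
            lambda s: s.value_counts().iloc[0] / len(s)
        )
        sizes = mc.assignments.value_counts()
        # weight by cluster size: big clusters must be essentially pure
        assert (purity * sizes).sum() / sizes.sum() >= 0.9

    def test_k_too_large_rejected(self):
        table, _ = point_mass_table([(0, 0)], n_per=10)
        with pytest.raises(ParameterError):
            micro_cluster(table, ["x", "y"], k=10, seed=0)

    def test_unmeasured_marker_rejected(self, three_pop_screen):
        table, _ = three_pop_screen
        with pytest.raises(InputError):
            micro_cluster(table, ["c0", "sA0"], k=5, seed=0)


class TestAggregateMedians:
    def test_constant_cluster(self, three_pop_screen):
        table, _ = three_pop_screen
        sub = table.subset(table.cell_ids[:40])
        assign = pd.Series(0, index=sub.cell_ids, name="micro")
        from cytostitch.integrate import MicroClustering

        mc = MicroClustering(assignments=assign, k=1, method={})
        data = sub.data.copy()
        data["c0"] = 2.5
        prof = aggregate_medians(mc, sub.copy_with(data), min_support=1)
        assert prof.medians.loc[0, "c0"] == 2.5
        assert prof.support.loc[0, "c0"] == 40

    @pytest.mark.parametrize(
        "values, expected",
        [([1.0, 2.0, 9.0], 2.0), ([1.0, 2.0, 3.0, 9.0], 2.0), ([5.0], 5.0)],
    )
    def test_lower_median_convention(self, values, expected):
        assert _lower_median(np.array(values)) == expected

    def test_empty_panel_support_is_missing(self, small_design):
        # cluster whose cells are all on panel pA: sB0 has support 0
        df = pd.DataFrame(
            {
                "donor_id": "d1",
                "panel_id": "pA",
                "c0": 1.0, "c1": 1.0, "c2": 1.0,
                "sA0": 2.0, "sA1": 3.0,
                "sB0": np.nan, "sB1": np.nan,
            },
            index=pd.Index([f"c{i}" for i in range(6)], name="cell_id"),
        )
        table = ExpressionTable(df, small_design)
        from cytostitch.integrate import MicroClustering

        mc = MicroClustering(
            assignments=pd.Series(0, index=table.cell_ids), k=1, method={}
        )
        prof = aggregate_medians(mc, table, min_support=1)
        assert prof.support.loc[0, "sB0"] == 0
        assert np.isnan(prof.medians.loc[0, "sB0"])

    def test_min_support_flags_thin_entries(self, small_design):
        df = pd.DataFrame(
            {
                "donor_id": "d1",
                "panel_id": ["pA"] * 3 + ["pB"] * 7,
                "c0": 1.0, "c1": 1.0, "c2": 1.0,
                "sA0": [2.0] * 3 + [np.nan] * 7,
                "sA1": [2.0] * 3 + [np.nan] * 7,
                "sB0": [np.nan] * 3 + [4.0] * 7,
                "sB1": [np.nan] * 3 + [4.0] * 7,
            },
            index=pd.Index([f"c{i}" for i in range(10)], name="cell_id"),
        )
        table = ExpressionTable(df, small_design)
        from cytostitch.integrate import MicroClustering

        mc = MicroClustering(
            assignments=pd.Series(0, index=table.cell_ids), k=1, method={}
        )
        prof = aggregate_medians(mc, table, min_support=5)
        assert np.isnan(prof.medians.loc[0, "sA0"])  # support 3 < 5
        assert prof.medians.loc[0, "sB0"] == 4.0  # support 7 >= 5


def block_profile(n_blocks: int, per_block: int, spread: float = 0.01) -> ClusterProfile:
    rng = np.random.default_rng(0)
    centers = np.arange(n_blocks)[:, None] * 10.0 + np.zeros((1, 4))
    rows = np.concatenate(
        [c + rng.normal(0, spread, size=(per_block, 4)) for c in centers]
    )
    med = pd.DataFrame(rows, columns=[f"m{i}" for i in range(4)])
    supp = pd.DataFrame(
        np.full(med.shape, 20, dtype=int), index=med.index, columns=med.columns
    )
    sizes = pd.Series(20, index=med.index)
    donors = pd.DataFrame({"d1": sizes})
    return ClusterProfile(med, supp, sizes, donors, min_support=5)


class TestMetaCluster:
    def test_two_separated_blocks(self):
        prof = block_profile(2, 12)
        meta = meta_cluster(prof, k_neighbors=5, resolution=1.0, seed=0)
        assert meta.n_meta == 2

    def test_resolution_limit_single_community(self):
        prof = block_profile(1, 20, spread=1.0)
        meta = meta_cluster(prof, k_neighbors=19, resolution=1e-4, seed=0)
        assert meta.n_meta == 1

    def test_k_neighbors_bound(self):
        prof = block_profile(2, 5)
        with pytest.raises(ParameterError):
            meta_cluster(prof, k_neighbors=10, seed=0)

    def test_recovery_on_simulated_screen(self, medium_screen):
        cfg, table, truth = medium_screen
        from cytostitch import percentile_normalize

        norm, _ = percentile_normalize(table)
        mc = micro_cluster(norm, cfg.panel_design.conserved_markers, k=60, seed=6)
        prof = aggregate_medians(mc, norm, min_support=3)
        meta = meta_cluster(prof, k_neighbors=10, resolution=1.0, seed=7)
        cells = meta.cell_labels(mc)
        _, ari = confusion_matrix(cells, truth.labels)
        assert ari >= 0.9


def pair_counting_ari(a, b) -> float:
    """Brute-force adjusted Rand index by pair enumeration."""
    a, b = list(a), list(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        ss += same_a and same_b
        sd += same_a and not same_b
        ds += not same_a and same_b
        dd += not same_a and not same_b
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


class TestConfusionMatrix:
    def _series(self, labels):
        return pd.Series(labels, index=[f"c{i}" for i in range(len(labels))])

    def test_identity_diagonal(self):
        a = self._series(["x", "x", "y", "z"])
        cm, ari = confusion_matrix(a, a)
        assert ari == 1.0
        assert (cm.to_numpy().sum(axis=1) == np.diag(cm)).all()

    def test_constant_labeling_chance_level(self):
        a = self._series(["x", "x", "y", "y"])
        b = self._series(["k"] * 4)
        _, ari = confusion_matrix(a, b)
        assert ari == 0.0

    def test_counts_and_pair_counting_oracle(self):
        a = self._series(["A", "A", "B", "B"])
        b = self._series(["X", "X", "X", "Y"])
        cm, ari = confusion_matrix(a, b)
        assert cm.loc["A", "X"] == 2 and cm.loc["A", "Y"] == 0
        assert cm.loc["B", "X"] == 1 and cm.loc["B", "Y"] == 1
        assert ari == pytest.approx(pair_counting_ari(a, b))

    def test_row_normalization(self):
        a = self._series(["A", "A", "B", "B"])
        b = self._series(["X", "X", "X", "Y"])
        cm, _ = confusion_matrix(a, b, normalize="row")
        assert np.allclose(cm.sum(axis=1), 1.0)

    def test_mismatched_universe_rejected(self):
        a = self._series(["A", "B"])
        b = pd.Series(["A", "B"], index=["q1", "q2"])
        with pytest.raises(InputError):
            confusion_matrix(a, b)


class TestStitchingStructure:
    def test_agreement_when_screen_markers_uninformative(self):
        """Conserved-only and stitched meta-clustering agree when screen
        markers carry no population structure."""
        from cytostitch import percentile_normalize

        cfg = well_separated_screen_config(
            n_populations=3, n_cells=6000, n_panels=4, n_conserved=7,
            screen_per_panel=3, informative_per_population=0, seed=21,
        )
        table, _ = simulate_screen(cfg)
        norm, _ = percentile_normalize(table)
        mc = micro_cluster(norm, cfg.panel_design.conserved_markers, k=50, seed=22)
        prof = aggregate_medians(mc, norm, min_support=3)
        meta_cons = meta_cluster(
            prof, markers=cfg.panel_design.conserved_markers,
            k_neighbors=10, resolution=0.5, seed=23,
        )
        meta_all = meta_cluster(prof, k_neighbors=10, resolution=0.5, seed=23)
        _, ari = confusion_matrix(meta_cons.labels, meta_all.labels)
        assert ari >= 0.8

    def test_screen_marker_splits_population_only_when_stitched(self):
        """A screen marker dividing one population (along a weak conserved
        gradient micro-clusters can sort on) adds a meta-cluster in the
        stitched run; the conserved-only run merges the two halves."""
        from cytostitch import percentile_normalize
        from cytostitch.synth import MarkerModel, SynthConfig

        design = PanelDesign(
            conserved_markers=[f"core{i}" for i in range(7)],
            panels={"p0": ["split0"], "p1": ["noise0"]},
        )
        hot = MarkerModel(0.95, 4.5, 0.5, 0.3, 0.2)
        cold = MarkerModel(0.02, 4.5, 0.5, 0.3, 0.2)
        flat = MarkerModel(0.3, 3.0, 0.6, 0.3, 0.25)

        def a_models(core5_mean: float, split: MarkerModel) -> dict:
            per = {f"core{i}": (hot if i in {0, 1, 6} else cold) for i in range(7)}
            per["core5"] = MarkerModel(1.0, core5_mean, 0.5, 0.3, 0.2)
            per["split0"] = split
            per["noise0"] = flat
            return per

        # A1/A2 share the binary conserved signature; only a mild graded
        # core5 shift (2.2 vs 2.8, sd 0.5) separates them there, while
        # split0 is fully on in A1 and off in A2
        pops = {"popA1": a_models(2.2, hot), "popA2": a_models(2.8, cold)}
        for name, sig in [("popB", {2, 3}), ("popC", {4, 5})]:
            per = {f"core{i}": (hot if i in sig or i == 6 else cold) for i in range(7)}
            per["split0"] = flat
            per["noise0"] = flat
            pops[name] = per
        cfg = SynthConfig(
            n_populations=4,
            population_proportions=[0.3, 0.3, 0.2, 0.2],
            n_cells=8000,
            n_donors=2,
            panel_design=design,
            marker_models=pops,
            seed=11,
        )
        table, truth = simulate_screen(cfg)
        norm, _ = percentile_normalize(table)
        mc = micro_cluster(norm, design.conserved_markers, k=60, seed=12)
        prof = aggregate_medians(mc, norm, min_support=5)
        meta_cons = meta_cluster(
            prof, markers=design.conserved_markers,
            k_neighbors=10, resolution=0.5, seed=13,
        )
        meta_all = meta_cluster(prof, k_neighbors=10, resolution=0.5, seed=13)
        merged = truth.labels.replace({"popA1": "popA", "popA2": "popA"})
        _, ari_merged = confusion_matrix(meta_cons.cell_labels(mc), merged)
        assert meta_cons.n_meta == 3  # A halves merge without the screen marker
        assert ari_merged >= 0.9
        assert meta_all.n_meta >= meta_cons.n_meta + 1
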