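"""Stitch K staining panels into one cluster-level co-expression landscape.

Cells from all panels are first grouped into many small micro-clusters
using only the conserved markers (measured on every cell).  Because each
micro-cluster contains cells from every panel, it has measurements for
every screen marker through some of its members: taking the per-cluster
median of each marker "bridges" markers that were never measured on the
same cell.  The resulting micro-cluster x marker median matrix is the
stitched landscape; community detection on its k-nearest-neighbor graph
yields the meta-clusters that play the role of cell populations.

The micro-clusterer is either a self-organizing map (a g x g rectangular
grid of code vectors trained with a shrinking Gaussian neighborhood, the
FlowSOM-style choice) or plain k-means.  Both operate on the conserved
markers only and are deterministic for a fixed seed; cells are sorted by
cell_id internally so input order is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.pairwise import nan_euclidean_distances

from .core import ExpressionTable, InputError, ParameterError

__all__ = [
    "MicroClustering",
    "ClusterProfile",
    "MetaClustering",
    "micro_cluster",
    "aggregate_medians",
    "meta_cluster",
    "confusion_matrix",
]


@dataclass
class MicroClustering:
    """Cell -> micro-cluster assignment with method metadata."""

    assignments: pd.Series  # index cell_id -> int in 0..k-1
    k: int
    method: dict

    def __post_init__(self) -> None:
        if self.assignments.isna().any():
            raise InputError("every cell must be assigned a micro-cluster")
        sizes = self.assignments.value_counts()
        if (sizes < 1).any() or len(sizes) != self.k:
            raise InputError("micro-cluster sizes must all be >= 1")


@dataclass
class ClusterProfile:
    """Micro-cluster x marker median matrix with per-entry support counts.

    ``medians[k, m]`` is the median expression of marker m over the cells
    of cluster k on panels measuring m; entries whose support is below
    ``min_support`` are NaN (missing).  Conserved markers always have
    support equal to the cluster size.
    """

    medians: pd.DataFrame  # index cluster -> columns markers
    support: pd.DataFrame  # same shape, int counts
    cluster_sizes: pd.Series
    donor_composition: pd.DataFrame  # cluster x donor counts
    min_support: int

    def __post_init__(self) -> None:
        if not self.medians.index.equals(self.support.index) or not (
            self.medians.columns.equals(self.support.columns)
        ):
            raise InputError("medians and support must be aligned")
        over = self.support.to_numpy() > self.cluster_sizes.to_numpy()[:, None]
        if over.any():
            raise InputError("support cannot exceed cluster size")

    @property
    def markers(self) -> list[str]:
        return list(self.medians.columns)


@dataclass
class MetaClustering:
    """Micro-cluster -> meta-cluster community labels."""

    labels: pd.Series  # index micro-cluster -> int meta label
    params: dict

    @property
    def n_meta(self) -> int:
        return int(self.labels.nunique())

    def cell_labels(self, clustering: MicroClustering) -> pd.Series:
        """Propagate meta labels from micro-clusters down to cells."""
        return clustering.assignments.map(self.labels).rename("meta")


# ---------------------------------------------------------------------------
# Micro-clustering


def _train_som(
    x: np.ndarray, grid: int, rng: np.random.Generator, epochs: int = 20
) -> np.ndarray:
    """Batch-train a grid x grid SOM; returns the (grid^2, d) codebook.

    Codebook initialized from random data samples; each epoch assigns
    every point to its best-matching unit and moves code vectors toward
    the neighborhood-weighted mean, with the Gaussian neighborhood radius
    shrinking from grid/2 to 0.5.
    """
    n_nodes = grid * grid
    codebook = x[rng.choice(len(x), size=n_nodes, replace=len(x) < n_nodes)].copy()
    gx, gy = np.divmod(np.arange(n_nodes), grid)
    grid_d2 = (gx[:, None] - gx[None, :]) ** 2 + (gy[:, None] - gy[None, :]) ** 2
    radii = np.geomspace(grid / 2.0, 0.5, epochs)
    x_sq = (x**2).sum(1)[:, None]
    for sigma in radii:
        d2 = x_sq + (codebook**2).sum(1)[None, :] - 2.0 * (x @ codebook.T)
        bmu = d2.argmin(1)
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # (node, node)
        w = h[bmu]  # (cell, node) neighborhood weight
        denom = w.sum(0)
        nonzero = denom > 1e-12
        codebook[nonzero] = (w.T @ x)[nonzero] / denom[nonzero, None]
    return codebook


def micro_cluster(
    table: ExpressionTable,
    markers: Sequence[str],
    k: int = 400,
    algorithm: str = "som",
    seed: int = 0,
) -> MicroClustering:
    """Partition cells into k micro-clusters on the given (conserved) markers.

    SOM: a ceil(sqrt(k))-sided rectangular grid is trained, cells map to
    their best-matching unit, empty nodes are dropped and, if more than k
    nodes remain non-empty, the smallest are merged into their nearest
    surviving code vector until exactly k clusters remain.  K-means: plain
    Lloyd's with k centers.  Deterministic for fixed seed and invariant to
    cell order.
    """
    if k >= table.n_cells:
        raise ParameterError(f"k={k} must be < n_cells={table.n_cells}")
    mask = table.measured_mask
    for m in markers:
        if m not in table.data.columns or not mask[m].all():
            raise InputError(f"marker {m!r} must be measured for every cell")
    data = table.data.sort_index()
    x = data[list(markers)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(x)
        labels = km.labels_
        meta = {"algorithm": "kmeans", "k": k, "seed": seed}
    elif algorithm == "som":
        grid = int(np.ceil(np.sqrt(k)))
        # subsample training set for speed on large tables; assignment
        # below still uses every cell
        train = x if len(x) <= 20000 else x[rng.choice(len(x), 20000, replace=False)]
        codebook = _train_som(train, grid, rng)
        labels = _assign_codebook(x, codebook)
        labels, codebook = _trim_merge(labels, codebook, k, x)
        meta = {"algorithm": "som", "grid": grid, "k": k, "seed": seed}
    else:
        raise ParameterError(f"unknown algorithm {algorithm!r}")

    labels = _relabel_compact(labels)
    assignments = pd.Series(labels, index=data.index, name="micro").reindex(
        table.cell_ids
    )
    return MicroClustering(
        assignments=assignments, k=int(assignments.nunique()), method=meta
    )


def _assign_codebook(x: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    out = np.empty(len(x), dtype=int)
    step = 65536
    c_sq = (codebook**2).sum(1)[None, :]
    for i in range(0, len(x), step):
        chunk = x[i : i + step]
        d2 = (chunk**2).sum(1)[:, None] + c_sq - 2.0 * (chunk @ codebook.T)
        out[i : i + step] = d2.argmin(1)
    return out


def _trim_merge(
    labels: np.ndarray, codebook: np.ndarray, k: int, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop empty SOM nodes; merge smallest clusters until at most k remain."""
    while True:
        occupied, counts = np.unique(labels, return_counts=True)
        if len(occupied) <= k:
            return labels, codebook
        victim = occupied[np.argmin(counts)]
        others = occupied[occupied != victim]
        d2 = ((codebook[others] - codebook[victim]) ** 2).sum(1)
        target = others[np.argmin(d2)]
        labels = np.where(labels == victim, target, labels)


def _relabel_compact(labels: np.ndarray) -> np.ndarray:
    """Renumber labels to 0..K-1 in order of first node index."""
    uniq = np.unique(labels)
    lut = np.full(uniq.max() + 1, -1, dtype=int)
    lut[uniq] = np.arange(len(uniq))
    return lut[labels]


# ---------------------------------------------------------------------------
# Median bridging


def aggregate_medians(
    clustering: MicroClustering, table: ExpressionTable, min_support: int = 5
) -> ClusterProfile:
    """Per-cluster, per-marker medians over measured cells.

    The median uses the lower-of-two-middles convention for even counts
    so stitched values are always observed intensities.  Entries with
    fewer than ``min_support`` measured cells are recorded missing (NaN)
    rather than estimated from a thin sample.
    """
    if not clustering.assignments.index.equals(table.cell_ids):
        missing = table.cell_ids.difference(clustering.assignments.index)
        if len(missing):
            raise InputError("clustering does not cover all cells in the table")
    assign = clustering.assignments.loc[table.cell_ids]
    clusters = np.sort(assign.unique())
    markers = table.markers
    medians = np.full((len(clusters), len(markers)), np.nan)
    support = np.zeros((len(clusters), len(markers)), dtype=int)
    grouped = table.data.groupby(assign)
    for ci, (_, sub) in enumerate(grouped):
        for mj, marker in enumerate(markers):
            vals = sub[marker].dropna().to_numpy()
            support[ci, mj] = vals.size
            if vals.size >= max(min_support, 1):
                medians[ci, mj] = _lower_median(vals)
    sizes = assign.value_counts().sort_index()
    donors = pd.crosstab(assign, table.data["donor_id"])
    return ClusterProfile(
        medians=pd.DataFrame(medians, index=clusters, columns=markers),
        support=pd.DataFrame(support, index=clusters, columns=markers),
        cluster_sizes=sizes,
        donor_composition=donors,
        min_support=min_support,
    )


def _lower_median(values: np.ndarray) -> float:
    """Lower middle order statistic (an observed value even for even n)."""
    v = np.sort(values)
    return float(v[(len(v) - 1) // 2])


# ---------------------------------------------------------------------------
# Meta-clustering


def meta_cluster(
    profile: ClusterProfile,
    markers: Sequence[str] | None = None,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    missing: str = "pairwise",
) -> MetaClustering:
    """Leiden communities on the kNN graph of micro-cluster median vectors.

    Distances are Euclidean over the chosen markers.  Missing stitched
    entries (a cluster too thin on some panel) are handled by
    ``missing``: the default "pairwise" uses pairwise-complete (NaN-aware)
    Euclidean distances, so no stitched value is ever fabricated;
    "drop" instead discards every marker that has any missing entry.
    Neighbor ties break by cluster index so the graph is reproducible
    across library versions.
    """
    med = profile.medians if markers is None else profile.medians[list(markers)]
    n = len(med)
    if k_neighbors >= n:
        raise ParameterError(f"k_neighbors={k_neighbors} must be < {n} micro-clusters")
    if missing == "drop":
        complete = med.columns[med.notna().all(axis=0)]
        if len(complete) == 0:
            raise InputError("no marker is complete across all micro-clusters")
        x = med[complete].to_numpy(dtype=float)
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        used = list(complete)
    elif missing == "pairwise":
        d = nan_euclidean_distances(med.to_numpy(dtype=float))
        used = list(med.columns)
    else:
        raise ParameterError(f"unknown missing policy {missing!r}")

    # stable kNN: sort by (distance, index), skip self
    np.fill_diagonal(d, np.inf)
    order = np.lexsort((np.arange(n)[None, :].repeat(n, 0), d), axis=1)
    edges = set()
    for i in range(n):
        for j in order[i, :k_neighbors]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = ig.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = pd.Series(part.membership, index=med.index, name="meta")
    return MetaClustering(
        labels=labels,
        params={
            "k_neighbors": k_neighbors,
            "resolution": resolution,
            "seed": seed,
            "missing": missing,
            "markers_used": used,
        },
    )


# ---------------------------------------------------------------------------
# Partition comparison


def confusion_matrix(
    labels_a: pd.Series, labels_b: pd.Series, normalize: str = "none"
) -> tuple[pd.DataFrame, float]:
    """Co-assignment counts between two labelings plus the adjusted Rand index.

    Accepts any two label series over the same universe (cells or
    micro-clusters).  ``normalize="row"`` scales each row to sum to 1.
    """
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise InputError("labelings cover different universes")
    b = b.loc[a.index]
    counts = pd.crosstab(a, b)
    ari = float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
    if normalize == "row":
        counts = counts.div(counts.sum(axis=1), axis=0)
    elif normalize != "none":
        raise ParameterError(f"unknown normalize {normalize!r}")
    return counts, ari


def _as_labels(obj) -> pd.Series:
    if isinstance(obj, pd.Series):
        return obj
    if isinstance(obj, MetaClustering):
        return obj.labels
    if isinstance(obj, MicroClustering):
        return obj.assignments
    if hasattr(obj, "labels"):
        return obj.labels
    raise InputError(f"cannot interpret {type(obj).__name__} as a labeling")
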