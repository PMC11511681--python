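"""Community-detection sub-clustering of cell populations.

Cells are embedded with PCA (first 10 components by default), joined into a
k-nearest-neighbour graph and partitioned with the Leiden algorithm over a
grid of neighbourhood sizes k in {15..35} and resolutions r in {0.1..1.0}.
Each grid point's robustness is measured by the average Variation of
Information against re-clusterings on random half-gene subsamples, and
clusters without at least two *specific* markers (expressed above 0.01 and
significantly upregulated in every pairwise comparison) are merged into
their nearest neighbour in PC space.  A supervised signature-based split is
provided for stages where the unsupervised grid finds a single cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from .clustering import (bh_adjust, log2_fold_changes, ranksum_test,
                         variation_of_information)
from .expression import ExpressionMatrix, feature_positions

GRID_KS = (15, 20, 25, 30, 35)
GRID_RESOLUTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


def pca_embed(values: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Deterministic PCA embedding (randomized SVD, sign-fixed)."""
    from sklearn.decomposition import PCA

    n_pcs = min(n_pcs, min(values.shape) - 1)
    p = PCA(n_components=n_pcs, svd_solver="randomized",
            random_state=seed, iterated_power=7)
    pcs = p.fit_transform(values)
    # fix signs so the largest-magnitude loading of each PC is positive
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(p.components_[j]))
        if p.components_[j, i] < 0:
            pcs[:, j] *= -1
    return pcs


@dataclass
class KnnGraph:
    """k-nearest-neighbour graph over a PC embedding."""

    pcs: np.ndarray
    neighbors: np.ndarray       # (n, k) neighbour indices
    distances: np.ndarray       # (n, k)
    k: int
    metric: str = "euclidean"

    @property
    def n_cells(self) -> int:
        return self.pcs.shape[0]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_cells, self.n_cells), dtype=bool)
        rows = np.repeat(np.arange(self.n_cells), self.k)
        a[rows, self.neighbors.ravel()] = True
        return a | a.T

    def to_igraph(self) -> ig.Graph:
        n = self.n_cells
        edges = set()
        for i in range(n):
            for j in self.neighbors[i]:
                edges.add((min(i, int(j)), max(i, int(j))))
        g = ig.Graph(n=n, edges=sorted(edges), directed=False)
        return g


def knn_graph(m, features=None, n_pcs: int = 10, k: int = 15,
              metric: str = "euclidean", seed: int = 0) -> KnnGraph:
    """PCA then kNN.

    ``metric="euclidean"`` (sub-clustering) takes Euclidean distance on the
    PCs; ``metric="spearman"`` (pseudotime usage) takes the Spearman
    correlation distance computed on the PC coordinates.
    """
    vals = m.values if hasattr(m, "values") else np.asarray(m, float)
    if features is not None and hasattr(m, "feature_ids"):
        vals = vals[:, feature_positions(m.feature_ids, features)]
    n = vals.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    pcs = pca_embed(vals, n_pcs, seed=seed)
    if metric == "euclidean":
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
        d, idx = nn.kneighbors(pcs)
        # drop self explicitly: with duplicate points self is not always
        # the first entry of the neighbour list
        keep_idx = np.empty((n, k), dtype=int)
        keep_d = np.empty((n, k))
        for i in range(n):
            cols = np.flatnonzero(idx[i] != i)[:k]
            if len(cols) < k:  # self appeared more than once is impossible;
                cols = np.r_[cols, [k]]  # pad with the last column
            keep_idx[i] = idx[i, cols]
            keep_d[i] = d[i, cols]
        return KnnGraph(pcs, keep_idx, keep_d, k, metric)
    elif metric == "spearman":
        from .clustering import _spearman_distance_from_values

        dist = _spearman_distance_from_values(pcs)
        np.fill_diagonal(dist, np.inf)
        idx = np.argsort(dist, axis=1, kind="stable")[:, :k]
        d = np.take_along_axis(dist, idx, axis=1)
        return KnnGraph(pcs, idx, d, k, metric)
    raise ValueError(f"unknown metric {metric!r}")


def community_detect(graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden community detection at the given resolution."""
    g = graph.to_igraph() if isinstance(graph, KnnGraph) else graph
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    return np.asarray(part.membership)


@dataclass(frozen=True)
class SpecificMarkerRule:
    """A gene is *specific* to a cluster when its mean log-normalized
    expression there exceeds ``min_mean_lognorm`` and it is significantly
    upregulated (BH-adjusted p < ``alpha``, positive log2FC) in every
    pairwise comparison with the other clusters."""

    min_mean_lognorm: float = 0.01
    alpha: float = 0.1


def count_specific_markers(m, partition,
                           rule: SpecificMarkerRule = SpecificMarkerRule()):
    """Specific marker genes per cluster.

    Returns ``(counts: dict, genes: dict)`` mapping cluster label to the
    number / list of specific genes.  A single-cluster partition yields an
    empty result.
    """
    labels = np.asarray(partition)
    clusters = list(pd.unique(labels))
    if len(clusters) < 2:
        return {}, {}
    masks = {c: labels == c for c in clusters}
    pair_p, pair_lfc = {}, {}
    for i, c in enumerate(clusters):
        for o in clusters[i + 1:]:
            p = ranksum_test(m.values[masks[c]], m.values[masks[o]],
                             method="asymptotic")
            pair_p[(c, o)] = bh_adjust(p)
            pair_lfc[(c, o)] = log2_fold_changes(m, masks[c], masks[o])
    counts, genes = {}, {}
    for c in clusters:
        mean_c = m.values[masks[c]].mean(axis=0)
        ok = mean_c > rule.min_mean_lognorm
        for o in clusters:
            if o == c:
                continue
            if (c, o) in pair_p:
                adj, lfc = pair_p[(c, o)], pair_lfc[(c, o)]
            else:
                adj, lfc = pair_p[(o, c)], -pair_lfc[(o, c)]
            ok &= (adj < rule.alpha) & (lfc > 0)
        genes[c] = list(np.asarray(m.feature_ids)[ok])
        counts[c] = int(ok.sum())
    return counts, genes


def cluster_centroids(pcs: np.ndarray, labels: np.ndarray) -> dict:
    return {c: pcs[labels == c].mean(axis=0) for c in pd.unique(labels)}


def merge_unsupported(m, partition, pcs,
                      rule: SpecificMarkerRule = SpecificMarkerRule(),
                      min_markers: int = 2):
    """Merge clusters lacking specific-marker support.

    Clusters with fewer than ``min_markers`` specific markers are merged
    into the Euclidean-nearest remaining cluster (centroids in PC space);
    marker counts are recomputed and the rule iterated until every cluster
    is supported or a single cluster remains.  Terminates because the
    cluster count strictly decreases each iteration.

    Returns ``(partition, counts)``.
    """
    labels = np.asarray(partition).copy()
    while True:
        counts, _ = count_specific_markers(m, labels, rule)
        if not counts:  # single cluster
            return labels, counts
        weak = [c for c, n in counts.items() if n < min_markers]
        if not weak:
            return labels, counts
        cents = cluster_centroids(pcs, labels)
        c = weak[0]
        others = [o for o in cents if o != c]
        d = [np.linalg.norm(cents[c] - cents[o]) for o in others]
        labels[labels == c] = others[int(np.argmin(d))]
        if len(pd.unique(labels)) == 1:
            return labels, {}


@dataclass
class SubclusterGridResult:
    """Grid of (k, resolution) Leiden partitions with VI robustness and
    post-merge marker support."""

    grid: pd.DataFrame = field(repr=False)   # k, r, n_clusters, avg_vi, ...
    partitions: dict = field(repr=False)     # (k, r) -> pre-merge labels
    merged_partitions: dict = field(repr=False)
    marker_counts: dict = field(repr=False)
    selected: tuple = None                   # (k, r) or None = single cluster

    @property
    def selected_partition(self) -> np.ndarray:
        if self.selected is None:
            n = len(next(iter(self.partitions.values())))
            return np.zeros(n, dtype=int)
        return self.merged_partitions[self.selected]


def grid_subcluster(m, features, ks=GRID_KS, resolutions=GRID_RESOLUTIONS,
                    n_pcs: int = 10, n_subsamples: int = 50,
                    subsample_fraction: float = 0.5,
                    rule: SpecificMarkerRule = SpecificMarkerRule(),
                    vi_threshold: float = 0.5,
                    seed: int = 0) -> SubclusterGridResult:
    """Evaluate the full (k, r) grid and select the most robust partition.

    Robustness per grid point = average VI between the full-gene partition
    and partitions from ``n_subsamples`` random half-gene subsamples
    (PCA + kNN + Leiden recomputed per subsample).  After merging
    marker-unsupported clusters, the selected partition is the one with the
    lowest average VI among multi-cluster results (ties -> fewer clusters),
    provided that VI stays below ``vi_threshold``: a split whose average VI
    approaches ln 2 (the information cost of losing a 2-way split outright)
    is not reproducible and is rejected.  If no multi-cluster grid point
    qualifies, a single cluster is returned.
    """
    vals = m.values[:, feature_positions(m.feature_ids, features)]
    n = vals.shape[0]
    kmax = max(ks)
    if kmax >= n:
        raise ValueError("largest k must be smaller than the number of cells")

    full = knn_graph(vals, n_pcs=n_pcs, k=kmax, seed=seed)
    partitions, merged, counts_by_point = {}, {}, {}
    for k in ks:
        gk = KnnGraph(full.pcs, full.neighbors[:, :k], full.distances[:, :k], k)
        g_ig = gk.to_igraph()
        for r in resolutions:
            partitions[(k, float(r))] = community_detect(g_ig, r, seed=seed)

    # robustness: one PCA/kNN per gene subsample, reused across the grid
    vi_sum = {key: 0.0 for key in partitions}
    n_feat = vals.shape[1]
    n_keep = max(2, int(round(subsample_fraction * n_feat)))
    for s in range(n_subsamples):
        rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
        keep = rng.choice(n_feat, size=n_keep, replace=False)
        sub = knn_graph(vals[:, keep], n_pcs=n_pcs, k=kmax, seed=seed)
        for k in ks:
            gk = KnnGraph(sub.pcs, sub.neighbors[:, :k],
                          sub.distances[:, :k], k)
            g_ig = gk.to_igraph()
            for r in resolutions:
                lab = community_detect(g_ig, r, seed=seed)
                key = (k, float(r))
                vi_sum[key] += variation_of_information(partitions[key], lab)

    sub_m = ExpressionMatrix(vals, m.cell_ids,
                             np.asarray(m.feature_ids)[
                                 feature_positions(m.feature_ids, features)],
                             layer="lognorm")
    rows = []
    # merge once per distinct pre-merge partition (grid points often repeat)
    merge_cache = {}
    for key, lab in partitions.items():
        fp = tuple(lab)
        if fp not in merge_cache:
            merge_cache[fp] = merge_unsupported(sub_m, lab, full.pcs, rule)
        mlab, mcounts = merge_cache[fp]
        merged[key] = mlab
        counts_by_point[key] = mcounts
        rows.append({"k": key[0], "r": key[1],
                     "n_clusters": len(pd.unique(lab)),
                     "n_clusters_merged": len(pd.unique(mlab)),
                     "avg_vi": vi_sum[key] / max(1, n_subsamples)})
    grid = pd.DataFrame(rows)

    multi = grid[(grid["n_clusters_merged"] > 1)
                 & (grid["avg_vi"] < vi_threshold)]
    if len(multi) == 0:
        selected = None
    else:
        best = multi.sort_values(["avg_vi", "n_clusters_merged", "k", "r"],
                                 kind="stable").iloc[0]
        selected = (int(best["k"]), float(best["r"]))
    return SubclusterGridResult(grid, partitions, merged, counts_by_point,
                                selected)


def signature_split(m, signature_genes, k: int = 15, n_pcs: int = 10,
                    target_clusters: int | None = 2,
                    resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Split cells on a supervised gene signature.

    Builds a kNN graph from the signature genes only and runs Leiden.  When
    ``target_clusters`` is given, the resolution is scanned upward from 0.05
    and the first partition reaching the target is returned (mirroring the
    fix-the-resolution-to-get-two-clusters procedure); otherwise the fixed
    ``resolution`` is used.  A signature with no variance yields a single
    cluster.
    """
    sig = list(signature_genes)
    if len(sig) == 0:
        raise ValueError("signature must contain at least one gene")
    vals = m.values[:, feature_positions(m.feature_ids, sig)]
    if np.allclose(vals.var(axis=0), 0):
        return np.zeros(m.n_cells, dtype=int)
    g = knn_graph(vals, n_pcs=min(n_pcs, len(sig)), k=k, seed=seed)
    g_ig = g.to_igraph()
    if target_clusters is None:
        return community_detect(g_ig, resolution, seed=seed)
    for r in np.arange(0.05, 2.01, 0.05):
        lab = community_detect(g_ig, float(r), seed=seed)
        if len(pd.unique(lab)) >= target_clusters:
            return lab
    warnings.warn("target cluster count not reached; returning the "
                  "highest-resolution partition")
    return lab
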