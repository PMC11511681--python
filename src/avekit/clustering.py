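"""Hierarchical cell clustering with information-theoretic model selection.

Cells are compared with the Spearman correlation distance ``(1 - rho)/2``
over a highly-variable-gene set, clustered by average-linkage hierarchical
clustering, and the dendrogram is cut with a deepsplit-indexed family of
increasingly aggressive cuts (deepsplit 0..4).  The number of clusters is
chosen by scanning the average Variation of Information (VI) between the
full-gene partition and partitions recomputed on random half-gene
subsamples: the chosen deepsplit is the last one before the VI curve
'kicks' upward (argmax of the forward difference).

Also provided: a PAM (partitioning around medoids) split for refining a
cluster, k-nearest-neighbour distance outlier flagging, and pairwise
Wilcoxon marker ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: dendrogram-height quantiles indexed by deepsplit 0..4
DEEPSPLIT_QUANTILES = (0.99, 0.95, 0.90, 0.80, 0.70)


# ---------------------------------------------------------------- distances

def spearman_distance(m, features=None) -> np.ndarray:
    """Cell-cell Spearman correlation distance ``d = (1 - rho) / 2``.

    Ties are handled by midranks.  A constant cell has undefined rho; its
    off-diagonal distances are set to 0.5 (uninformative) and logged.
    """
    vals = m.values if hasattr(m, "values") else np.asarray(m, float)
    if features is not None and hasattr(m, "feature_ids"):
        from .expression import feature_positions
        vals = vals[:, feature_positions(m.feature_ids, features)]
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 features")
    return _spearman_distance_from_values(vals)


def _spearman_distance_from_values(vals: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(vals, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant cell(s): distance set to 0.5",
                       int(constant.sum()))
        sd = np.where(constant, 1.0, sd)
    z = (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]
    rho = z @ z.T / ranks.shape[1]
    rho = np.clip(rho, -1.0, 1.0)
    d = (1.0 - rho) / 2.0
    if constant.any():
        d[constant, :] = 0.5
        d[:, constant] = 0.5
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


# ------------------------------------------------- variation of information

def variation_of_information(p1, p2) -> float:
    """VI = H(p1) + H(p2) - 2 I(p1; p2), in nats.

    A metric on the space of partitions of the same element set.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must label the same element set")
    n = len(p1)
    joint = pd.crosstab(p1, p2).to_numpy() / n
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)

    def h(p):
        p = p[p > 0]
        return -np.sum(p * np.log(p))

    hij = h(joint.ravel())
    return float(max(0.0, 2.0 * hij - h(pi) - h(pj)))


# ------------------------------------------------------- dendrogram cutting

#: hybrid-cut acceptance leniency per deepsplit: maximum core scatter as a
#: fraction of the dendrogram height range (minimum gap is 3/4 of the rest)
DEEPSPLIT_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


def hierarchical_partition(dist: np.ndarray, deepsplit: int,
                           min_size: int = 10, linkage=None) -> np.ndarray:
    """Hybrid dendrogram cut indexed by deepsplit 0..4.

    Average-linkage tree; candidate clusters come from a static cut at the
    ``DEEPSPLIT_QUANTILES[deepsplit]`` quantile of the merge heights (higher
    deepsplit = lower cut = more candidates).  A candidate is *accepted*
    only if it is large enough and cleanly separated: its core scatter
    (mean merge height inside its subtree) must stay below a
    deepsplit-dependent ceiling and the gap up to its attachment height
    must exceed 3/4 of what remains of the height range — homogeneous data
    therefore yield a single cluster at every deepsplit.  Members of
    rejected candidates are absorbed into the nearest accepted cluster by
    average inter-cluster distance.
    """
    z = linkage if linkage is not None else hierarchy.linkage(
        squareform(dist, checks=False), method="average")
    return _hybrid_cut(dist, z, deepsplit, min_size)


def _hybrid_cut(dist, z, deepsplit, min_size) -> np.ndarray:
    heights = z[:, 2]
    cut = np.quantile(heights, DEEPSPLIT_QUANTILES[deepsplit])
    labels = hierarchy.fcluster(z, t=cut, criterion="distance")
    n = len(labels)
    ids = np.unique(labels)
    if len(ids) == 1:
        return np.zeros(n, dtype=int)

    hmin, hmax = heights.min(), heights.max()
    span = max(hmax - hmin, 1e-12)
    frac = DEEPSPLIT_MAX_CORE_SCATTER[deepsplit]
    max_scatter = hmin + frac * span
    min_gap = 0.75 * (1.0 - frac) * span

    # every fcluster cluster is a maximal subtree below the cut: walk the
    # linkage to get each subtree's internal merge heights and the height
    # at which it attaches to the rest of the tree; stray subtrees smaller
    # than min_size joining a labelled cluster are absorbed so that an
    # outlier cell does not masquerade as the cluster's attachment point
    node_label = list(labels - 0)  # leaves first, merge nodes appended
    node_count = [1] * n
    internal = {c: [] for c in ids}
    attach = {c: hmax for c in ids}
    for k in range(z.shape[0]):
        a, b = int(z[k, 0]), int(z[k, 1])
        la, lb = node_label[a], node_label[b]
        ca, cb = node_count[a], node_count[b]
        node_count.append(ca + cb)
        if la is not None and la == lb:
            node_label.append(la)
            internal[la].append(heights[k])
        elif la is not None and ca >= min_size and cb < min_size:
            node_label.append(la)
            if lb is not None:
                attach[lb] = min(attach[lb], heights[k])
        elif lb is not None and cb >= min_size and ca < min_size:
            node_label.append(lb)
            if la is not None:
                attach[la] = min(attach[la], heights[k])
        else:
            node_label.append(None)
            for child in (la, lb):
                if child is not None:
                    attach[child] = min(attach[child], heights[k])

    accepted = []
    for c in ids:
        if (labels == c).sum() < min_size:
            continue
        scatter = float(np.mean(internal[c])) if internal[c] else hmin
        if scatter <= max_scatter and attach[c] - scatter >= min_gap:
            accepted.append(c)
    if not accepted:
        return np.zeros(n, dtype=int)
    out = labels.copy()
    for c in ids:
        if c in accepted:
            continue
        members = out == c
        avg = [dist[np.ix_(members, labels == r)].mean() for r in accepted]
        out[members] = accepted[int(np.argmin(avg))]
    _, relabeled = np.unique(out, return_inverse=True)
    return relabeled


@dataclass
class ClusterModelSelection:
    """Per-deepsplit partitions and their gene-subsampling VI robustness."""

    deepsplit_values: list
    partitions: dict            # deepsplit -> labels
    avg_vi: dict                # deepsplit -> mean VI over subsamples
    chosen_deepsplit: int
    min_cluster_size: int = 10

    @property
    def chosen_partition(self) -> np.ndarray:
        return self.partitions[self.chosen_deepsplit]


def choose_deepsplit_by_kick(avg_vi: dict, rel_threshold: float = 0.25) -> int:
    """Elbow rule on the VI robustness curve.

    The 'kick' is where the curve first leaves its low plateau: the first
    deepsplit whose average VI exceeds the curve minimum by more than
    ``rel_threshold`` of the curve's range.  The chosen deepsplit is the
    largest one before that point.  A flat curve has no kick and the
    smallest (most conservative) deepsplit is returned.
    """
    ds = sorted(avg_vi)
    vals = np.array([avg_vi[d] for d in ds])
    lo, hi = vals.min(), vals.max()
    if hi - lo <= 1e-12:
        return ds[0]
    thr = lo + rel_threshold * (hi - lo)
    above = np.flatnonzero(vals > thr)
    if len(above) == 0 or above[0] == 0:
        return ds[0]
    return ds[above[0] - 1]


def cluster_with_vi_selection(m, features, deepsplits=range(5),
                              n_subsamples: int = 50,
                              subsample_fraction: float = 0.5,
                              min_size: int = 10,
                              seed: int = 0) -> ClusterModelSelection:
    """Cluster cells and select the deepsplit by VI robustness.

    For each deepsplit the full-gene partition is compared (by VI) with
    partitions recomputed on ``n_subsamples`` random subsets of
    ``subsample_fraction`` of the genes; the deepsplit is chosen by the
    kick rule on the averaged VI curve.  Each subsample draws from its own
    seed stream, so results are invariant to evaluation order.
    """
    from .expression import feature_positions

    deepsplits = list(deepsplits)
    vals = m.values[:, feature_positions(m.feature_ids, features)]
    n = vals.shape[0]
    if n < 2 * min_size:
        warnings.warn("too few cells for model selection; single cluster")
        part = np.zeros(n, dtype=int)
        return ClusterModelSelection(deepsplits, {d: part for d in deepsplits},
                                     {d: 0.0 for d in deepsplits},
                                     deepsplits[0], min_size)

    dist = _spearman_distance_from_values(vals)
    z_full = hierarchy.linkage(squareform(dist, checks=False),
                               method="average")
    partitions = {d: _hybrid_cut(dist, z_full, d, min_size)
                  for d in deepsplits}

    vi_sum = {d: 0.0 for d in deepsplits}
    n_feat = vals.shape[1]
    n_keep = max(2, int(round(subsample_fraction * n_feat)))
    for s in range(n_subsamples):
        rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
        keep = rng.choice(n_feat, size=n_keep, replace=False)
        dist_s = _spearman_distance_from_values(vals[:, keep])
        z = hierarchy.linkage(squareform(dist_s, checks=False),
                              method="average")
        for d in deepsplits:
            lab = _hybrid_cut(dist_s, z, d, min_size)
            vi_sum[d] += variation_of_information(partitions[d], lab)
    avg_vi = {d: vi_sum[d] / n_subsamples for d in deepsplits}
    chosen = choose_deepsplit_by_kick(avg_vi)
    return ClusterModelSelection(deepsplits, partitions, avg_vi, chosen,
                                 min_size)


# ---------------------------------------------------------------------- PAM

def pam_split(dist: np.ndarray, k: int = 2, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids (build + swap) on a distance matrix."""
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    if k >= n and k != 1:
        raise ValueError("k must be smaller than the number of cells")
    # BUILD: greedy medoid selection
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        gains = np.array([np.minimum(cur, dist[:, j]).sum() for j in range(n)])
        gains[medoids] = np.inf
        medoids.append(int(np.argmin(gains)))
    # SWAP
    best_cost = dist[:, medoids].min(axis=1).sum()
    improved = True
    it = 0
    while improved and it < max_iter:
        improved = False
        it += 1
        for mi in range(k):
            for j in range(n):
                if j in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = j
                cost = dist[:, cand].min(axis=1).sum()
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    medoids = cand
                    improved = True
    return np.argmin(dist[:, medoids], axis=1)


# ------------------------------------------------------------ kNN outliers

def knn_outliers(m, features=None, k: int = 5,
                 contamination: float = 0.05) -> np.ndarray:
    """Flag cells by distance to their k-th nearest neighbour.

    The top ``contamination`` fraction of scores is flagged (ties broken by
    cell index; ``contamination=0`` flags nothing).
    """
    from sklearn.neighbors import NearestNeighbors

    vals = m.values if hasattr(m, "values") else np.asarray(m, float)
    if features is not None and hasattr(m, "feature_ids"):
        from .expression import feature_positions
        vals = vals[:, feature_positions(m.feature_ids, features)]
    n = vals.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(vals)
    d, _ = nn.kneighbors(vals)
    scores = d[:, -1]
    flags = np.zeros(n, dtype=bool)
    n_flag = int(np.floor(contamination * n))
    if n_flag > 0:
        order = np.argsort(-scores, kind="stable")
        flags[order[:n_flag]] = True
    return flags


# ------------------------------------------------------------- marker genes

def bh_adjust(p: np.ndarray) -> np.ndarray:
    from .expression import _bh_adjust
    return _bh_adjust(p)


def _tie_terms(col_sorted: np.ndarray) -> float:
    _, counts = np.unique(col_sorted, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t ** 3 - t))


def ranksum_test(a: np.ndarray, b: np.ndarray, method: str = "auto"):
    """Two-sided Wilcoxon rank-sum for each column of ``a`` vs ``b``.

    ``a``: (na x G), ``b``: (nb x G).  ``method="auto"`` uses the exact
    null distribution when both groups have <= 8 observations and a column
    has no ties, else the tie-corrected normal approximation (no continuity
    correction).  Returns p-values, shape (G,).
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    na, nb = a.shape[0], b.shape[0]
    stacked = np.vstack([a, b])
    nn = na + nb
    ranks = stats.rankdata(stacked, axis=0)
    r1 = ranks[:na].sum(axis=0)
    u = r1 - na * (na + 1) / 2.0
    mean = na * nb / 2.0
    g = stacked.shape[1]
    pvals = np.empty(g)
    srt = np.sort(stacked, axis=0)
    for j in range(g):
        tie = _tie_terms(srt[:, j])
        exact_ok = (method == "exact"
                    or (method == "auto" and max(na, nb) <= 8 and tie == 0))
        if exact_ok and tie == 0:
            res = stats.mannwhitneyu(a[:, j], b[:, j],
                                     alternative="two-sided", method="exact")
            pvals[j] = res.pvalue
            continue
        var = na * nb / 12.0 * (nn + 1 - tie / (nn * (nn - 1)))
        if var <= 0:
            pvals[j] = 1.0
            continue
        z = (u[j] - mean) / np.sqrt(var)
        pvals[j] = 2.0 * stats.norm.sf(abs(z))
    return pvals


def log2_fold_changes(m, mask_a, mask_b, eps: float = 1e-9) -> np.ndarray:
    """log2 fold change on expm1 of mean log-normalized values."""
    a = np.expm1(m.values[mask_a].mean(axis=0))
    b = np.expm1(m.values[mask_b].mean(axis=0))
    return np.log2((a + eps) / (b + eps))


@dataclass
class MarkerTable:
    """Pairwise-Wilcoxon marker results.

    ``pairwise[(c, o)]`` holds log2FC and BH-adjusted p of cluster ``c`` vs
    ``o`` for every gene; ``markers[c]`` lists genes with log2FC > 1 and
    adjusted p < 0.1 against every other cluster, ordered by ``scores``
    (average -log10 adjusted p across all pairwise comparisons).
    """

    clusters: list
    pairwise: dict = field(repr=False)
    scores: pd.DataFrame = field(repr=False)
    markers: dict = None


def rank_markers(m, partition, lfc_threshold: float = 1.0,
                 alpha: float = 0.1) -> MarkerTable:
    """Pairwise Wilcoxon marker detection and ranking.

    Expects the log-normalized layer.  For each ordered cluster pair a
    two-sided rank-sum test with BH correction across genes; a gene marks a
    cluster when log2FC > ``lfc_threshold`` and adjusted p < ``alpha`` in
    every comparison with the other clusters; ranking is by average
    -log10 adjusted p over all pairwise comparisons.
    """
    labels = np.asarray(partition)
    clusters = list(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for marker detection")
    sizes = {c: int((labels == c).sum()) for c in clusters}
    for c, s in sizes.items():
        if s < 3:
            warnings.warn(f"cluster {c!r} has {s} cells; markers unreliable")
    pairwise = {}
    for c in clusters:
        for o in clusters:
            if c == o or (o, c) in pairwise:
                continue
            pa = ranksum_test(m.values[labels == c], m.values[labels == o],
                              method="asymptotic")
            adj = bh_adjust(pa)
            lfc = log2_fold_changes(m, labels == c, labels == o)
            pairwise[(c, o)] = pd.DataFrame(
                {"log2fc": lfc, "p": pa, "adj_p": adj}, index=m.feature_ids)

    def comp(c, o):
        if (c, o) in pairwise:
            return pairwise[(c, o)]
        df = pairwise[(o, c)].copy()
        df["log2fc"] = -df["log2fc"]
        return df

    scores = pd.DataFrame(index=pd.Index(m.feature_ids), columns=clusters,
                          dtype=float)
    markers = {}
    for c in clusters:
        others = [o for o in clusters if o != c]
        neglog = np.zeros(m.n_features)
        ok = np.ones(m.n_features, dtype=bool)
        for o in others:
            df = comp(c, o)
            neglog += -np.log10(np.clip(df["adj_p"].to_numpy(), 1e-300, None))
            ok &= (df["log2fc"].to_numpy() > lfc_threshold) \
                & (df["adj_p"].to_numpy() < alpha)
        scores[c] = neglog / len(others)
        sel = pd.Index(m.feature_ids)[ok]
        markers[c] = list(sel[np.argsort(-scores[c][sel].to_numpy(),
                                         kind="stable")])
    return MarkerTable(clusters, pairwise, scores, markers)
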