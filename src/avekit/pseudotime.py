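"""Diffusion maps, diffusion pseudotime and trend-based differential
expression along the pseudotime axis.

The transition matrix is built from a k-nearest-neighbour graph with a
Gaussian kernel of per-cell adaptive bandwidth (distance to the
ceil(k/2)-th neighbour), density-normalized (alpha = 1) and row-normalized.
Diffusion pseudotime is the Euclidean distance between rows of the
accumulated transition operator M = (I - (T - 1 pi^T))^-1 - I, measured
from a root cell chosen as the extremum of the second diffusion component.

Genes are tested for expression trends along pseudotime with a cubic
regression spline (4 effective degrees of freedom) against an
intercept-only model (F-test, BH-FDR), and significant genes are grouped by
clustering their standardized fitted trends with the VI-guided hierarchical
procedure, subsampling cells for robustness; groups are labelled
``high-in-AVE`` (decreasing along pseudotime away from the AVE) or
``low-in-AVE`` (increasing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, sparse, stats

from .clustering import (_spearman_distance_from_values,
                         choose_deepsplit_by_kick, hierarchical_partition,
                         variation_of_information)
from .subclustering import KnnGraph


@dataclass
class DiffusionMap:
    """Spectral decomposition of the diffusion transition matrix.

    ``components[:, i]`` is the i-th non-trivial diffusion component (DC1 at
    column 0), sign-fixed so its largest-magnitude entry is positive.
    ``cell_indices`` maps rows back to the input cells (a strict subset when
    the graph was disconnected and the largest component was used).
    """

    transition: np.ndarray
    eigenvalues: np.ndarray          # non-trivial, decreasing
    components: np.ndarray           # right eigenvectors, cells x n_comps
    left: np.ndarray = field(repr=False)  # matching left eigenvectors
    stationary: np.ndarray = None
    cell_indices: np.ndarray = None


def _largest_component(adj: np.ndarray) -> np.ndarray:
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(adj), directed=False)
    if n_comp == 1:
        return np.arange(adj.shape[0])
    warnings.warn(f"graph has {n_comp} components; using the largest")
    sizes = np.bincount(labels)
    return np.flatnonzero(labels == np.argmax(sizes))


def diffusion_map(graph: KnnGraph, n_comps: int | None = None) -> DiffusionMap:
    """Diffusion map from a kNN graph with adaptive Gaussian kernel.

    Kernel: ``K_ij = exp(-d_ij^2 / (sigma_i sigma_j))`` on the symmetrized
    edge set, with ``sigma_i`` the distance from cell i to its
    ceil(k/2)-th neighbour; density normalization divides by the kernel row
    sums (alpha = 1) before row-normalizing into the transition matrix.
    """
    n, k = graph.neighbors.shape
    sigma = graph.distances[:, int(np.ceil(k / 2)) - 1].astype(float)
    sigma = np.clip(sigma, 1e-12, None)
    kernel = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    cols = graph.neighbors.ravel()
    d = graph.distances.ravel()
    kernel[rows, cols] = np.exp(-d ** 2 / (sigma[rows] * sigma[cols]))
    kernel = np.maximum(kernel, kernel.T)   # symmetrize the edge set
    # exchangeability guard: exact-duplicate cells must get identical rows
    # (kNN truncation can otherwise break ties asymmetrically)
    _, first, inv = np.unique(np.round(graph.pcs, 12), axis=0,
                              return_index=True, return_inverse=True)
    if len(first) < n:
        for gid in np.unique(inv):
            members = np.flatnonzero(inv == gid)
            if len(members) > 1:
                row = kernel[members].max(axis=0)
                kernel[members, :] = row
                kernel[:, members] = row[:, None]
                kernel[np.ix_(members, members)] = 1.0
    np.fill_diagonal(kernel, 1.0)

    keep = _largest_component(kernel > 0)
    kernel = kernel[np.ix_(keep, keep)]
    q = kernel.sum(axis=1)
    kernel = kernel / np.outer(q, q)        # density normalization, alpha=1
    deg = kernel.sum(axis=1)
    t_mat = kernel / deg[:, None]

    # symmetric conjugate S = D^-1/2 K D^-1/2 shares T's spectrum
    inv_sqrt = 1.0 / np.sqrt(deg)
    s_mat = kernel * np.outer(inv_sqrt, inv_sqrt)
    evals, u = np.linalg.eigh((s_mat + s_mat.T) / 2.0)
    order = np.argsort(-evals)
    evals, u = evals[order], u[:, order].copy()
    right = u * inv_sqrt[:, None]
    # sign-fix right eigenvectors, propagating the flip to the left ones so
    # that the biorthogonal pairing (left_i . right_j = delta_ij) is kept
    for j in range(right.shape[1]):
        i = np.argmax(np.abs(right[:, j]))
        if right[i, j] < 0:
            u[:, j] *= -1
            right[:, j] *= -1
    left = u * np.sqrt(deg)[:, None]
    if n_comps is None:
        n_comps = len(evals) - 1
    stationary = deg / deg.sum()
    return DiffusionMap(t_mat, evals[1:n_comps + 1],
                        right[:, 1:n_comps + 1],
                        left=left, stationary=stationary, cell_indices=keep)


@dataclass
class PseudotimeResult:
    root_cell: int
    dpt: np.ndarray
    params: dict = field(default_factory=dict)


def dpt_distance_matrix(dm: DiffusionMap) -> np.ndarray:
    """Rows of the accumulated operator M (spectral form)."""
    lam = dm.eigenvalues
    bad = np.abs(1.0 - lam) < 1e-12
    if bad.any():
        raise np.linalg.LinAlgError(
            f"eigenvalue 1 has multiplicity {1 + int(bad.sum())}: "
            "the transition matrix is reducible; use a connected graph")
    f = lam / (1.0 - lam)
    # M = sum_i f_i v_i w_i^T over the non-stationary eigenpairs
    right = dm.components
    left = dm.left[:, 1:1 + len(lam)]
    return (right * f) @ left.T


def dpt(dm: DiffusionMap, root="min_dc2") -> PseudotimeResult:
    """Diffusion pseudotime from a root cell.

    ``root`` is a cell index, or ``"min_dc2"`` / ``"max_dc2"`` to select the
    extremum of the second diffusion component (the stage-dependent
    convention; there is no silent default beyond requiring the caller to
    pass one of these).  dpt(x) is the Euclidean distance between the rows
    of M for the root and for x; dpt(root) = 0.
    """
    if isinstance(root, str):
        if root not in ("min_dc2", "max_dc2"):
            raise ValueError(f"unknown root selector {root!r}")
        # DC numbering counts the trivial stationary component as DC1, so
        # DC2 is the first non-trivial component (components[:, 0])
        dc2 = dm.components[:, 0]
        root_idx = int(np.argmin(dc2) if root == "min_dc2" else np.argmax(dc2))
    else:
        root_idx = int(root)
    m_rows = dpt_distance_matrix(dm)
    diff = m_rows - m_rows[root_idx]
    vals = np.sqrt((diff ** 2).sum(axis=1))
    vals[root_idx] = 0.0
    return PseudotimeResult(root_idx, vals,
                            params={"root": root, "n_comps": len(dm.eigenvalues)})


# -------------------------------------------------- trend-based DE

def _spline_design(x: np.ndarray, df: int = 4):
    """Cubic B-spline design matrix with ``df`` non-intercept effective df.

    df + 1 basis functions spanning cubic splines (including the constant),
    interior knots at quantiles of x.
    """
    k = 3
    n_basis = df + 1
    n_interior = n_basis - (k + 1)
    xs = np.asarray(x, float)
    lo, hi = xs.min(), xs.max()
    if hi <= lo:
        hi = lo + 1e-9
    interior = (np.quantile(xs, np.linspace(0, 1, n_interior + 2)[1:-1])
                if n_interior > 0 else np.array([]))
    t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    xc = np.clip(xs, lo, hi - 1e-12 * max(1.0, abs(hi)))
    return interpolate.BSpline.design_matrix(xc, t, k).toarray(), t, k


@dataclass
class TrendDEResult:
    """Per-gene spline-trend test along pseudotime plus fitted trends."""

    table: pd.DataFrame = field(repr=False)   # F, p, fdr, detected, significant
    fitted: pd.DataFrame = field(repr=False)  # significant genes x grid
    grid: np.ndarray = None
    fdr_threshold: float = 0.01
    groups: pd.Series = None                  # filled by group_trends


def trend_de(m, dpt_values, min_cells: int = 10, fdr: float = 0.01,
             df: int = 4, n_grid: int = 100) -> TrendDEResult:
    """Smooth-trend differential expression along pseudotime.

    Genes detected (count/expression > 0) in fewer than ``min_cells`` cells
    are excluded.  Each remaining gene's log-normalized expression is fit
    with a cubic regression spline in dpt and compared with an
    intercept-only model by F-test; p-values are BH-corrected and genes
    called significant at FDR < ``fdr``.  Fitted trends are evaluated on a
    uniform dpt grid for downstream grouping.
    """
    x = np.asarray(dpt_values, float)
    y_all = m.values
    detected = (y_all > 0).sum(axis=0)
    use = detected >= min_cells
    genes = np.asarray(m.feature_ids)
    y = y_all[:, use]
    n = len(x)
    design, knots, k = _spline_design(x, df=df)
    p_par = np.linalg.matrix_rank(design)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss1 = (resid ** 2).sum(axis=0)
    rss0 = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    q = p_par - 1
    dof2 = n - p_par
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss0 - rss1) / q) / (rss1 / dof2)
    pvals = np.where(rss0 <= 1e-300, 1.0, stats.f.sf(f_stat, q, dof2))
    pvals = np.where(rss1 <= 1e-300, np.where(rss0 <= 1e-300, 1.0, 0.0), pvals)
    from .expression import _bh_adjust
    adj = _bh_adjust(pvals)

    table = pd.DataFrame({"detected_cells": detected,
                          "F": np.nan, "p": np.nan, "fdr": np.nan,
                          "significant": False}, index=pd.Index(genes))
    table.loc[genes[use], "F"] = f_stat
    table.loc[genes[use], "p"] = pvals
    table.loc[genes[use], "fdr"] = adj
    table.loc[genes[use], "significant"] = adj < fdr

    grid = np.linspace(x.min(), x.max(), n_grid)
    design_grid = interpolate.BSpline.design_matrix(
        np.clip(grid, x.min(), x.max() - 1e-12 * max(1.0, abs(x.max()))),
        knots, k).toarray()
    sig_mask = (adj < fdr)
    fitted = pd.DataFrame((design_grid @ beta[:, sig_mask]).T,
                          index=pd.Index(genes[use][sig_mask]))
    return TrendDEResult(table, fitted, grid=grid, fdr_threshold=fdr)


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (a - mu) / sd


def group_trends(m, dpt_values, trends: TrendDEResult, min_group: int = 50,
                 subsample_fraction: float = 0.7, n_subsamples: int = 50,
                 df: int = 4, seed: int = 0) -> pd.Series:
    """Group significant genes by their pseudotime trend shape.

    Standardized fitted trends are clustered with the VI-guided hierarchical
    procedure (Spearman distance, average linkage, deepsplit selected by the
    kick rule) with a minimum cluster size of ``min_group``; robustness
    subsamples draw ``subsample_fraction`` of the *cells* and refit the
    trends.  Each cluster is labelled ``high-in-AVE`` when its mean fitted
    trend decreases along dpt (negative slope) and ``low-in-AVE`` otherwise.
    Genes that are not significant get ``"none"``.
    """
    genes = trends.fitted.index.to_numpy()
    labels_out = pd.Series("none", index=trends.table.index, dtype=object)
    if len(genes) == 0:
        return labels_out
    z_full = _standardize_rows(trends.fitted.to_numpy())
    x = np.asarray(dpt_values, float)

    if len(genes) < 2 * min_group:
        warnings.warn("fewer than 2*min_group significant genes; one group")
        part = np.zeros(len(genes), dtype=int)
    else:
        dist = _spearman_distance_from_values(z_full)
        deepsplits = range(5)
        partitions = {d: hierarchical_partition(dist, d, min_group)
                      for d in deepsplits}
        vi_sum = {d: 0.0 for d in deepsplits}
        from .expression import feature_positions
        cols = feature_positions(m.feature_ids, genes)
        n_cells = m.n_cells
        n_keep = max(5, int(round(subsample_fraction * n_cells)))
        grid = trends.grid
        for s in range(n_subsamples):
            rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
            keep = np.sort(rng.choice(n_cells, size=n_keep, replace=False))
            design, knots, k = _spline_design(x[keep], df=df)
            beta, *_ = np.linalg.lstsq(design, m.values[np.ix_(keep, cols)],
                                       rcond=None)
            gclip = np.clip(grid, x[keep].min(),
                            x[keep].max() - 1e-12 * max(1.0, abs(x[keep].max())))
            fit = (interpolate.BSpline.design_matrix(gclip, knots, k).toarray()
                   @ beta).T
            dist_s = _spearman_distance_from_values(_standardize_rows(fit))
            for d in deepsplits:
                lab = hierarchical_partition(dist_s, d, min_group)
                vi_sum[d] += variation_of_information(partitions[d], lab)
        avg_vi = {d: vi_sum[d] / n_subsamples for d in deepsplits}
        part = partitions[choose_deepsplit_by_kick(avg_vi)]

    for c in np.unique(part):
        mean_trend = z_full[part == c].mean(axis=0)
        slope = np.polyfit(trends.grid, mean_trend, 1)[0]
        labels_out.loc[genes[part == c]] = ("high-in-AVE" if slope < 0
                                            else "low-in-AVE")
    trends.groups = labels_out
    return labels_out
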