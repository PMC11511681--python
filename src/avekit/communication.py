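"""Ligand-receptor communication graphs and pathway PCA with bootstrap
loading significance.

Each ligand-receptor pair (LRP) alpha is scored as a weighted directed
graph over cell-type nodes with

    w_ij = (phi_i^lig * phi_j^rec) * (p_i^lig * p_j^rec)

where phi is the fraction of cells in the node expressing the gene
(values below 0.1 set to 0) and p is the node's mean non-zero
log-expression divided by the maximum of those means over nodes.  For
multi-gene complexes phi and p are products over member genes.  Weights
below the 50th percentile of the pooled weight distribution are zeroed and
all-zero LRPs dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRP:
    """One ligand-receptor pair; either unit may be a multi-gene complex."""

    id: str
    ligand_genes: tuple
    receptor_genes: tuple

    def __post_init__(self):
        if not self.ligand_genes or not self.receptor_genes:
            raise ValueError(f"LRP {self.id}: empty ligand or receptor unit")


def read_lrp_table(path) -> list[LRP]:
    """TSV with columns ``lrp_id, ligand_genes, receptor_genes``
    (comma-joined complex members)."""
    df = pd.read_csv(path, sep="\t")
    return [LRP(str(r["lrp_id"]),
                tuple(str(r["ligand_genes"]).split(",")),
                tuple(str(r["receptor_genes"]).split(",")))
            for _, r in df.iterrows()]


@dataclass
class NodeExpressionSummary:
    """Per-node phi (expressing fraction, floored at 0.1) and p
    (mean non-zero log-expression, scaled to the node-wise maximum)."""

    nodes: list
    phi: pd.DataFrame = field(repr=False)   # nodes x genes
    p: pd.DataFrame = field(repr=False)


def summarize_nodes(m, partition, genes=None, phi_min: float = 0.1,
                    min_cells: int = 10, min_nonzero_mean: float = 1.0
                    ) -> NodeExpressionSummary:
    """Node-level expression summary entering the communication weights.

    A gene filter is applied first on the full cell set: genes detected in
    fewer than ``min_cells`` cells, or whose mean log-expression over
    non-zero values is below ``min_nonzero_mean``, are removed.  phi values
    below ``phi_min`` are set to 0.  p = 1 at the node with the largest
    non-zero mean.
    """
    labels = np.asarray(partition)
    nodes = list(pd.unique(labels))
    for node in nodes:
        if (labels == node).sum() == 0:
            raise ValueError(f"empty node {node!r}")
    vals = m.values
    feature_ids = np.asarray(m.feature_ids)
    if genes is not None:
        from .expression import feature_positions
        cols = feature_positions(feature_ids, genes)
        vals = vals[:, cols]
        feature_ids = feature_ids[cols]
    nz = vals > 0
    detected = nz.sum(axis=0)
    with np.errstate(invalid="ignore"):
        nzmean_all = np.where(detected > 0, vals.sum(axis=0)
                              / np.maximum(detected, 1), 0.0)
    keep = (detected >= min_cells) & (nzmean_all >= min_nonzero_mean)
    vals, feature_ids, nz = vals[:, keep], feature_ids[keep], nz[:, keep]

    phi_rows, mean_rows = [], []
    for node in nodes:
        mask = labels == node
        sub, subnz = vals[mask], nz[mask]
        phi = subnz.mean(axis=0)
        phi = np.where(phi < phi_min, 0.0, phi)
        cnt = subnz.sum(axis=0)
        nzmean = np.where(cnt > 0, sub.sum(axis=0) / np.maximum(cnt, 1), 0.0)
        phi_rows.append(phi)
        mean_rows.append(nzmean)
    phi = pd.DataFrame(phi_rows, index=nodes, columns=feature_ids)
    means = pd.DataFrame(mean_rows, index=nodes, columns=feature_ids)
    mx = means.max(axis=0)
    p = means.div(mx.where(mx > 0, 1.0), axis=1)
    return NodeExpressionSummary(nodes, phi, p)


@dataclass
class LRPCommunicationGraph:
    """Per-LRP weighted directed node x node adjacency matrices."""

    nodes: list
    weights: dict = field(repr=False)   # lrp_id -> DataFrame nodes x nodes

    def to_long(self) -> pd.DataFrame:
        rows = []
        for lid, w in self.weights.items():
            for i in self.nodes:
                for j in self.nodes:
                    rows.append((lid, i, j, float(w.loc[i, j])))
        return pd.DataFrame(rows, columns=["lrp_id", "source_node",
                                           "target_node", "weight"])


def _unit_phi_p(summary: NodeExpressionSummary, genes) -> tuple:
    """Per-node phi and p of a (possibly multi-gene) unit: products over
    the member genes."""
    phi = np.ones(len(summary.nodes))
    p = np.ones(len(summary.nodes))
    for g in genes:
        phi = phi * summary.phi[g].to_numpy()
        p = p * summary.p[g].to_numpy()
    return phi, p


def lrp_weights(summary: NodeExpressionSummary, lrps,
                weight_percentile: float = 50.0,
                include_zeros: bool = True) -> LRPCommunicationGraph:
    """Communication weight matrices for a list of LRPs.

    LRPs with genes missing from the (filtered) summary are dropped with a
    log message.  After computing all matrices, weights strictly below the
    ``weight_percentile`` of the pooled distribution (zeros included by
    default) are set to 0 and all-zero LRPs removed.
    """
    nodes = summary.nodes
    avail = set(summary.phi.columns)
    raw = {}
    for lrp in lrps:
        missing = [g for g in (*lrp.ligand_genes, *lrp.receptor_genes)
                   if g not in avail]
        if missing:
            logger.info("LRP %s dropped: missing genes %s", lrp.id, missing)
            continue
        phi_l, p_l = _unit_phi_p(summary, lrp.ligand_genes)
        phi_r, p_r = _unit_phi_p(summary, lrp.receptor_genes)
        w = np.outer(phi_l * p_l, phi_r * p_r)
        raw[lrp.id] = w
    if not raw:
        return LRPCommunicationGraph(nodes, {})
    pooled = np.concatenate([w.ravel() for w in raw.values()])
    if not include_zeros:
        pooled = pooled[pooled > 0]
    thr = np.percentile(pooled, weight_percentile)
    out = {}
    for lid, w in raw.items():
        w = np.where(w < thr, 0.0, w)
        if np.any(w > 0):
            out[lid] = pd.DataFrame(w, index=nodes, columns=nodes)
    return LRPCommunicationGraph(nodes, out)


def restrict_to_gene_group(graph: LRPCommunicationGraph, lrps,
                           gene_group) -> LRPCommunicationGraph:
    """Keep LRPs with at least one ligand or receptor gene in
    ``gene_group`` (e.g. the high-in-AVE genes)."""
    group = set(gene_group)
    if not group:
        return LRPCommunicationGraph(graph.nodes, {})
    by_id = {l.id: l for l in lrps}
    kept = {}
    for lid, w in graph.weights.items():
        lrp = by_id[lid]
        if group & set((*lrp.ligand_genes, *lrp.receptor_genes)):
            kept[lid] = w
    return LRPCommunicationGraph(graph.nodes, kept)


# ------------------------------------------ bootstrap PCA loading p-values

@dataclass
class BootstrapPCAResult:
    """Loadings of the first PCs with sign-inversion bootstrap p-values."""

    genes: list
    loadings: pd.DataFrame = field(repr=False)   # genes x PCs
    p_values: pd.DataFrame = field(repr=False)   # genes x PCs
    significant: list = None
    explained_variance_ratio: np.ndarray = None


def _pca_loadings(x: np.ndarray, n_pcs: int):
    """Loadings (genes x PCs) via eigendecomposition of the covariance."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / max(1, x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(-evals)
    evals = np.clip(evals[order], 0, None)
    return evecs[:, order[:n_pcs]], evals


def pathway_pca_bootstrap(m, pathway_genes, min_mean: float = 0.5,
                          n_boot: int = 1000, n_pcs: int = 3,
                          alpha: float = 0.01, seed: int = 0
                          ) -> BootstrapPCAResult:
    """Which pathway genes drive the first principal components?

    Genes with mean log-normalized expression <= ``min_mean`` are dropped
    (at least 3 must survive).  PCA on cells x genes gives reference
    loadings; in each of ``n_boot`` bootstrap resamples of the cells the
    PCA is recomputed, every component is reflection-aligned to the
    reference (flipped when the loading vectors' dot product is negative),
    and a loading's p-value is the fraction of replicates in which its sign
    differs from the reference.  Genes with any of the first ``n_pcs``
    loadings at p < ``alpha`` are reported significant.
    """
    from .expression import feature_positions

    cols = feature_positions(m.feature_ids, list(pathway_genes))
    vals = m.values[:, cols]
    means = vals.mean(axis=0)
    keep = means > min_mean
    survivors = [g for g, k in zip(pathway_genes, keep) if k]
    if len(survivors) < 3:
        raise ValueError(
            f"only {len(survivors)} pathway genes pass the mean-expression "
            f"filter (> {min_mean}): {survivors}")
    x = vals[:, keep]
    n, g = x.shape
    ref, evals = _pca_loadings(x, n_pcs)
    rng = np.random.default_rng(seed)
    inversions = np.zeros((g, n_pcs))
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        lo, _ = _pca_loadings(x[idx], n_pcs)
        flips = np.sign(np.einsum("gc,gc->c", lo, ref))
        flips[flips == 0] = 1.0
        lo = lo * flips
        inversions += np.sign(lo) != np.sign(ref)
    pvals = inversions / n_boot
    pcs = [f"PC{i + 1}" for i in range(n_pcs)]
    loadings = pd.DataFrame(ref, index=survivors, columns=pcs)
    p_df = pd.DataFrame(pvals, index=survivors, columns=pcs)
    significant = list(p_df.index[(p_df < alpha).any(axis=1)])
    evr = evals[:n_pcs] / evals.sum() if evals.sum() > 0 else evals[:n_pcs]
    return BootstrapPCAResult(survivors, loadings, p_df, significant, evr)
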