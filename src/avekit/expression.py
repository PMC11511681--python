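"""Expression data model, QC, normalization, HVG selection and isoform tests.

The central container is :class:`ExpressionMatrix`, a light cells x features
matrix with per-cell metadata, carrying either raw counts or log-normalized
values (natural log of size-factor-scaled counts plus a pseudocount of 1).

Quality control follows five per-cell criteria evaluated simultaneously:
number of genes above 10 reads-per-million, log10 total reads, fraction of
mapped reads, mitochondrial read fraction and spike-in read fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: metadata columns required for QC filtering
QC_COLUMNS = (
    "n_genes_over_10rpm",
    "log10_total_reads",
    "mapped_fraction",
    "mito_fraction",
    "spikein_fraction",
)


@dataclass
class ExpressionMatrix:
    """Cells x features expression matrix with per-cell metadata.

    Parameters
    ----------
    values
        Dense array, shape ``(n_cells, n_features)``.  Raw counts
        (non-negative integers) when ``layer == "counts"``, finite floats
        when ``layer == "lognorm"``.
    cell_ids, feature_ids
        Unique string identifiers.
    cell_metadata
        DataFrame indexed by ``cell_ids``; QC columns as in
        :data:`QC_COLUMNS`, optionally a ``cluster`` column.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    layer: str = "counts"
    cell_metadata: pd.DataFrame = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x features)")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.feature_ids) != g:
            raise ValueError("id lengths inconsistent with values shape")
        if len(set(self.cell_ids)) != n or len(set(self.feature_ids)) != g:
            raise ValueError("cell/feature ids must be unique")
        if self.layer not in ("counts", "lognorm"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == "counts":
            if np.any(self.values < 0):
                raise ValueError("counts layer must be non-negative")
        else:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("lognorm layer must be finite")
        if self.cell_metadata is None:
            self.cell_metadata = pd.DataFrame(index=pd.Index(self.cell_ids))
        else:
            self.cell_metadata = self.cell_metadata.copy()
            self.cell_metadata.index = pd.Index(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            self.values[idx],
            self.cell_ids[idx],
            self.feature_ids,
            layer=self.layer,
            cell_metadata=self.cell_metadata.iloc[idx],
        )

    def subset_features(self, features) -> "ExpressionMatrix":
        pos = feature_positions(self.feature_ids, features)
        return ExpressionMatrix(
            self.values[:, pos],
            self.cell_ids,
            self.feature_ids[pos],
            layer=self.layer,
            cell_metadata=self.cell_metadata,
        )

    def feature_index(self) -> dict:
        return {f: i for i, f in enumerate(self.feature_ids)}


def feature_positions(feature_ids, features) -> np.ndarray:
    """Positions of ``features`` within ``feature_ids`` (order preserved)."""
    lookup = {f: i for i, f in enumerate(feature_ids)}
    missing = [f for f in features if f not in lookup]
    if missing:
        raise KeyError(f"features not present: {missing[:5]}")
    return np.array([lookup[f] for f in features], dtype=int)


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality-control thresholds (defaults as used for the
    embryo Smart-seq2 data: >3000 genes over 10 rpm, log10 reads > 4,
    mapped fraction > 0.5, mitochondrial fraction < 0.1, spike-in
    fraction < 0.3)."""

    min_genes_over_10rpm: float = 3000
    min_log10_reads: float = 4.0
    min_mapped_fraction: float = 0.5
    max_mito_fraction: float = 0.1
    max_spikein_fraction: float = 0.3


def qc_pass_matrix(meta: pd.DataFrame, t: QCThresholds) -> pd.DataFrame:
    """Boolean frame, one column per criterion, True = criterion passed."""
    for col in QC_COLUMNS:
        if col not in meta.columns:
            raise KeyError(f"cell metadata is missing QC column {col!r}")
    return pd.DataFrame(
        {
            "n_genes_over_10rpm": meta["n_genes_over_10rpm"] > t.min_genes_over_10rpm,
            "log10_total_reads": meta["log10_total_reads"] > t.min_log10_reads,
            "mapped_fraction": meta["mapped_fraction"] > t.min_mapped_fraction,
            "mito_fraction": meta["mito_fraction"] < t.max_mito_fraction,
            "spikein_fraction": meta["spikein_fraction"] < t.max_spikein_fraction,
        },
        index=meta.index,
    )


def filter_cells(m: ExpressionMatrix, t: QCThresholds = QCThresholds()):
    """Remove low-quality cells.

    A cell is retained only if it passes all five criteria simultaneously.

    Returns
    -------
    retained : ExpressionMatrix
    report : pandas.Series
        Number of cells failing each criterion (a cell may fail several),
        plus ``n_input``, ``n_retained``.
    """
    if m.layer != "counts":
        raise ValueError("filter_cells expects the raw counts layer")
    passed = qc_pass_matrix(m.cell_metadata, t)
    keep = passed.all(axis=1).to_numpy()
    report = (~passed).sum(axis=0)
    report["n_input"] = m.n_cells
    report["n_retained"] = int(keep.sum())
    return m.subset_cells(keep), report


def library_size_factors(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=1).astype(float)
    if np.any(lib == 0):
        raise ValueError("all-zero cell encountered; run QC filtering first")
    return lib / lib.mean()


def pooled_size_factors(counts: np.ndarray, pool_size: int = 15,
                        n_pools_per_cell: int = 4) -> np.ndarray:
    """Pooled-deconvolution size factors (lightweight variant).

    Cells are ordered by library size on a ring; sliding pools of
    ``pool_size`` cells are summed and each pool's factor estimated as the
    median ratio of the pooled profile to the average-cell profile.  The
    linear system pool-matrix @ s = pool-factors is solved by least squares
    and the solution rescaled to mean 1.  Robust to composition bias that a
    plain library-size factor would absorb into the factor.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        raise ValueError("all-zero cell encountered; run QC filtering first")
    if n < pool_size * 2:
        return library_size_factors(counts)
    order = np.argsort(lib, kind="stable")
    ref = counts.mean(axis=0)
    use = ref > 0
    rows, cols, b = [], [], []
    offsets = np.linspace(0, n, n_pools_per_cell, endpoint=False).astype(int)
    r = 0
    for off in offsets:
        for start in range(n):
            members = order[(np.arange(start, start + pool_size) + off) % n]
            pooled = counts[members].sum(axis=0)
            ratio = np.median(pooled[use] / ref[use])
            rows.extend([r] * pool_size)
            cols.extend(members)
            b.append(ratio)
            r += 1
    A = np.zeros((r, n))
    A[rows, cols] = 1.0
    # mild ridge toward library-size factors keeps the system well posed
    lam = 0.01
    A = np.vstack([A, lam * np.eye(n)])
    b = np.concatenate([b, lam * library_size_factors(counts) * 1.0])
    s, *_ = np.linalg.lstsq(A, np.asarray(b), rcond=None)
    s = np.clip(s, 1e-8, None)
    return s / s.mean()


def normalize_log(m: ExpressionMatrix, method: str = "pooled") -> ExpressionMatrix:
    """Log-normalize raw counts: ``ln(count / size_factor + 1)``.

    ``method`` selects the size factors: ``"pooled"`` (deconvolution-style,
    default) or ``"library"`` (plain library size).  Size factors are
    rescaled to mean 1, so a zero count always maps to 0.
    """
    if m.layer != "counts":
        raise ValueError("normalize_log expects the raw counts layer")
    if method == "pooled":
        sf = pooled_size_factors(m.values)
    elif method == "library":
        sf = library_size_factors(m.values)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    vals = np.log1p(m.values / sf[:, None])
    meta = m.cell_metadata.copy()
    meta["size_factor"] = sf
    return ExpressionMatrix(vals, m.cell_ids, m.feature_ids,
                            layer="lognorm", cell_metadata=meta)


def select_hvgs(m: ExpressionMatrix, n_top: int = 3000, max_mean: float = 10.0,
                n_bins: int = 20) -> np.ndarray:
    """Rank highly variable genes by binned dispersion z-score.

    Mean and dispersion (variance/mean) are computed on ``expm1`` of the
    log-normalized values; genes are placed into ``n_bins`` equal-occupancy
    mean bins and the dispersion z-scored within each bin.  Genes with mean
    above ``max_mean`` are excluded; the top ``n_top`` feature ids are
    returned in decreasing order of the z-score.
    """
    if m.layer != "lognorm":
        raise ValueError("select_hvgs expects the log-normalized layer")
    x = np.expm1(m.values)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if m.n_cells > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    ok = (mean <= max_mean) & (mean > 0) & (disp > 1e-12)
    z = np.full(mean.shape, -np.inf)
    if ok.sum() > 0:
        idx = np.flatnonzero(ok)
        ldisp = np.log(disp[idx])
        # equal-width bins over the mean; log dispersion keeps a handful of
        # extreme genes from inflating the bin spread
        nb = min(n_bins, len(idx))
        edges = np.linspace(mean[idx].min(), mean[idx].max(), nb + 1)
        bins = np.clip(np.digitize(mean[idx], edges[1:-1]), 0, nb - 1)
        for b in range(nb):
            sel = bins == b
            if not sel.any():
                continue
            d = ldisp[sel]
            sd = d.std(ddof=0)
            z[idx[sel]] = (d - d.mean()) / sd if sd > 0 else 0.0
    order = np.argsort(-z, kind="stable")
    order = order[np.isfinite(z[order])]
    if n_top > len(order):
        warnings.warn(
            f"n_top={n_top} exceeds the {len(order)} eligible features; "
            "returning all of them"
        )
        n_top = len(order)
    return m.feature_ids[order[:n_top]]


@dataclass
class IsoformTestResult:
    """Chi-squared comparison of isoform usage between two clusters."""

    gene: str
    chi2_statistic: float
    degrees_of_freedom: int
    p_value: float
    adjusted_p: float = np.nan
    table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    adj[order] = p[order] * n / (np.arange(n) + 1)
    adj[order] = np.minimum.accumulate(adj[order][::-1])[::-1]
    return np.clip(adj, 0, 1)


def isoform_de(transcripts: ExpressionMatrix, gene_map: pd.DataFrame,
               clusters=None, labels=None,
               single_isoform_cutoff: float = 0.8,
               floor: float = 1e-6) -> list[IsoformTestResult]:
    """Differential isoform usage between two cell clusters.

    ``transcripts`` holds transcript-level normalized (TPM-like) values;
    ``gene_map`` maps ``transcript`` -> ``gene`` (two columns).  Genes with
    more than ``single_isoform_cutoff`` of their total signal on one isoform
    are removed.  For each remaining gene a (#isoforms x 2) table of average
    expression per cluster is tested with Pearson's chi-squared (no
    continuity correction); p-values are BH-adjusted across genes.

    ``clusters`` names the two cluster labels; ``labels`` gives the per-cell
    labels (defaults to ``cell_metadata["cluster"]``).
    """
    if labels is None:
        labels = transcripts.cell_metadata["cluster"].to_numpy()
    labels = np.asarray(labels)
    if clusters is None:
        clusters = pd.unique(labels)
    if len(clusters) != 2:
        raise ValueError("isoform_de compares exactly two clusters")
    gm = gene_map.copy()
    gm.columns = ["transcript", "gene"][: len(gm.columns)]
    tx2gene = dict(zip(gm["transcript"], gm["gene"]))
    genes: dict[str, list[int]] = {}
    for j, t in enumerate(transcripts.feature_ids):
        genes.setdefault(tx2gene.get(t, t), []).append(j)

    masks = [labels == c for c in clusters]
    for c, mk in zip(clusters, masks):
        if mk.sum() == 0:
            raise ValueError(f"cluster {c!r} has no cells")
    results = []
    for gene, cols in genes.items():
        if len(cols) < 2:
            continue
        sub = transcripts.values[:, cols]
        total = sub.sum(axis=0)
        grand = total.sum()
        if grand <= 0:
            continue
        if total.max() / grand > single_isoform_cutoff:
            continue  # dominated by a single isoform
        table = np.column_stack([sub[mk].mean(axis=0) for mk in masks])
        table = np.clip(table, floor, None)
        if table.sum(axis=1).min() <= 0 or table.sum(axis=0).min() <= 0:
            logger.info("gene %s skipped: empty margin", gene)
            continue
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        results.append(
            IsoformTestResult(
                gene=gene,
                chi2_statistic=float(chi2),
                degrees_of_freedom=len(cols) - 1,
                p_value=float(p),
                table=pd.DataFrame(
                    table,
                    index=[transcripts.feature_ids[c] for c in cols],
                    columns=list(clusters),
                ),
            )
        )
    if results:
        adj = _bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    return results


def ap_ratio(anterior_signal: float, posterior_signal: float,
             anterior_ref: float, posterior_ref: float) -> float:
    """Anterior:posterior expression ratio, each side normalized to its
    reference (nuclear stain) intensity; 1 means balanced expression."""
    if anterior_ref <= 0 or posterior_ref <= 0:
        raise ValueError("reference intensities must be positive")
    return (anterior_signal / anterior_ref) / (posterior_signal / posterior_ref)
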