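"""Proteomics / phosphoproteomics differential analysis.

Peptide-level count tables (peptides x sample-run columns) are aggregated
to proteins, cyclic-loess normalized, averaged over technical runs, and
tested for differential abundance between the embryonic and abembryonic
halves with a moderated two-sample t-statistic (empirical-Bayes variance
shrinkage, BH correction; |log2FC| > 1 and adjusted p < 0.1 flag a protein
differential).  Differential phosphoproteins are joined with a
kinase-substrate interaction table, requiring exact phospho-site
correspondence, into side-specific bipartite networks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .expression import _bh_adjust

logger = logging.getLogger(__name__)


# ----------------------------------------------------------- aggregation

def aggregate_peptides(table: pd.DataFrame, protein_col: str = "protein",
                       peptide_col: str = "peptide") -> pd.DataFrame:
    """Sum peptide counts per protein; measurement columns are every column
    other than the peptide/protein/site annotations."""
    if table.empty:
        raise ValueError("empty peptide table")
    drop = [c for c in (peptide_col, "site") if c in table.columns]
    return table.drop(columns=drop).groupby(protein_col, sort=True).sum()


def peptide_support(table: pd.DataFrame, protein_col: str = "protein",
                    peptide_col: str = "peptide") -> pd.Series:
    """Number of distinct peptides supporting each protein."""
    return table.groupby(protein_col)[peptide_col].nunique()


# ---------------------------------------------------------- normalization

def normalize_loess(matrix: pd.DataFrame, n_cycles: int = 10,
                    tol: float = 1e-6, frac: float = 0.6) -> pd.DataFrame:
    """Cyclic-loess normalization.

    Works on ``log2(x + 1)``: for every column pair an MA-trend is
    estimated by loess and half the fitted offset moved from one column to
    the other; cycles repeat until the mean absolute offset falls below
    ``tol``.  The result is returned on the input intensity scale
    (``2**normalized - 1``), so an already balanced matrix round-trips
    unchanged.
    """
    if (matrix <= 0).all(axis=0).any():
        raise ValueError("column with no positive values cannot be normalized")
    raw = matrix.to_numpy(dtype=float)
    # strictly positive intensities are transformed without a pseudocount so
    # that pure scale factors are removed exactly; zeros force log2(x + 1)
    offset = 1.0 if (raw <= 0).any() else 0.0
    x = np.log2(raw + offset)
    n_samp = x.shape[1]
    if n_samp < 2:
        raise ValueError("need at least two samples")
    for _ in range(n_cycles):
        max_off = 0.0
        for i in range(n_samp - 1):
            for j in range(i + 1, n_samp):
                mdiff = x[:, i] - x[:, j]
                avg = (x[:, i] + x[:, j]) / 2.0
                fit = lowess(mdiff, avg, frac=frac, return_sorted=False)
                x[:, i] -= fit / 2.0
                x[:, j] += fit / 2.0
                max_off = max(max_off, float(np.mean(np.abs(fit))))
        if max_off < tol:
            break
    return pd.DataFrame(2.0 ** x - offset, index=matrix.index,
                        columns=matrix.columns)


def average_runs(matrix: pd.DataFrame, run_map: dict) -> pd.DataFrame:
    """Average technical runs into samples.

    ``run_map`` maps each column to its sample; NaN runs are skipped with a
    log message, an all-NaN sample is an error.
    """
    missing = [c for c in matrix.columns if c not in run_map]
    if missing:
        raise KeyError(f"columns without a run_map entry: {missing}")
    out = {}
    for sample in dict.fromkeys(run_map[c] for c in matrix.columns):
        cols = [c for c in matrix.columns if run_map[c] == sample]
        block = matrix[cols].to_numpy(dtype=float)
        if np.isnan(block).all(axis=1).any():
            raise ValueError(f"sample {sample!r} has proteins with no "
                             "finite run values")
        if np.isnan(block).any():
            logger.info("sample %r: NaN runs averaged over the rest", sample)
        out[sample] = np.nanmean(block, axis=1)
    return pd.DataFrame(out, index=matrix.index)


# ------------------------------------------------------- moderated t-test

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y (Newton iterations, as in empirical-Bayes
    variance moderation)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float):
    """Moment-match log-variances to a scaled F distribution; returns the
    prior variance s0^2 and prior degrees of freedom d0 (inf allowed)."""
    ok = s2 > 0
    if ok.sum() < 2:
        return float(np.mean(s2[ok])) if ok.any() else 0.0, np.inf
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(np.mean(e))
    ve = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if ve <= 0:
        return float(np.exp(ebar)), np.inf
    d0 = 2.0 * _trigamma_inverse(ve)
    s0 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return s0, d0


def differential_proteins(matrix: pd.DataFrame, groups,
                          lfc_threshold: float = 1.0, alpha: float = 0.1,
                          test: str = "moderated",
                          peptide_counts: pd.Series | None = None
                          ) -> pd.DataFrame:
    """Two-group differential abundance on normalized values.

    ``groups`` maps column -> group label (exactly two labels, >= 2
    replicates each); the statistic is computed on ``log2(x + 1)``.
    ``test`` is ``"moderated"`` (empirical-Bayes shrunken variance,
    default) or ``"welch"``.  Returns a DataFrame with ``log2fc``
    (first group minus second, label-sorted), ``p``, ``adj_p`` and the
    ``de`` flag (|log2FC| > ``lfc_threshold`` and adjusted p < ``alpha``).
    """
    groups = {c: groups[c] for c in matrix.columns}
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    cols1 = [c for c in matrix.columns if groups[c] == labels[0]]
    cols2 = [c for c in matrix.columns if groups[c] == labels[1]]
    n1, n2 = len(cols1), len(cols2)
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least two replicates")
    x1 = np.log2(matrix[cols1].to_numpy(dtype=float) + 1.0)
    x2 = np.log2(matrix[cols2].to_numpy(dtype=float) + 1.0)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = m1 - m2
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)

    if test == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v1 / n1 + v2 / n2
            t = lfc / np.sqrt(se2)
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1)
                             + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif test == "moderated":
        df_res = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_res
        s0, d0 = _fit_f_dist(s2, df_res)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0)
            df_total = np.inf
        else:
            s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
            df_total = df_res + d0
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        raise ValueError(f"unknown test {test!r}")

    # proteins with no variation anywhere and no shift carry no evidence
    flat = (v1 == 0) & (v2 == 0) & (lfc == 0)
    p = np.where(flat, 1.0, p)
    adj = _bh_adjust(p)
    out = pd.DataFrame({"log2fc": lfc, "p": p, "adj_p": adj,
                        "de": (np.abs(lfc) > lfc_threshold) & (adj < alpha)},
                       index=matrix.index)
    if peptide_counts is not None:
        out["n_peptides"] = peptide_counts.reindex(out.index)
    return out


# -------------------------------------------------- cross-omics comparison

def compare_with_rna(protein_de: pd.DataFrame, rna_de: pd.DataFrame,
                     mapping: pd.DataFrame | None = None):
    """Pair protein and RNA log2 fold changes and correlate them.

    ``mapping`` is an optional two-column frame (gene, protein); without it
    the indexes are joined directly.  Returns ``(paired, r, p)`` with
    Pearson's r and its two-sided p-value.
    """
    prot = protein_de[["log2fc"]].rename(columns={"log2fc": "log2fc_protein"})
    rna = rna_de[["log2fc"]].rename(columns={"log2fc": "log2fc_rna"})
    if mapping is not None:
        mp = mapping.copy()
        mp.columns = ["gene", "protein"][: len(mp.columns)]
        rna = rna.join(mp.set_index("gene"), how="inner")
        rna = rna.set_index("protein")
    paired = prot.join(rna, how="inner").dropna()
    if len(paired) < 3:
        raise ValueError("fewer than 3 shared identifiers after mapping")
    r, p = stats.pearsonr(paired["log2fc_protein"], paired["log2fc_rna"])
    return paired, float(r), float(p)


# ------------------------------------------------ kinase-substrate network

_SITE_RE = re.compile(r"^([A-Za-z])\s*(\d+)$")


def normalize_site(site) -> str | None:
    """Canonical phospho-site string: upper-case residue + integer position
    (``"s23 " -> "S23"``); None when malformed."""
    m = _SITE_RE.match(str(site).strip())
    if not m:
        return None
    return m.group(1).upper() + str(int(m.group(2)))


def kinase_substrate_network(de_phospho: pd.DataFrame,
                             interactions: pd.DataFrame) -> dict:
    """Side-specific bipartite kinase-substrate networks.

    ``de_phospho`` needs columns ``protein``, ``site``, ``side`` (e.g.
    ``embryonic`` / ``abembryonic``, from the sign of the fold change of
    differential phosphoproteins); ``interactions`` needs ``kinase``,
    ``substrate``, ``site``.  An interaction becomes an edge only when the
    substrate is differential on that side *and* the site annotations match
    exactly after normalization; malformed sites are skipped and logged.

    Returns a dict side -> ``networkx.DiGraph`` (kinase -> "substrate@site"
    nodes, ``bipartite`` attribute 0/1).
    """
    de = de_phospho.copy()
    de["site_norm"] = de["site"].map(normalize_site)
    bad = de["site_norm"].isna()
    if bad.any():
        logger.warning("%d differential rows with malformed sites skipped",
                       int(bad.sum()))
    de = de[~bad]
    de_keys = {side: set(zip(grp["protein"], grp["site_norm"]))
               for side, grp in de.groupby("side")}

    nets = {side: nx.DiGraph(side=side) for side in de_keys}
    for _, row in interactions.iterrows():
        site = normalize_site(row["site"])
        if site is None:
            logger.warning("interaction row with malformed site %r skipped",
                           row["site"])
            continue
        key = (row["substrate"], site)
        for side, keys in de_keys.items():
            if key in keys:
                g = nets[side]
                sub = f"{row['substrate']}@{site}"
                g.add_node(row["kinase"], bipartite=0)
                g.add_node(sub, bipartite=1)
                g.add_edge(row["kinase"], sub)
    return nets
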