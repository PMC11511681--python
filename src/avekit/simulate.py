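"""Synthetic data generators for every downstream stage.

Two generators are provided:

* :func:`simulate_counts` / :func:`simulate_transcript_counts` draw
  negative-binomial, cluster-structured single-cell count matrices with
  planted marker genes, an optional pseudotime-gradient population, planted
  ligand-receptor expression patterns, isoform splits and QC-failure cells.
* :func:`simulate_migration_video` renders 2-D time-lapse stacks of
  Gaussian-blob cells advecting from a motion source toward a sink, with a
  logistic slow-down, for the motion-phenotyping stage.

Both return the ground truth needed for parameter-recovery tests, and both
are bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

QC_FAIL_VALUES = {
    "n_genes_over_10rpm": 1500.0,
    "log10_total_reads": 3.5,
    "mapped_fraction": 0.4,
    "mito_fraction": 0.2,
    "spikein_fraction": 0.5,
}


@dataclass
class IsoformPlan:
    """Isoform split for one gene: transcript ids and per-cluster
    proportions (rows = clusters, columns = isoforms; each row sums to 1)."""

    transcripts: list
    proportions: np.ndarray

    def __post_init__(self):
        self.proportions = np.atleast_2d(np.asarray(self.proportions, float))
        if not np.allclose(self.proportions.sum(axis=1), 1.0):
            raise ValueError("isoform proportions must sum to 1 per cluster")
        if self.proportions.shape[1] != len(self.transcripts):
            raise ValueError("proportions shape inconsistent with transcripts")


@dataclass
class LrpPlanEntry:
    """Planted ligand-receptor expression pattern.

    ``ligand_phi`` / ``receptor_phi`` give, per cluster, the fraction of
    cells expressing each unit; ``magnitude`` is the negative-binomial mean
    of the expressing cells (counts).
    """

    ligand_genes: list
    receptor_genes: list
    ligand_phi: np.ndarray
    receptor_phi: np.ndarray
    magnitude: float = 50.0


@dataclass
class ExpressionSimSpec:
    """Conditions for the count simulator.

    Defaults emulate a plate-based (Smart-seq2-like) experiment: a few
    hundred cells, deep libraries, overdispersed counts (dispersion 0.3),
    log-normal gene baselines around ``baseline_mean`` counts, and markers
    raised by ``marker_log_fold_change`` (natural log) in their home cluster.
    """

    n_cells_per_cluster: list = field(default_factory=lambda: [100, 100, 100])
    n_genes: int = 12000
    n_marker_genes_per_cluster: int = 100
    marker_log_fold_change: float = 2.0
    nb_dispersion: float = 0.3
    baseline_mean: float = 5.0
    pseudotime_fraction: float = 0.0
    gradient_gene_sets: tuple = ((), ())  # (decreasing, increasing) indices
    gradient_amplitude: float = 2.0  # natural-log swing over latent time
    qc_fail_fraction: float = 0.0
    mito_gene_indices: tuple = ()
    spikein_gene_indices: tuple = ()
    isoform_map: dict = field(default_factory=dict)  # gene index -> IsoformPlan
    lrp_plan: list = field(default_factory=list)
    #: extra (clusters, gene_indices, log_fold_change) blocks, applied after
    #: the per-cluster markers; lets several clusters share an identity
    #: programme (hierarchical structure: major identity + sub-identity)
    marker_blocks: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or len(self.n_cells_per_cluster) == 0:
            raise ValueError("spec must have at least one gene and one cluster")
        if any(n <= 0 for n in self.n_cells_per_cluster):
            raise ValueError("cluster sizes must be positive")
        dec, inc = (set(self.gradient_gene_sets[0]), set(self.gradient_gene_sets[1]))
        if dec & inc:
            raise ValueError("gradient gene sets must be disjoint")
        if not 0 <= self.pseudotime_fraction <= 1:
            raise ValueError("pseudotime_fraction must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_cluster))

    @property
    def n_clusters(self) -> int:
        return len(self.n_cells_per_cluster)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB draw with var = mu + dispersion * mu^2 (Poisson when 0)."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def marker_indices(spec: ExpressionSimSpec) -> dict:
    """Planted marker gene indices per cluster (disjoint blocks)."""
    k = spec.n_marker_genes_per_cluster
    if k * spec.n_clusters > spec.n_genes:
        raise ValueError("not enough genes for the requested markers")
    return {c: list(range(c * k, (c + 1) * k)) for c in range(spec.n_clusters)}


def simulate_counts(spec: ExpressionSimSpec):
    """Draw a cluster-structured negative-binomial count matrix.

    Returns ``(ExpressionMatrix, truth)`` where ``truth`` records cluster
    labels, marker indices per cluster, the latent time of the gradient
    cells (NaN elsewhere), isoform proportions, the ligand-receptor plan,
    and the criterion violated by each planted QC-failure cell.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_cells, spec.n_genes
    labels = np.repeat(np.arange(spec.n_clusters), spec.n_cells_per_cluster)

    base = spec.baseline_mean * np.exp(rng.normal(0.0, 0.5, g))
    mu = np.tile(base, (n, 1))
    markers = marker_indices(spec)
    for c, idx in markers.items():
        mu[np.ix_(labels == c, idx)] *= np.exp(spec.marker_log_fold_change)
    for block_clusters, gene_idx, lfc in spec.marker_blocks:
        cells = np.isin(labels, list(block_clusters))
        mu[np.ix_(cells, list(gene_idx))] *= np.exp(lfc)

    # gradient population: the first ceil(f*n) cells carry a latent time in
    # [0, 1]; gradient genes vary log-linearly in it (symmetric about 0.5)
    latent = np.full(n, np.nan)
    n_grad = int(np.ceil(spec.pseudotime_fraction * n))
    if n_grad > 0:
        t = np.sort(rng.uniform(0, 1, n_grad))
        latent[:n_grad] = t
        dec, inc = spec.gradient_gene_sets
        a = spec.gradient_amplitude
        if len(dec):
            mu[np.ix_(np.arange(n_grad), list(dec))] *= np.exp(a * (0.5 - t))[:, None]
        if len(inc):
            mu[np.ix_(np.arange(n_grad), list(inc))] *= np.exp(a * (t - 0.5))[:, None]

    counts = _nb_sample(rng, mu, spec.nb_dispersion)

    # planted ligand-receptor patterns overwrite their genes
    for entry in spec.lrp_plan:
        for genes, phis in ((entry.ligand_genes, entry.ligand_phi),
                            (entry.receptor_genes, entry.receptor_phi)):
            phis = np.asarray(phis, float)
            for gi in genes:
                col = np.zeros(n, dtype=counts.dtype)
                for c in range(spec.n_clusters):
                    cells = np.flatnonzero(labels == c)
                    on = rng.random(len(cells)) < phis[c]
                    col[cells[on]] = _nb_sample(
                        rng, np.full(on.sum(), entry.magnitude),
                        spec.nb_dispersion)
                counts[:, gi] = col

    meta = _qc_metadata(rng, counts, spec)
    qc_fail = {}
    n_fail = int(round(spec.qc_fail_fraction * n))
    if n_fail > 0:
        fail_cells = rng.choice(n, size=n_fail, replace=False)
        crits = list(QC_FAIL_VALUES)
        for j, cell in enumerate(fail_cells):
            crit = crits[j % len(crits)]
            meta.iloc[cell, meta.columns.get_loc(crit)] = QC_FAIL_VALUES[crit]
            qc_fail[int(cell)] = crit
    meta["cluster"] = [f"c{c}" for c in labels]

    cell_ids = np.array([f"cell{i:04d}" for i in range(n)], dtype=object)
    gene_ids = np.array([f"gene{j:05d}" for j in range(g)], dtype=object)
    m = ExpressionMatrix(counts, cell_ids, gene_ids, layer="counts",
                         cell_metadata=meta)
    truth = {
        "cluster_labels": labels,
        "markers": markers,
        "latent_time": latent,
        "gradient_cells": np.arange(n_grad),
        "isoform_map": spec.isoform_map,
        "lrp_plan": spec.lrp_plan,
        "qc_fail": qc_fail,
    }
    return m, truth


def _qc_metadata(rng, counts, spec) -> pd.DataFrame:
    total = counts.sum(axis=1).astype(float)
    total = np.clip(total, 1, None)
    mapped = rng.beta(40, 10, len(total))  # ~0.8, comfortably above 0.5
    rpm = counts / total[:, None] * 1e6
    mito = (counts[:, list(spec.mito_gene_indices)].sum(axis=1) / total
            if len(spec.mito_gene_indices) else np.zeros(len(total)))
    spike = (counts[:, list(spec.spikein_gene_indices)].sum(axis=1) / total
             if len(spec.spikein_gene_indices) else np.zeros(len(total)))
    return pd.DataFrame({
        "n_genes_over_10rpm": (rpm > 10).sum(axis=1).astype(float),
        "log10_total_reads": np.log10(total / mapped),
        "mapped_fraction": mapped,
        "mito_fraction": mito,
        "spikein_fraction": spike,
    })


def simulate_transcript_counts(spec: ExpressionSimSpec, gene_counts=None,
                               labels=None):
    """Split gene counts into transcript counts.

    Per cell, each mapped gene's count is divided among its transcripts by a
    multinomial draw with the cell's cluster isoform proportions; genes
    without an isoform entry pass through as a single transcript.  Per-gene
    transcript sums equal the gene counts exactly.

    Returns ``(transcripts: ExpressionMatrix, gene_map: DataFrame)`` with
    ``gene_map`` columns ``transcript``, ``gene``.
    """
    if gene_counts is None:
        gene_counts, truth = simulate_counts(spec)
        labels = truth["cluster_labels"]
    if labels is None:
        raise ValueError("labels required when gene_counts is supplied")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = gene_counts.n_cells
    cols, tids, genes = [], [], []
    for j, gene in enumerate(gene_counts.feature_ids):
        plan = spec.isoform_map.get(j)
        cnt = gene_counts.values[:, j]
        if plan is None:
            cols.append(cnt[:, None])
            tids.append(f"{gene}.t1")
            genes.append(gene)
            continue
        k = len(plan.transcripts)
        out = np.zeros((n, k), dtype=cnt.dtype)
        for c in range(plan.proportions.shape[0]):
            cells = np.flatnonzero(np.asarray(labels) == c)
            if len(cells) == 0:
                continue
            out[cells] = rng.multinomial(cnt[cells], plan.proportions[c])
        cols.append(out)
        tids.extend(plan.transcripts)
        genes.extend([gene] * k)
    values = np.concatenate(cols, axis=1)
    tx = ExpressionMatrix(values, gene_counts.cell_ids, np.array(tids, dtype=object),
                          layer="counts", cell_metadata=gene_counts.cell_metadata)
    gene_map = pd.DataFrame({"transcript": tids, "gene": genes})
    return tx, gene_map


@dataclass
class VideoSimSpec:
    """Conditions for the migration-video simulator.

    Defaults emulate the confocal live-imaging setup: 6-minute frame
    interval, cells starting near a distal motion source and advecting
    toward a proximal sink at ``mean_speed`` px/frame, with a logistic
    slow-down after ``deceleration_onset`` (None = no slow-down).
    """

    frame_shape: tuple = (128, 128)  # (height, width)
    n_frames: int = 60
    frame_interval: float = 6.0  # minutes
    n_cells: int = 25
    blob_sigma: float = 2.5
    source_position: tuple = (64.0, 110.0)  # (x, y)
    sink_position: tuple = (64.0, 20.0)
    mean_speed: float = 1.5  # px/frame
    deceleration_onset: int | None = None
    deceleration_tau: float = 3.0  # frames; logistic decay scale
    start_spread: float | None = None  # default 3 * blob_sigma
    positional_noise_sigma: float = 0.0
    intensity_noise_sigma: float = 0.0
    #: amplitude of a static smooth background texture (tissue-like);
    #: keeps the optical flow well conditioned away from the labelled cells
    background_texture: float = 0.3
    background_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.frame_shape
        for x, y in (self.source_position, self.sink_position):
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError("source/sink must lie inside the frame")
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be non-negative")
        if self.start_spread is None:
            self.start_spread = 3.0 * self.blob_sigma


def _speed_profile(spec: VideoSimSpec) -> np.ndarray:
    t = np.arange(spec.n_frames - 1, dtype=float)
    if spec.deceleration_onset is None:
        return np.full(spec.n_frames - 1, spec.mean_speed)
    return spec.mean_speed / (
        1.0 + np.exp((t - spec.deceleration_onset) / spec.deceleration_tau))


def _render(frames, positions, sigma, rng, noise):
    h, w = frames.shape[1:]
    r = int(np.ceil(4 * sigma))
    for t in range(frames.shape[0]):
        for x, y in positions[:, t]:
            x0, y0 = int(round(x)), int(round(y))
            xs = slice(max(0, x0 - r), min(w, x0 + r + 1))
            ys = slice(max(0, y0 - r), min(h, y0 + r + 1))
            gx = np.arange(xs.start, xs.stop) - x
            gy = np.arange(ys.start, ys.stop) - y
            frames[t, ys, xs] += np.exp(
                -(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma ** 2))
        if noise > 0:
            frames[t] += rng.normal(0, noise, (h, w))


def simulate_migration_video(spec: VideoSimSpec):
    """Render a migration time-lapse with planted source/sink kinematics.

    Cells start clustered around ``source_position`` and step toward
    ``sink_position`` at the per-frame speed profile (constant, or logistic
    decay after ``deceleration_onset``); steps are clamped so cells stop at
    the sink, and positions are clamped to the frame.

    Returns ``(frames, truth)``: ``frames`` is a float array
    ``(n_frames, H, W)``; ``truth`` holds exact trajectories
    ``(n_cells, n_frames, 2)`` in (x, y), and the speed profile.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_shape
    n, f = spec.n_cells, spec.n_frames
    src = np.asarray(spec.source_position, float)
    snk = np.asarray(spec.sink_position, float)

    pos = np.empty((n, f, 2))
    pos[:, 0] = src + rng.normal(0, spec.start_spread, (n, 2))
    pos[:, 0, 0] = np.clip(pos[:, 0, 0], 0, w - 1)
    pos[:, 0, 1] = np.clip(pos[:, 0, 1], 0, h - 1)
    speeds = _speed_profile(spec)
    for t in range(f - 1):
        cur = pos[:, t]
        delta = snk - cur
        dist = np.linalg.norm(delta, axis=1)
        step = np.zeros_like(cur)
        moving = dist > 1e-12
        step[moving] = (delta[moving] / dist[moving, None]
                        * np.minimum(speeds[t], dist[moving])[:, None])
        if spec.positional_noise_sigma > 0:
            step += rng.normal(0, spec.positional_noise_sigma, (n, 2))
        nxt = cur + step
        nxt[:, 0] = np.clip(nxt[:, 0], 0, w - 1)
        nxt[:, 1] = np.clip(nxt[:, 1], 0, h - 1)
        pos[:, t + 1] = nxt

    frames = np.zeros((f, h, w))
    if spec.background_texture > 0:
        from scipy.ndimage import gaussian_filter

        texture = gaussian_filter(rng.normal(0, 1.0, (h, w)),
                                  spec.background_sigma)
        texture = spec.background_texture * (texture - texture.min()) \
            / max(np.ptp(texture), 1e-12)
        frames += texture
    _render(frames, pos, spec.blob_sigma, rng, spec.intensity_noise_sigma)
    truth = {"trajectories": pos, "speeds": speeds,
             "source": src, "sink": snk}
    return frames, truth
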