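"""Superpixel tracking, mesh strain and motion phenotyping of time-lapse
migration videos.

A registered single-channel video is tracked densely: the frame is
equipartitioned into ~``n_superpixels`` grid regions whose centroids are
advected by the mean dense optical flow inside a superpixel-sized window,
forwards (first frame to last; captures motion sinks) and in reverse
(captures motion sources), with automatic reseeding of vacated grid cells.
Tracks alive at the start frame are joined into a mesh (neighbours closer
than 1.2x the mean superpixel width); the mesh strain curve is the mean
absolute relative change of edge lengths per frame.  Concatenated
forward+reverse strain curves, truncated to a common frame count, form the
motion signature used for PCA phenotyping; smoothed densities of terminal
track positions give the motion-saliency source/sink maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.registration import optical_flow_ilk


# ------------------------------------------------------------- dense flow

def dense_flow(frames: np.ndarray, radius: int = 7, num_warp: int = 10
               ) -> np.ndarray:
    """Dense optical flow between consecutive frames.

    Iterative Lucas-Kanade flow (window ``radius``); returns an array
    ``(n_frames-1, H, W, 2)`` whose last axis is the forward displacement
    ``(dx, dy)`` in pixels at each pixel of the earlier frame.  Constant
    frame pairs yield zero flow.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames, H, W) stack with >= 2 frames")
    out = np.empty((frames.shape[0] - 1, *frames.shape[1:], 2))
    for t in range(frames.shape[0] - 1):
        a, b = frames[t], frames[t + 1]
        if np.allclose(a, b):
            out[t] = 0.0
            continue
        vr, vc = optical_flow_ilk(a, b, radius=radius, num_warp=num_warp,
                                  prefilter=True)
        out[t, ..., 0] = vc
        out[t, ..., 1] = vr
    return out


# ---------------------------------------------------------------- tracking

@dataclass
class TrackSet:
    """Superpixel trajectories.

    ``positions`` has shape (n_tracks, n_frames, 2) in (x, y); entries
    before a track's ``birth`` frame are NaN.  Positions are clamped at the
    frame borders so mesh edges stay defined.
    """

    positions: np.ndarray
    birth: np.ndarray
    superpixel_width: float
    direction: str = "forward"
    frame_shape: tuple = None

    @property
    def n_tracks(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


def _grid_centroids(h: int, w: int, n_superpixels: int):
    """Near-uniform grid with count closest to ``n_superpixels``."""
    width = np.sqrt(h * w / n_superpixels)
    ny = max(1, int(round(h / width)))
    nx = max(1, int(round(w / width)))
    ys = (np.arange(ny) + 0.5) * h / ny
    xs = (np.arange(nx) + 0.5) * w / nx
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts, width, ny, nx


def _window_mean_flow(flow_t: np.ndarray, pos: np.ndarray, half: int
                      ) -> np.ndarray:
    h, w = flow_t.shape[:2]
    out = np.empty((len(pos), 2))
    for i, (x, y) in enumerate(pos):
        x0, y0 = int(round(x)), int(round(y))
        xs = slice(max(0, x0 - half), min(w, x0 + half + 1))
        ys = slice(max(0, y0 - half), min(h, y0 + half + 1))
        out[i] = flow_t[ys, xs].reshape(-1, 2).mean(axis=0)
    return out


def track_superpixels(frames: np.ndarray, n_superpixels: int = 1000,
                      direction: str = "forward", flow: np.ndarray = None,
                      reseed: bool = True, radius: int = 7) -> TrackSet:
    """Dense superpixel tracking through the flow field.

    Initial centroids sit on a regular grid with count closest to
    ``n_superpixels``; each step moves a track by the mean flow in a
    superpixel-sized window around it.  ``direction="reverse"`` tracks the
    time-reversed video.  After each step, grid cells left without any
    track receive a newly seeded track (dense coverage for cells entering
    the field of view).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if direction == "reverse":
        frames = frames[::-1]
    elif direction != "forward":
        raise ValueError(f"unknown direction {direction!r}")
    if flow is None:
        flow = dense_flow(frames, radius=radius)
    nf = frames.shape[0]
    h, w = frames.shape[1:]
    pts, width, ny, nx = _grid_centroids(h, w, n_superpixels)
    half = max(1, int(round(width / 2)))

    birth = list(np.zeros(len(pts), dtype=int))
    n_existing = len(pts)
    history = np.full((len(pts), nf, 2), np.nan)
    history[:, 0] = pts
    for t in range(nf - 1):
        cur = history[:n_existing, t]
        step = _window_mean_flow(flow[t], cur, half)
        nxt = cur + step
        nxt[:, 0] = np.clip(nxt[:, 0], 0, w - 1)
        nxt[:, 1] = np.clip(nxt[:, 1], 0, h - 1)
        history[:n_existing, t + 1] = nxt
        if reseed:
            cells = set(zip(np.minimum((nxt[:, 1] * ny / h).astype(int), ny - 1),
                            np.minimum((nxt[:, 0] * nx / w).astype(int), nx - 1)))
            empty = [(r, c) for r in range(ny) for c in range(nx)
                     if (r, c) not in cells]
            if empty:
                new = np.array([[(c + 0.5) * w / nx, (r + 0.5) * h / ny]
                                for r, c in empty])
                add = np.full((len(new), nf, 2), np.nan)
                add[:, t + 1] = new
                history = np.concatenate([history, add], axis=0)
                birth.extend([t + 1] * len(new))
                n_existing += len(new)
    return TrackSet(history, np.asarray(birth), width, direction, (h, w))


# -------------------------------------------------------------------- mesh

@dataclass
class MotionMesh:
    """Neighbour graph between tracks, frozen at the tracking start."""

    edges: np.ndarray            # (n_edges, 2) track indices
    rest_lengths: np.ndarray     # undeformed edge lengths L_e(0)


def build_mesh(tracks: TrackSet, factor: float = 1.2) -> MotionMesh:
    """Join each start-frame track to neighbours closer than
    ``factor`` x mean superpixel width at the start frame."""
    alive = np.flatnonzero(tracks.birth == 0)
    pts = tracks.positions[alive, 0]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(factor * tracks.superpixel_width,
                             output_type="ndarray")
    if len(pairs) == 0:
        return MotionMesh(np.empty((0, 2), dtype=int), np.empty(0))
    edges = alive[pairs]
    rest = np.linalg.norm(tracks.positions[edges[:, 0], 0]
                          - tracks.positions[edges[:, 1], 0], axis=1)
    keep = rest > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-length edges excluded")
    return MotionMesh(edges[keep], rest[keep])


def mesh_strain_curve(mesh: MotionMesh, tracks: TrackSet,
                      relative: bool = True) -> np.ndarray:
    """Mean absolute change of mesh edge lengths per frame.

    ``relative=True`` (default) divides each edge's deviation by its
    undeformed length; strain(0) = 0 by construction and rigid motion
    (translation or rotation of all tracks) keeps the curve at 0.
    """
    if len(mesh.edges) == 0:
        raise ValueError("empty mesh")
    a = tracks.positions[mesh.edges[:, 0]]
    b = tracks.positions[mesh.edges[:, 1]]
    lengths = np.linalg.norm(a - b, axis=2)      # (n_edges, n_frames)
    dev = np.abs(lengths - mesh.rest_lengths[:, None])
    if relative:
        dev = dev / mesh.rest_lengths[:, None]
    return dev.mean(axis=0)


# ---------------------------------------------------------------- saliency

@dataclass
class SaliencyMap:
    """Smoothed terminal-track density in [0, 1]; ``kind="sink"`` from
    forward tracking, ``kind="source"`` from reverse tracking."""

    values: np.ndarray
    kind: str
    median_coord: tuple          # (x, y) of pixels above the 95th percentile


def motion_saliency(tracks: TrackSet, kind: str,
                    percentile: float = 95.0) -> SaliencyMap:
    """Terminal-position density map, Gaussian-smoothed with
    sigma = superpixel width and max-normalized."""
    if kind not in ("source", "sink"):
        raise ValueError("kind must be 'source' or 'sink'")
    expected = "reverse" if kind == "source" else "forward"
    if tracks.direction != expected:
        warnings.warn(f"{kind} maps are conventionally built from "
                      f"{expected} tracking (got {tracks.direction})")
    if tracks.n_tracks == 0:
        raise ValueError("no tracks")
    h, w = tracks.frame_shape
    final = tracks.positions[:, -1]
    final = final[np.isfinite(final).all(axis=1)]
    hist = np.zeros((h, w))
    ix = np.clip(np.round(final[:, 0]).astype(int), 0, w - 1)
    iy = np.clip(np.round(final[:, 1]).astype(int), 0, h - 1)
    np.add.at(hist, (iy, ix), 1.0)
    sal = ndimage.gaussian_filter(hist, sigma=tracks.superpixel_width)
    mx = sal.max()
    if mx > 0:
        sal = sal / mx
    thr = np.percentile(sal, percentile)
    ys, xs = np.nonzero(sal > thr)
    if len(xs) == 0:
        ys, xs = np.nonzero(sal >= thr)
    return SaliencyMap(sal, kind, (float(np.median(xs)), float(np.median(ys))))


# -------------------------------------------------------------- signatures

def motion_signature(forward: np.ndarray, reverse: np.ndarray,
                     common_frames: int) -> np.ndarray:
    """Concatenate forward then reverse strain curves, each truncated to
    ``common_frames`` (trailing frames dropped); length 2*common_frames."""
    forward = np.asarray(forward, float)
    reverse = np.asarray(reverse, float)
    if len(forward) < common_frames or len(reverse) < common_frames:
        raise ValueError("strain curve shorter than common_frames")
    return np.concatenate([forward[:common_frames], reverse[:common_frames]])


def embryo_signature(frames: np.ndarray, n_superpixels: int = 1000,
                     common_frames: int | None = None, radius: int = 7):
    """Forward + reverse strain curves and their concatenated signature
    for one video.  Returns ``(signature, forward_curve, reverse_curve)``."""
    curves = {}
    for direction in ("forward", "reverse"):
        tr = track_superpixels(frames, n_superpixels, direction,
                               radius=radius)
        mesh = build_mesh(tr)
        curves[direction] = mesh_strain_curve(mesh, tr)
    if common_frames is None:
        common_frames = len(curves["forward"])
    sig = motion_signature(curves["forward"], curves["reverse"],
                           common_frames)
    return sig, curves["forward"], curves["reverse"]


@dataclass
class PhenotypePCA:
    """PCA over embryo motion signatures."""

    scores: np.ndarray                 # embryos x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray               # components x signature dims
    labels: list = None

    def loading_halves(self, component: int = 0):
        """Forward and reverse halves of one component's loading vector,
        for temporal interpretation."""
        v = self.loadings[component]
        half = len(v) // 2
        return v[:half], v[half:]


def phenotype_pca(signatures, labels=None, n_components: int = 2
                  ) -> PhenotypePCA:
    """Column-centered PCA over embryos x signature dimensions.

    Components are capped at min(n_embryos - 1, n_dims); loadings have unit
    Euclidean norm.
    """
    x = np.asarray(signatures, float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need >= 3 embryo signatures of equal length")
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    loadings = vt[:n_components]
    for j in range(n_components):
        i = np.argmax(np.abs(loadings[j]))
        if loadings[j, i] < 0:
            loadings[j] *= -1
    scores = xc @ loadings.T
    return PhenotypePCA(scores, evr[:n_components], loadings,
                        list(labels) if labels is not None else None)
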