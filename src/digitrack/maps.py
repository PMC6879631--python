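"""Attention maps: fixation detection, duration-weighted KDE, group maps.

An attention map is the unity-normalized (max = 1) spatial density of
exploration over the analysis raster. The default raster is the original
picture space, 1280 x 1024 pixels, but every operation accepts an arbitrary
``(height, width)`` grid so that simulations can run at reduced scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Trajectory

__all__ = [
    "DEFAULT_RASTER",
    "FixationSet",
    "AttentionMap",
    "detect_fixations",
    "kde_attention_map",
    "group_map",
    "map_correlation",
]

#: (height, width) of the default analysis raster.
DEFAULT_RASTER = (1024, 1280)


class ConstantMapError(ValueError):
    """Correlation requested on a spatially constant map."""


@dataclass
class FixationSet:
    """Detected fixations for one subject on one picture."""

    xs: np.ndarray
    ys: np.ndarray
    onsets_s: np.ndarray
    durations_ms: np.ndarray
    subject_id: str = ""
    image_id: str = ""
    method: str = "eye"

    def __post_init__(self) -> None:
        self.xs = np.atleast_1d(np.asarray(self.xs, dtype=float))
        self.ys = np.atleast_1d(np.asarray(self.ys, dtype=float))
        self.onsets_s = np.atleast_1d(np.asarray(self.onsets_s, dtype=float))
        self.durations_ms = np.atleast_1d(
            np.asarray(self.durations_ms, dtype=float))
        n = len(self.xs)
        if not (len(self.ys) == len(self.onsets_s)
                == len(self.durations_ms) == n):
            raise ValueError("fixation arrays must have equal length")

    def __len__(self) -> int:
        return len(self.xs)


@dataclass
class AttentionMap:
    """Unity-normalized 2-D exploration density.

    Invariant: values lie in [0, 1] and the maximum is exactly 1 whenever
    any exploration mass exists. ``constant`` flags degenerate all-equal
    maps (e.g. a zero-weight saliency prediction).
    """

    grid: np.ndarray
    n_subjects: int = 1
    method: str = ""
    image_id: str = ""
    constant: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("attention map grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _unity_normalize(grid: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale so the maximum is 1; return (grid, is_constant)."""
    m = grid.max()
    if m <= 0 or np.allclose(grid, grid.flat[0]):
        return np.zeros_like(grid), True
    return grid / m, False


def detect_fixations(traj: Trajectory, radius_px: float = 50.0,
                     min_duration_ms: float = 50.0,
                     raster: tuple[int, int] | None = None) -> FixationSet:
    """Dispersion-style fixation filter.

    Scans the sample stream and grows a run while every incoming sample
    stays within ``radius_px`` of the running centroid; a run whose time
    span reaches ``min_duration_ms`` becomes a fixation at the centroid
    with the run's duration. Sampling gaps longer than ``min_duration_ms``
    split a run. When ``raster`` (height, width) is given, fixations whose
    centroid falls outside it are dropped.
    """
    t, x, y = traj.sample_times, traj.xs, traj.ys
    n = len(traj)
    fx, fy, fo, fd = [], [], [], []

    def close_run(i0: int, i1: int) -> None:
        # run is samples i0..i1 inclusive
        span_ms = (t[i1] - t[i0]) * 1000.0
        if span_ms < min_duration_ms:
            return
        cx = float(np.mean(x[i0:i1 + 1]))
        cy = float(np.mean(y[i0:i1 + 1]))
        if raster is not None:
            h, w = raster
            if not (0 <= cx < w and 0 <= cy < h):
                return
        fx.append(cx)
        fy.append(cy)
        fo.append(float(t[i0]))
        fd.append(span_ms)

    start = 0
    sx, sy = x[0], y[0]  # running sums
    for i in range(1, n):
        gap_ms = (t[i] - t[i - 1]) * 1000.0
        count = i - start
        cx, cy = sx / count, sy / count
        if gap_ms > min_duration_ms or np.hypot(x[i] - cx, y[i] - cy) > radius_px:
            close_run(start, i - 1)
            start = i
            sx, sy = x[i], y[i]
        else:
            sx += x[i]
            sy += y[i]
    close_run(start, n - 1)

    return FixationSet(np.array(fx), np.array(fy), np.array(fo),
                       np.array(fd), subject_id=traj.subject_id,
                       image_id=traj.image_id, method="eye")


def kde_attention_map(points_xy: np.ndarray, weights: np.ndarray | None = None,
                      bandwidth_px: float = 30.0,
                      raster: tuple[int, int] = DEFAULT_RASTER,
                      **meta) -> AttentionMap:
    """Gaussian kernel density of exploration, unity-normalized.

    density(p) = sum_i w_i * exp(-||p - x_i||^2 / (2 h^2)) evaluated at every
    raster pixel. The Gaussian kernel is separable, so the sum is evaluated
    as a single matrix product of per-axis kernel tables — algebraically
    identical to the brute-force per-pixel summation.

    ``points_xy`` is (n, 2) in (x, y) pixel coordinates; ``weights`` defaults
    to all ones (the convention for regularly sampled digit trajectories).
    """
    points_xy = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if points_xy.size == 0:
        raise ValueError("kde_attention_map requires at least one point")
    if points_xy.shape[1] != 2:
        raise ValueError("points_xy must be (n, 2)")
    n = len(points_xy)
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != n:
        raise ValueError("weights length must match points")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if weights.sum() <= 0:
        raise ValueError("total weight must be positive")

    h, w = raster
    ygrid = np.arange(h, dtype=float)
    xgrid = np.arange(w, dtype=float)
    inv = -1.0 / (2.0 * bandwidth_px ** 2)
    # ky[j, i] = w_i * exp(inv * (y_j - y_i)^2); kx[i, j] = exp(inv * (x_j - x_i)^2)
    ky = weights * np.exp(inv * (ygrid[:, None] - points_xy[:, 1]) ** 2)
    kx = np.exp(inv * (points_xy[:, 0][:, None] - xgrid) ** 2)
    grid = ky @ kx
    grid, const = _unity_normalize(grid)
    return AttentionMap(grid, n_subjects=1, constant=const, **meta)


def map_from_fixations(fixations: FixationSet, bandwidth_px: float = 30.0,
                       raster: tuple[int, int] = DEFAULT_RASTER) -> AttentionMap:
    """Duration-weighted KDE attention map from a fixation set."""
    pts = np.column_stack([fixations.xs, fixations.ys])
    return kde_attention_map(pts, fixations.durations_ms,
                             bandwidth_px=bandwidth_px, raster=raster,
                             method=fixations.method,
                             image_id=fixations.image_id)


def map_from_trajectory(traj: Trajectory, bandwidth_px: float = 30.0,
                        raster: tuple[int, int] = DEFAULT_RASTER) -> AttentionMap:
    """Equal-weight KDE over every retained trajectory sample."""
    pts = np.column_stack([traj.xs, traj.ys])
    return kde_attention_map(pts, None, bandwidth_px=bandwidth_px,
                             raster=raster, method="digit",
                             image_id=traj.image_id)


def group_map(maps: list[AttentionMap]) -> AttentionMap:
    """Pixelwise mean of per-subject maps, renormalized to max 1."""
    if not maps:
        raise ValueError("group_map requires at least one map")
    shape = maps[0].shape
    image_id = maps[0].image_id
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError(f"raster mismatch: {m.shape} vs {shape}")
        if m.image_id != image_id:
            raise ValueError("group_map inputs must share an image")
    mean = np.mean([m.grid for m in maps], axis=0)
    grid, const = _unity_normalize(mean)
    return AttentionMap(grid, n_subjects=sum(m.n_subjects for m in maps),
                        method=maps[0].method, image_id=image_id,
                        constant=const)


def map_correlation(a: AttentionMap | np.ndarray,
                    b: AttentionMap | np.ndarray) -> float:
    """Pearson correlation between two maps over all raster pixels."""
    ga = a.grid if isinstance(a, AttentionMap) else np.asarray(a, dtype=float)
    gb = b.grid if isinstance(b, AttentionMap) else np.asarray(b, dtype=float)
    if ga.shape != gb.shape:
        raise ValueError(f"raster mismatch: {ga.shape} vs {gb.shape}")
    va, vb = ga.ravel(), gb.ravel()
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ConstantMapError("correlation undefined for a constant map")
    va = va - va.mean()
    vb = vb - vb.mean()
    return float(va @ vb / np.sqrt((va @ va) * (vb @ vb)))
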