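"""Measurement procedures on dissected capsule segments.

Rehydrated locules are cut into longitudinal segments which bend as they
dry.  Each dried segment trace is fitted with a circle; its curvature is
kappa = 1/R.  Segment widths d_n place each segment on the locule
circumference via the cumulative-width positions
l_n = sum_{i<=n} d_i / sum_{i<=N} d_i.  Wet/dry thickness pairs quantify
the hygroscopic shrinkage of the mesocarp parenchyma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .profile import CurvatureProfile, NoMovementError

__all__ = [
    "SegmentTrace",
    "SegmentSeries",
    "SectionThicknessPair",
    "CircleFit",
    "fit_circle",
    "curvature_of",
    "relative_positions",
    "measure_curvature_profile",
    "ShrinkageResult",
    "shrinkage_ratio",
    "thickness_from_mask",
]

# Relative flatness below which a point cloud is declared a straight segment.
_STRAIGHT_RTOL = 1e-9


@dataclass(frozen=True)
class SegmentTrace:
    """Digitized 2-D points along one dried segment, plus its width d_n."""

    points: np.ndarray
    width_d: float
    segment_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("trace needs an (n>=3, 2) point array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trace points must be finite")
        if np.allclose(pts, pts[0]):
            raise ValueError("trace points are all coincident")
        if not self.width_d > 0.0:
            raise ValueError("segment width d must be > 0")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class SegmentSeries:
    """Ordered segment traces, anatomical order from the split region."""

    traces: tuple[SegmentTrace, ...]

    def __init__(self, traces) -> None:
        traces = tuple(traces)
        if not traces:
            raise ValueError("series needs at least one segment")
        object.__setattr__(self, "traces", traces)

    @property
    def widths(self) -> np.ndarray:
        return np.array([t.width_d for t in self.traces])


@dataclass(frozen=True)
class SectionThicknessPair:
    """Same-locus mesocarp thickness samples before and after drying."""

    wet: np.ndarray
    dry: np.ndarray

    def __post_init__(self) -> None:
        wet = np.asarray(self.wet, dtype=float)
        dry = np.asarray(self.dry, dtype=float)
        if wet.size == 0 or wet.size != dry.size:
            raise ValueError("wet and dry must be nonempty and of equal length")
        if np.any(wet <= 0.0) or np.any(dry <= 0.0):
            raise ValueError("thickness samples must be positive")
        object.__setattr__(self, "wet", wet)
        object.__setattr__(self, "dry", dry)


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: center, radius and RMS orthogonal residual.

    A collinear point set is reported with ``is_straight=True`` and an
    infinite radius rather than an error: the segment from the split
    region genuinely barely bends.
    """

    center: tuple[float, float]
    radius: float
    rms_residual: float
    is_straight: bool = False


def _kasa_circle(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit: linear least squares on x^2+y^2."""
    a = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:2]
    radius = math.sqrt(max(sol[2] + center @ center, 0.0))
    return center, radius


def fit_circle(points: np.ndarray) -> CircleFit:
    """Fit a circle to a point trace.

    Kasa algebraic solution refined by a geometric (orthogonal-distance)
    Levenberg-Marquardt iteration; exact on noise-free circular data and
    deterministic for a fixed input point order.  Collinear points give a
    straight-segment result with radius infinity.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    span = svals[0]
    if span == 0.0:
        raise ValueError("all points coincide; cannot fit a circle")
    if svals[1] / span < _STRAIGHT_RTOL:
        return CircleFit(
            center=(math.inf, math.inf),
            radius=math.inf,
            rms_residual=0.0,
            is_straight=True,
        )

    center0, _ = _kasa_circle(pts)

    def resid(c: np.ndarray) -> np.ndarray:
        d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        return d - d.mean()

    sol = least_squares(resid, center0, method="lm")
    center = sol.x
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    radius = float(d.mean())
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    return CircleFit(center=(float(center[0]), float(center[1])), radius=radius, rms_residual=rms)


def curvature_of(trace: SegmentTrace) -> float:
    """Segment curvature kappa = 1/R; a straight segment maps to kappa = 0."""
    fit = fit_circle(trace.points)
    if fit.is_straight:
        return 0.0
    return 1.0 / fit.radius


def relative_positions(series: SegmentSeries) -> np.ndarray:
    """Cumulative relative circumferential positions l_n = sum d_i / total.

    The last entry is exactly 1; the sequence is strictly increasing and
    invariant under uniform rescaling of the widths.
    """
    d = series.widths
    return np.cumsum(d) / d.sum()


def measure_curvature_profile(series: SegmentSeries) -> CurvatureProfile:
    """Measured curvature profile from a segment series.

    Each segment's curvature is paired with its midpoint position
    (l_n - d_n/2 / total width) and the profile is normalized by the
    maximum curvature over the segments.
    """
    d = series.widths
    l_n = relative_positions(series)
    s_mid = l_n - d / (2.0 * d.sum())
    kappa = np.array([curvature_of(t) for t in series.traces])
    if np.all(kappa == 0.0):
        raise NoMovementError("every segment is straight: no movement")
    return CurvatureProfile.from_kappa(s_mid, kappa)


@dataclass(frozen=True)
class ShrinkageResult:
    ratio_percent: float
    fold_change: float
    per_sample_ratios: np.ndarray
    swelling: bool


def shrinkage_ratio(pair: SectionThicknessPair) -> ShrinkageResult:
    """Dry-to-wet thickness ratio of the mesocarp.

    ``ratio_percent`` is 100 * mean(dry) / mean(wet); ``fold_change`` the
    reciprocal wet/dry factor (a ratio of 30% corresponds to a ~3.3-fold
    change).  Dry thicker than wet is allowed but flagged as swelling.
    """
    mean_wet = float(pair.wet.mean())
    mean_dry = float(pair.dry.mean())
    ratio = mean_dry / mean_wet
    return ShrinkageResult(
        ratio_percent=100.0 * ratio,
        fold_change=1.0 / ratio,
        per_sample_ratios=pair.dry / pair.wet,
        swelling=ratio > 1.0,
    )


def thickness_from_mask(mask: np.ndarray, axis: int = 0, min_rays: int = 20) -> np.ndarray:
    """Per-ray layer thickness from a binary section mask.

    Counts foreground pixels along ``axis`` (rays normal to a roughly
    axis-aligned layer band); rays that miss the layer are dropped.
    Intended for paired wet/dry masks feeding :func:`shrinkage_ratio`.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D binary image")
    counts = mask.sum(axis=axis).astype(float)
    counts = counts[counts > 0]
    if counts.size < min_rays:
        raise ValueError(
            f"only {counts.size} rays intersect the layer; need >= {min_rays}"
        )
    return counts
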