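"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: the canonical
graded thickness profile around a locule circumference, dried-segment
arc traces for the curvature measurement, polarized-light azimuth
fixtures for MFA estimation, and wet/dry thickness pairs for the
shrinkage measurement.  All generators are deterministic under a fixed
seed.

The canonical profile's knot values are fixture calibration, not
measured data: they are free parameters chosen once so that the
generated architecture shows a longitudinal-fiber monolayer at the
split region, a transverse-fiber + parenchyma zone with vanishing
longitudinal fibers near the vascular bundle (s ~ 0.8), mostly
longitudinal fibers again at the far side, and the strong negative
parenchyma/longitudinal-fiber thickness correlation characteristic of
the capsule wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .mfa import AzimuthMap, CellROI
from .morphometry import SectionThicknessPair, SegmentSeries, SegmentTrace
from .profile import CurvatureProfile, ThicknessProfile

__all__ = [
    "TRANSVERSE_MFA_DEG",
    "LONGITUDINAL_MFA_DEG",
    "DEFAULT_SHRINKAGE_RATIO",
    "ProfileSpec",
    "NoiseSpec",
    "canonical_profile",
    "arcs_from_profile",
    "azimuth_fixture",
    "shrinkage_fixture",
]

# Cohort-truth MFA defaults for the two fiber-cell types (degrees).
TRANSVERSE_MFA_DEG = 8.0
LONGITUDINAL_MFA_DEG = 12.0

# Default dry/wet mesocarp thickness ratio of the shrinkage fixture.
DEFAULT_SHRINKAGE_RATIO = 0.30

# Knot table: anatomical anchor -> (s, (X_M, X_L, X_T)).  Calibration
# values, see module docstring.
_DEFAULT_KNOTS: dict[str, tuple[float, tuple[float, float, float]]] = {
    "split": (0.0, (0.05, 0.90, 0.05)),
    "early": (0.26, (0.06, 0.71, 0.23)),
    "mid": (0.53, (0.41, 0.38, 0.21)),
    "vascular_bundle": (0.775, (0.55, 0.02, 0.43)),
    "post_bundle": (0.9, (0.13, 0.65, 0.22)),
    "far_side": (1.0, (0.09, 0.78, 0.13)),
}


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for the canonical graded thickness profile.

    ``n_stations`` equally spaced stations are placed at the midpoint
    grid s_i = (i + 1/2) / n, matching the midpoint convention used for
    dissected segments.  ``residual_sd`` adds station-level relative
    (multiplicative) Gaussian jitter to the fractions, renormalized
    afterwards; a coefficient of variation of a few percent emulates
    measurement scatter in layer-thickness readings.
    """

    n_stations: int = 20
    knots: dict[str, tuple[float, tuple[float, float, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_KNOTS)
    )
    residual_sd: float = 0.03
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_stations < 3:
            raise ValueError("need at least 3 stations")
        if self.residual_sd < 0.0:
            raise ValueError("residual_sd must be >= 0")
        for name, (s, fracs) in self.knots.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"knot {name!r}: position {s} outside [0, 1]")
            if any(f < 0.0 or f > 1.0 for f in fracs):
                raise ValueError(f"knot {name!r}: fractions outside [0, 1]")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError(f"knot {name!r}: fractions must sum to 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels for synthetic traces and azimuth maps."""

    arc_point_sd: float = 0.0
    mfa_noise_sd_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arc_point_sd < 0.0 or self.mfa_noise_sd_deg < 0.0:
            raise ValueError("noise levels must be >= 0")


def canonical_profile(spec: ProfileSpec | None = None) -> ThicknessProfile:
    """Generate the canonical graded thickness profile.

    Monotone-shape-preserving (PCHIP) interpolation through the knots,
    per layer component, sampled at the midpoint station grid, clipped
    to nonnegative values and renormalized to sum to 1 per station;
    optional jitter is applied and the fractions renormalized again.
    Deterministic for a fixed seed.
    """
    spec = spec or ProfileSpec()
    knots = sorted(spec.knots.values(), key=lambda kv: kv[0])
    s_k = np.array([k[0] for k in knots])
    x_k = np.array([k[1] for k in knots])  # (n_knots, 3)
    if np.any(np.diff(s_k) <= 0.0):
        raise ValueError("knot positions must be distinct")
    n = spec.n_stations
    s = (np.arange(n) + 0.5) / n
    interp = PchipInterpolator(s_k, x_k, axis=0, extrapolate=True)
    x = np.clip(interp(s), 0.0, None)
    x /= x.sum(axis=1, keepdims=True)
    if spec.residual_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        x = np.clip(x * (1.0 + rng.normal(0.0, spec.residual_sd, size=x.shape)), 0.0, None)
        x /= x.sum(axis=1, keepdims=True)
    return ThicknessProfile(s=s, X_M=x[:, 0], X_L=x[:, 1], X_T=x[:, 2])


def arcs_from_profile(
    curv: CurvatureProfile,
    n_segments: int = 20,
    arc_length: float = 1.0,
    noise: NoiseSpec | None = None,
    n_points: int = 25,
    circumference: float = 1.0,
) -> SegmentSeries:
    """Synthesize dried-segment traces realizing a curvature profile.

    The locule circumference is cut into ``n_segments`` equal-width
    segments; each trace is a circular arc of the curvature linearly
    interpolated from ``curv`` at the segment midpoint (a straight line
    for zero curvature), with a random rigid pose per segment and
    optional Gaussian coordinate noise.  With ``n_segments`` equal to
    the number of profile stations on the midpoint grid, segment
    midpoints coincide with the stations and the noiseless measurement
    round trip is exact.
    """
    if not np.all(np.isfinite(curv.kappa)):
        raise ValueError("curvature profile must be finite")
    if arc_length <= 0.0 or n_segments < 1:
        raise ValueError("arc_length must be > 0 and n_segments >= 1")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    width = circumference / n_segments
    mid_frac = (np.arange(n_segments) + 0.5) / n_segments
    kappas = np.interp(mid_frac, curv.s, curv.kappa)
    t = np.linspace(0.0, arc_length, n_points)
    traces = []
    for j, kappa in enumerate(kappas):
        if abs(kappa) < 1e-12:
            pts = np.column_stack([t, np.zeros_like(t)])
        else:
            pts = np.column_stack(
                [np.sin(kappa * t) / kappa, (1.0 - np.cos(kappa * t)) / kappa]
            )
        phi = rng.uniform(0.0, 2.0 * np.pi)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        shift = rng.uniform(-5.0, 5.0, size=2)
        pts = pts @ rot.T + shift
        if noise.arc_point_sd > 0.0:
            pts = pts + rng.normal(0.0, noise.arc_point_sd, size=pts.shape)
        traces.append(SegmentTrace(points=pts, width_d=width, segment_id=f"seg{j + 1}"))
    return SegmentSeries(traces)


def azimuth_fixture(
    true_mfa_deg: float,
    n_cells: int = 5,
    noise: NoiseSpec | None = None,
    cell_shape: tuple[int, int] = (24, 10),
    pad: int = 2,
) -> tuple[AzimuthMap, list[CellROI]]:
    """Synthetic polarized-light map with known MFA ground truth.

    Rectangular fiber-cell masks are laid out side by side, each with a
    different cell-axis angle.  Inside a cell the azimuth equals
    cell axis + true MFA + von Mises angular noise (sd
    ``noise.mfa_noise_sd_deg``); retardance is high inside the fiber
    masks and near zero in the background, mimicking the dark
    parenchyma.
    """
    if not 0.0 <= true_mfa_deg <= 90.0:
        raise ValueError("true_mfa_deg must lie in [0, 90]")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    ch, cw = cell_shape
    shape = (ch + 2 * pad, n_cells * (cw + 2 * pad))
    azimuth = rng.uniform(0.0, 180.0, size=shape)
    retardance = rng.uniform(0.0, 2.0, size=shape)
    rois: list[CellROI] = []
    sd_rad = np.deg2rad(noise.mfa_noise_sd_deg)
    for i in range(n_cells):
        mask = np.zeros(shape, dtype=bool)
        c0 = i * (cw + 2 * pad) + pad
        mask[pad : pad + ch, c0 : c0 + cw] = True
        axis = (10.0 + i * 180.0 / max(n_cells, 1) * 0.9) % 180.0
        if sd_rad > 0.0:
            delta = np.rad2deg(rng.vonmises(0.0, 1.0 / sd_rad**2, size=int(mask.sum())))
        else:
            delta = np.zeros(int(mask.sum()))
        azimuth[mask] = (axis + true_mfa_deg + delta) % 180.0
        retardance[mask] = rng.uniform(80.0, 135.0, size=int(mask.sum()))
        rois.append(CellROI(mask=mask, cell_axis_deg=axis, cell_id=f"cell{i + 1}"))
    return AzimuthMap(azimuth=azimuth, retardance=retardance), rois


def shrinkage_fixture(
    ratio: float = DEFAULT_SHRINKAGE_RATIO,
    n_samples: int = 20,
    noise_cv: float = 0.02,
    seed: int = 3,
    nominal_wet: float = 300.0,
) -> SectionThicknessPair:
    """Paired wet/dry mesocarp thickness samples at a known shrinkage ratio.

    Wet thicknesses are lognormal around ``nominal_wet`` (micrometres);
    dry thicknesses are wet * ratio with multiplicative Gaussian noise
    of coefficient of variation ``noise_cv``.
    """
    if ratio <= 0.0:
        raise ValueError("ratio must be > 0")
    if noise_cv < 0.0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    wet = rng.lognormal(mean=np.log(nominal_wet), sigma=0.15, size=n_samples)
    dry = wet * ratio * np.clip(1.0 + rng.normal(0.0, noise_cv, size=n_samples), 1e-6, None)
    return SectionThicknessPair(wet=wet, dry=dry)
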