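"""Cellulose microfibril angle (MFA) from polarized-light maps.

An LC-PolScope-style acquisition yields, per pixel, the slow-axis
azimuth (degrees, 180-degree periodic) and the retardance magnitude
(nm).  Crystalline cellulose is strongly birefringent, so bright
(high-retardance) pixels inside a fiber cell carry the orientation
signal while parenchyma stays dark.  The MFA of a cell is the acute
angle between the microfibril azimuth and the cell's long axis.

All circular statistics treat angles as axial (180-degree periodic)
data via angle doubling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AzimuthMap",
    "CellROI",
    "DarkCellError",
    "MfaAggregate",
    "estimate_cell_mfa",
    "aggregate_mfa",
]


class DarkCellError(ValueError):
    """Cell mask has too few pixels above the retardance noise floor."""


@dataclass(frozen=True)
class AzimuthMap:
    """Paired slow-axis azimuth (degrees in [0, 180)) and retardance grids."""

    azimuth: np.ndarray
    retardance: np.ndarray

    def __post_init__(self) -> None:
        az = np.asarray(self.azimuth, dtype=float)
        ret = np.asarray(self.retardance, dtype=float)
        if az.shape != ret.shape or az.ndim != 2:
            raise ValueError("azimuth and retardance must be 2-D grids of one shape")
        if np.any(ret < 0.0):
            raise ValueError("retardance must be nonnegative")
        if np.any((az < 0.0) | (az >= 180.0)):
            raise ValueError("azimuth must lie in [0, 180) degrees")
        object.__setattr__(self, "azimuth", az)
        object.__setattr__(self, "retardance", ret)

    def default_noise_floor(self) -> float:
        """5% of the 95th percentile of the retardance map."""
        return 0.05 * float(np.percentile(self.retardance, 95.0))


@dataclass(frozen=True)
class CellROI:
    """Binary mask of one fiber cell and its long-axis angle (degrees)."""

    mask: np.ndarray
    cell_axis_deg: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("ROI mask must be a nonempty 2-D binary mask")
        if not 0.0 <= self.cell_axis_deg < 180.0:
            raise ValueError("cell_axis_deg must lie in [0, 180)")
        object.__setattr__(self, "mask", mask)


def _fold_axial(delta_deg: np.ndarray) -> np.ndarray:
    """Fold angle differences of a 180-periodic quantity into [-90, 90)."""
    return (np.asarray(delta_deg, dtype=float) + 90.0) % 180.0 - 90.0


def _axial_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of axial angles via doubling, in (-90, 90]."""
    doubled = np.deg2rad(2.0 * np.asarray(angles_deg, dtype=float))
    return math.degrees(math.atan2(np.mean(np.sin(doubled)), np.mean(np.cos(doubled)))) / 2.0


def estimate_cell_mfa(
    amap: AzimuthMap,
    roi: CellROI,
    n_points: int = 3,
    noise_floor: float | None = None,
    rng: np.random.Generator | None = None,
    sampling: str = "top",
) -> float:
    """MFA of one fiber cell, in degrees within [0, 90].

    Samples ``n_points`` pixels inside the ROI (default: the highest-
    retardance pixels, ties broken by grid order; ``sampling="random"``
    draws uniformly from above-floor pixels using ``rng``), folds the
    azimuth-minus-cell-axis differences to [-90, 90) and returns the
    absolute axial circular mean.  The result is invariant to rotating
    both the azimuth map and the cell axis by a common angle.

    Raises
    ------
    DarkCellError
        If fewer than ``n_points`` mask pixels exceed the retardance
        noise floor (the parenchyma, for instance, stays dark).
    """
    if noise_floor is None:
        noise_floor = amap.default_noise_floor()
    flat_ok = np.flatnonzero(roi.mask.ravel() & (amap.retardance.ravel() > noise_floor))
    if flat_ok.size < n_points:
        raise DarkCellError(
            f"cell {roi.cell_id!r}: {flat_ok.size} pixels above retardance floor "
            f"{noise_floor:.3g}, need {n_points} (dark cell)"
        )
    if sampling == "top":
        ret_vals = amap.retardance.ravel()[flat_ok]
        # stable sort on descending retardance keeps grid order among ties
        order = np.argsort(-ret_vals, kind="stable")
        chosen = flat_ok[order[:n_points]]
    elif sampling == "random":
        if rng is None:
            raise ValueError("random sampling requires an explicit rng")
        chosen = rng.choice(flat_ok, size=n_points, replace=False)
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    az = amap.azimuth.ravel()[chosen]
    delta = _fold_axial(az - roi.cell_axis_deg)
    return abs(_axial_mean_deg(delta))


@dataclass(frozen=True)
class MfaAggregate:
    mean_deg: float
    sd_deg: float
    n: int
    below_sampling_floor: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.mean_deg:.1f} ± {self.sd_deg:.1f}° (n={self.n})"


def aggregate_mfa(mfas) -> MfaAggregate:
    """Cohort mean and spread of per-cell MFA values.

    Uses the axial circular mean and circular standard deviation
    (angles doubled for the 180-degree periodicity), reported in
    degrees.  Fewer than five cells is flagged (below the customary
    sampling floor) but not an error.
    """
    vals = np.asarray(list(mfas), dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one cell")
    doubled = np.deg2rad(2.0 * vals)
    z = np.mean(np.exp(1j * doubled))
    mean = math.degrees(np.angle(z)) / 2.0 % 180.0
    if mean > 90.0:
        mean -= 180.0
    mean = abs(mean)
    rbar = min(max(abs(z), 1e-300), 1.0)
    sd = math.degrees(math.sqrt(-2.0 * math.log(rbar))) / 2.0
    return MfaAggregate(
        mean_deg=float(mean),
        sd_deg=float(sd),
        n=int(vals.size),
        below_sampling_floor=vals.size < 5,
    )
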