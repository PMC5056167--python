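"""Circumferential thickness profiles and predicted curvature profiles.

The capsule wall architecture is functionally graded: the relative
thicknesses of the mesocarp parenchyma (X_M), longitudinal fiber layer
(X_L) and transverse fiber layer (X_T) vary with position ``s`` along
the locule circumference (``s`` in [0, 1], measured from the split
region).  Each station defines a local laminate; solving the free
hygro-elastic problem station by station yields the predicted
longitudinal curvature profile, normalized by its maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .laminate import (
    ElasticLayer,
    Laminate,
    ModelParams,
    isotropic_layer,
    solve_free_hygro,
)

__all__ = [
    "ThicknessProfile",
    "CurvatureProfile",
    "NoMovementError",
    "station_laminate",
    "predict_curvature_profile",
    "peak_location",
    "anticorrelation_stats",
    "compare_profiles",
]

_SUM_TOL = 1e-9


class NoMovementError(ValueError):
    """Raised when every station of a curvature profile is zero."""


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-station relative layer thicknesses along the locule circumference.

    ``s`` is strictly increasing in [0, 1]; at every station the three
    fractions are nonnegative and sum to 1.
    """

    s: np.ndarray
    X_M: np.ndarray
    X_L: np.ndarray
    X_T: np.ndarray

    def __post_init__(self) -> None:
        for name in ("s", "X_M", "X_L", "X_T"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.s.size
        if n == 0:
            raise ValueError("profile needs at least one station")
        if any(getattr(self, name).size != n for name in ("X_M", "X_L", "X_T")):
            raise ValueError("s, X_M, X_L, X_T must have equal length")
        if np.any(np.diff(self.s) <= 0.0):
            raise ValueError("station positions s must be strictly increasing")
        if self.s[0] < 0.0 or self.s[-1] > 1.0:
            raise ValueError("station positions must lie in [0, 1]")
        x = self.fractions
        if np.any(x < 0.0):
            bad = int(np.argwhere(np.any(x < 0.0, axis=1))[0, 0])
            raise ValueError(f"negative thickness fraction at station {bad}")
        sums = x.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _SUM_TOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"fractions at station {bad} (s={self.s[bad]:.4g}) sum to "
                f"{sums[bad]:.6g}, expected 1"
            )

    @property
    def fractions(self) -> np.ndarray:
        """(n_stations, 3) array of columns (X_M, X_L, X_T)."""
        return np.column_stack([self.X_M, self.X_L, self.X_T])

    @property
    def n_stations(self) -> int:
        return self.s.size


@dataclass(frozen=True)
class CurvatureProfile:
    """Predicted or measured longitudinal curvature per station.

    ``kappa_norm`` is ``kappa`` divided by the maximum over stations
    (all zeros when no station moves).
    """

    s: np.ndarray
    kappa: np.ndarray
    kappa_norm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("s", "kappa", "kappa_norm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.s.size == 0:
            raise ValueError("curvature profile needs at least one station")
        if np.any(np.diff(self.s) <= 0.0):
            raise ValueError("station positions s must be strictly increasing")

    @classmethod
    def from_kappa(cls, s, kappa) -> "CurvatureProfile":
        kappa = np.asarray(kappa, dtype=float)
        kmax = kappa.max() if kappa.size else 0.0
        norm = kappa / kmax if kmax != 0.0 else np.zeros_like(kappa)
        return cls(s=np.asarray(s, dtype=float), kappa=kappa, kappa_norm=norm)

    @property
    def moves(self) -> bool:
        return bool(np.any(self.kappa != 0.0))


def station_laminate(
    profile: ThicknessProfile, index: int, params: ModelParams | None = None
) -> Laminate:
    """Build the local three-layer laminate at one station.

    Inner to outer: transverse fibers (90 deg), longitudinal fibers
    (0 deg), parenchyma (quasi-isotropic, hygroscopically active).
    Zero-thickness layers are dropped to keep the ABD well conditioned.
    """
    params = params or ModelParams()
    x_m = float(profile.X_M[index])
    x_l = float(profile.X_L[index])
    x_t = float(profile.X_T[index])
    if x_m + x_l + x_t <= 0.0:
        raise ValueError(f"station {index}: all three layer fractions are zero")
    h = params.total_wall_thickness
    nu = params.nu_default
    layers: list[ElasticLayer] = []
    if x_t > 0.0:
        layers.append(
            ElasticLayer(
                thickness=x_t * h,
                orientation_deg=90.0,
                E_parallel=params.E_axial,
                E_perp=params.E_perp,
                nu12=nu,
                name="transverse_fibers",
            )
        )
    if x_l > 0.0:
        layers.append(
            ElasticLayer(
                thickness=x_l * h,
                orientation_deg=0.0,
                E_parallel=params.E_axial,
                E_perp=params.E_perp,
                nu12=nu,
                name="longitudinal_fibers",
            )
        )
    if x_m > 0.0:
        layers.append(
            isotropic_layer(
                thickness=x_m * h,
                E=params.E_parenchyma,
                nu=nu,
                hygro_strain=params.eps_parenchyma,
                name="parenchyma",
            )
        )
    return Laminate(layers)


def predict_curvature_profile(
    profile: ThicknessProfile, params: ModelParams | None = None
) -> CurvatureProfile:
    """Predicted longitudinal curvature at each station, normalized by the max.

    Deterministic: the per-station laminate solve has no random element.
    """
    params = params or ModelParams()
    kappa = np.empty(profile.n_stations)
    for i in range(profile.n_stations):
        try:
            lam = station_laminate(profile, i, params)
            kappa[i] = solve_free_hygro(lam).kappa_L
        except ValueError as exc:
            raise ValueError(f"station {i} (s={profile.s[i]:.4g}): {exc}") from exc
    return CurvatureProfile.from_kappa(profile.s, kappa)


def peak_location(curv: CurvatureProfile) -> float:
    """Station position of the maximum curvature (ties -> smallest s)."""
    if not curv.moves:
        raise NoMovementError("all stations have zero curvature: no movement")
    return float(curv.s[int(np.argmax(curv.kappa))])


@dataclass(frozen=True)
class CorrelationStats:
    r2_M_vs_L: float
    r2_M_vs_T: float
    sign_M_vs_L: int
    sign_M_vs_T: int
    undefined: bool = False


def anticorrelation_stats(profile: ThicknessProfile) -> CorrelationStats:
    """Squared Pearson correlations of X_M against X_L and X_T across stations.

    The capsule architecture trades parenchyma against longitudinal
    fibers, so X_M vs X_L is expected strongly negative while X_M vs X_T
    is weak.  A zero-variance series yields NaN correlations with the
    ``undefined`` flag set.
    """
    if profile.n_stations < 3:
        raise ValueError("need at least 3 stations for correlation statistics")
    out = {}
    undefined = False
    for key, other in (("L", profile.X_L), ("T", profile.X_T)):
        if np.std(profile.X_M) == 0.0 or np.std(other) == 0.0:
            out[key] = (math.nan, 0)
            undefined = True
            continue
        r = stats.pearsonr(profile.X_M, other).statistic
        out[key] = (r * r, int(np.sign(r)))
    return CorrelationStats(
        r2_M_vs_L=out["L"][0],
        r2_M_vs_T=out["T"][0],
        sign_M_vs_L=out["L"][1],
        sign_M_vs_T=out["T"][1],
        undefined=undefined,
    )


@dataclass(frozen=True)
class ProfileComparison:
    rmse_norm: float
    pearson_r: float
    delta_peak_s: float
    n_common: int


def compare_profiles(
    predicted: CurvatureProfile, measured: CurvatureProfile
) -> ProfileComparison:
    """Compare normalized curvature profiles on the predicted stations.

    Measured stations are linearly interpolated onto the predicted ``s``
    (restricted to the overlap of the two ranges).  Returns the RMSE of
    the normalized curvature, the Pearson correlation (NaN when either
    series is constant) and the difference of peak locations.
    """
    lo = max(predicted.s[0], measured.s[0])
    hi = min(predicted.s[-1], measured.s[-1])
    if lo > hi:
        raise ValueError("predicted and measured profiles cover disjoint s ranges")
    sel = (predicted.s >= lo - 1e-12) & (predicted.s <= hi + 1e-12)
    s_common = predicted.s[sel]
    p = predicted.kappa_norm[sel]
    m = np.interp(s_common, measured.s, measured.kappa_norm)
    rmse = float(np.sqrt(np.mean((p - m) ** 2)))
    if np.std(p) == 0.0 or np.std(m) == 0.0:
        r = math.nan
    else:
        r = float(stats.pearsonr(p, m).statistic)
    delta = peak_location(predicted) - peak_location(measured)
    return ProfileComparison(
        rmse_norm=rmse, pearson_r=r, delta_peak_s=float(delta), n_common=int(sel.sum())
    )
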