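"""Hygro-elastic classical laminate plate mechanics.

The capsule wall is modelled as a thin laminated plate of orthotropic
layers.  Each layer carries an in-plane stiffness (plane stress) and an
isotropic free hygroscopic strain; drying loads enter as hygroscopic
force/moment resultants and the free deformation follows from the
standard ABD relation

    [[A, B], [B, D]] . (eps0, kappa) = (N_h, M_h)

Sign convention: x is the capsule longitudinal axis, y the
circumferential direction and z runs from the inner (endocarp) surface
outward.  Reported curvatures are positive when the outer (mesocarp)
face becomes concave, so a shrinking outer parenchyma layer yields a
positive longitudinal curvature kappa_L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StiffnessError",
    "SingularLaminateError",
    "ElasticLayer",
    "isotropic_layer",
    "Laminate",
    "PlateState",
    "ModelParams",
    "reduced_stiffness",
    "effective_fiber_moduli",
    "assemble_abd",
    "hygro_resultants",
    "solve_free_hygro",
    "timoshenko_bilayer_curvature",
]


class StiffnessError(ValueError):
    """Layer elastic constants do not define a positive-definite stiffness."""


class SingularLaminateError(np.linalg.LinAlgError):
    """The assembled ABD matrix is singular or numerically unusable."""


@dataclass(frozen=True)
class ElasticLayer:
    """One tissue lamina of the capsule wall.

    Parameters
    ----------
    thickness : float
        Layer thickness, in the common length unit of the stack.
    orientation_deg : float
        Fiber-axis angle from the capsule longitudinal axis, in degrees
        (0 = longitudinal fibers, 90 = transverse fibers).
    E_parallel, E_perp : float
        Young's moduli along / across the fiber axis (relative units are
        fine; only stiffness ratios matter for normalized curvature).
    nu12 : float
        Major in-plane Poisson ratio.
    G12 : float or None
        In-plane shear modulus; ``None`` selects the isotropic-like
        default ``E_perp / (2 (1 + nu12))``.
    hygro_strain : float
        Isotropic in-plane free strain on drying/wetting (negative =
        shrinkage on drying).
    name : str
        Optional label used in error messages.
    """

    thickness: float
    orientation_deg: float = 0.0
    E_parallel: float = 1.0
    E_perp: float = 1.0
    nu12: float = 0.3
    G12: float | None = None
    hygro_strain: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.thickness > 0.0 and math.isfinite(self.thickness)):
            raise StiffnessError(f"layer {self.name!r}: thickness must be > 0")
        if not (self.E_perp > 0.0 and self.E_parallel >= self.E_perp):
            raise StiffnessError(
                f"layer {self.name!r}: need E_parallel >= E_perp > 0, "
                f"got ({self.E_parallel}, {self.E_perp})"
            )
        nu_max = math.sqrt(self.E_parallel / self.E_perp)
        if not (0.0 <= self.nu12 < nu_max):
            raise StiffnessError(
                f"layer {self.name!r}: nu12={self.nu12} outside [0, "
                f"sqrt(E_parallel/E_perp)={nu_max:.4g}); stiffness would not "
                "be positive definite"
            )
        if self.G12 is not None and not self.G12 > 0.0:
            raise StiffnessError(f"layer {self.name!r}: G12 must be > 0")
        if not math.isfinite(self.hygro_strain):
            raise StiffnessError(f"layer {self.name!r}: hygro_strain not finite")

    @property
    def shear_modulus(self) -> float:
        if self.G12 is not None:
            return self.G12
        return self.E_perp / (2.0 * (1.0 + self.nu12))


def isotropic_layer(
    thickness: float,
    E: float,
    nu: float = 0.3,
    hygro_strain: float = 0.0,
    name: str = "",
) -> ElasticLayer:
    """Convenience constructor for a quasi-isotropic (parenchyma-like) layer."""
    return ElasticLayer(
        thickness=thickness,
        orientation_deg=0.0,
        E_parallel=E,
        E_perp=E,
        nu12=nu,
        G12=E / (2.0 * (1.0 + nu)),
        hygro_strain=hygro_strain,
        name=name,
    )


@dataclass(frozen=True)
class Laminate:
    """Ordered stack of layers, inner surface first.

    ``z_ref`` places the reference plane of the ABD bookkeeping: the
    string ``"midplane"`` (default) or a float offset measured from the
    inner surface.  The physical free curvature is independent of this
    choice.
    """

    layers: tuple[ElasticLayer, ...]
    z_ref: str | float = "midplane"

    def __init__(self, layers, z_ref: str | float = "midplane") -> None:
        layers = tuple(layers)
        if not layers:
            raise ValueError("laminate needs at least one layer")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "z_ref", z_ref)

    @property
    def total_thickness(self) -> float:
        return float(sum(layer.thickness for layer in self.layers))

    @property
    def z_interfaces(self) -> np.ndarray:
        """Interface coordinates z_0 < ... < z_n relative to the reference plane."""
        h = self.total_thickness
        if self.z_ref == "midplane":
            offset = h / 2.0
        else:
            offset = float(self.z_ref)
        edges = np.concatenate(
            ([0.0], np.cumsum([layer.thickness for layer in self.layers]))
        )
        return edges - offset


@dataclass(frozen=True)
class PlateState:
    """Free-deformation solution of the plate.

    ``midplane_strains`` is (eps_x, eps_y, gamma_xy) at the reference
    plane; ``curvatures`` is (kappa_x, kappa_y, kappa_xy) with kappa_x
    the longitudinal curvature kappa_L (positive = outer face concave).
    """

    midplane_strains: np.ndarray
    curvatures: np.ndarray

    @property
    def kappa_L(self) -> float:
        return float(self.curvatures[0])

    @property
    def kappa_T(self) -> float:
        return float(self.curvatures[1])


@dataclass(frozen=True)
class ModelParams:
    """Default material parameters of the capsule-wall model.

    The stiffness triplet (E along fibers, E across fibers, E of the
    parenchymatous mesocarp) defaults to the relative values 20 : 5 : 0.1.
    Only the parenchyma carries a hygroscopic strain; its default in-plane
    drying strain is -0.7 (shrinkage).  Because the free curvature is
    linear in the hygroscopic strain, the normalized curvature profile
    does not depend on that magnitude.
    """

    stiffness_triplet: tuple[float, float, float] = (20.0, 5.0, 0.1)
    nu_default: float = 0.3
    eps_parenchyma: float = -0.7
    total_wall_thickness: float = 1.0

    def __post_init__(self) -> None:
        if any(not (e > 0.0) for e in self.stiffness_triplet):
            raise ValueError("all moduli in stiffness_triplet must be > 0")
        if not self.eps_parenchyma > -1.0:
            raise ValueError("eps_parenchyma must exceed -1 (cannot shrink past zero)")
        if not self.total_wall_thickness > 0.0:
            raise ValueError("total_wall_thickness must be > 0")

    @property
    def E_axial(self) -> float:
        return self.stiffness_triplet[0]

    @property
    def E_perp(self) -> float:
        return self.stiffness_triplet[1]

    @property
    def E_parenchyma(self) -> float:
        return self.stiffness_triplet[2]


def reduced_stiffness(layer: ElasticLayer) -> np.ndarray:
    """Plane-stress stiffness of a layer, rotated into laminate axes.

    Returns the 3x3 matrix Q-bar relating (sigma_x, sigma_y, tau_xy) to
    engineering strains (eps_x, eps_y, gamma_xy) in the laminate frame.
    """
    e1, e2 = layer.E_parallel, layer.E_perp
    nu12 = layer.nu12
    nu21 = nu12 * e2 / e1
    denom = 1.0 - nu12 * nu21
    q11 = e1 / denom
    q22 = e2 / denom
    q12 = nu12 * e2 / denom
    q66 = layer.shear_modulus

    th = math.radians(layer.orientation_deg)
    c, s = math.cos(th), math.sin(th)
    c2, s2 = c * c, s * s
    c4, s4 = c2 * c2, s2 * s2

    qb11 = q11 * c4 + 2.0 * (q12 + 2.0 * q66) * s2 * c2 + q22 * s4
    qb22 = q11 * s4 + 2.0 * (q12 + 2.0 * q66) * s2 * c2 + q22 * c4
    qb12 = (q11 + q22 - 4.0 * q66) * s2 * c2 + q12 * (s4 + c4)
    qb16 = (q11 - q12 - 2.0 * q66) * s * c2 * c + (q12 - q22 + 2.0 * q66) * s2 * s * c
    qb26 = (q11 - q12 - 2.0 * q66) * s2 * s * c + (q12 - q22 + 2.0 * q66) * s * c2 * c
    qb66 = (q11 + q22 - 2.0 * q12 - 2.0 * q66) * s2 * c2 + q66 * (s4 + c4)

    qbar = np.array(
        [[qb11, qb12, qb16], [qb12, qb22, qb26], [qb16, qb26, qb66]], dtype=float
    )
    # Positive definiteness is implied by the layer invariants; verify anyway
    # so malformed inputs fail loudly here rather than in the ABD solve.
    if np.any(np.linalg.eigvalsh(qbar) <= 0.0):
        raise StiffnessError(
            f"layer {layer.name!r}: reduced stiffness not positive definite"
        )
    return qbar


def effective_fiber_moduli(
    E_fibril: float, E_matrix: float, volume_fraction: float
) -> tuple[float, float]:
    """Rule-of-mixtures moduli of a unidirectional fiber composite.

    The modulus along the fibers follows the Voigt (arithmetic) mixture,
    the modulus across them the Reuss (harmonic) mixture:

        E_parallel = vf * E_f + (1 - vf) * E_m
        E_perp     = 1 / (vf / E_f + (1 - vf) / E_m)
    """
    if not (E_fibril > 0.0 and E_matrix > 0.0):
        raise ValueError("moduli must be > 0")
    if not 0.0 <= volume_fraction <= 1.0:
        raise ValueError(f"volume_fraction {volume_fraction} outside [0, 1]")
    vf = volume_fraction
    e_par = vf * E_fibril + (1.0 - vf) * E_matrix
    e_perp = 1.0 / (vf / E_fibril + (1.0 - vf) / E_matrix)
    return e_par, e_perp


def assemble_abd(laminate: Laminate) -> np.ndarray:
    """Assemble the 6x6 ABD stiffness matrix [[A, B], [B, D]].

    A = sum Qbar_k (z_k - z_{k-1}),  B = 1/2 sum Qbar_k (z_k^2 - z_{k-1}^2),
    D = 1/3 sum Qbar_k (z_k^3 - z_{k-1}^3), about the reference plane.
    """
    z = laminate.z_interfaces
    a = np.zeros((3, 3))
    b = np.zeros((3, 3))
    d = np.zeros((3, 3))
    for k, layer in enumerate(laminate.layers):
        qbar = reduced_stiffness(layer)
        z0, z1 = z[k], z[k + 1]
        a += qbar * (z1 - z0)
        b += qbar * (z1**2 - z0**2) / 2.0
        d += qbar * (z1**3 - z0**3) / 3.0
    abd = np.block([[a, b], [b, d]])
    return abd


def hygro_resultants(laminate: Laminate) -> np.ndarray:
    """Hygroscopic force and moment resultants (N_h, M_h) as a 6-vector.

    Each layer contributes its isotropic free-strain vector
    beta_k = (eps, eps, 0), which is rotation invariant, weighted by the
    layer stiffness over its thickness span.
    """
    z = laminate.z_interfaces
    out = np.zeros(6)
    for k, layer in enumerate(laminate.layers):
        eps = layer.hygro_strain
        if eps == 0.0:
            continue
        qbar = reduced_stiffness(layer)
        beta = np.array([eps, eps, 0.0])
        qb = qbar @ beta
        z0, z1 = z[k], z[k + 1]
        out[:3] += qb * (z1 - z0)
        out[3:] += qb * (z1**2 - z0**2) / 2.0
    return out


def solve_free_hygro(laminate: Laminate) -> PlateState:
    """Free hygro-elastic deformation of an unconstrained laminate plate.

    Solves [[A, B], [B, D]] (eps0, kappa) = (N_h, M_h) and reports the
    curvatures in the capsule sign convention (positive kappa_x bends the
    outer face concave).  The solution is linear in the layer hygroscopic
    strains: scaling every hygro_strain by alpha scales the state by alpha.
    """
    abd = assemble_abd(laminate)
    rhs = hygro_resultants(laminate)
    cond = np.linalg.cond(abd)
    if not np.isfinite(cond) or cond > 1e12:
        names = [layer.name or f"layer{k}" for k, layer in enumerate(laminate.layers)]
        raise SingularLaminateError(
            f"ABD matrix numerically singular (cond={cond:.3g}) for stack {names}"
        )
    x = np.linalg.solve(abd, rhs)
    # Flip to the outward-bending-positive convention (see module docstring):
    # a shrinking layer at z > 0 then produces kappa_x > 0.
    return PlateState(midplane_strains=x[:3].copy(), curvatures=-x[3:].copy())


def timoshenko_bilayer_curvature(
    h1: float, h2: float, E1: float, E2: float, eps: float
) -> float:
    """Closed-form bimetal-strip curvature of an isotropic bilayer.

    Layer 1 (thickness ``h1``, modulus ``E1``) is the inner, hygroscopically
    active layer carrying free strain ``eps``; layer 2 is passive.  With
    m = h1/h2 and n = E1/E2:

        kappa = 6 eps (1+m)^2 / (h [3 (1+m)^2 + (1+mn)(m^2 + 1/(mn))])

    In the capsule sign convention an inner shrinking layer (eps < 0)
    bends the plate inward, so the returned curvature carries the sign
    of ``eps``.
    """
    if not (h1 > 0 and h2 > 0 and E1 > 0 and E2 > 0):
        raise ValueError("thicknesses and moduli must be > 0")
    m = h1 / h2
    n = E1 / E2
    h = h1 + h2
    denom = 3.0 * (1.0 + m) ** 2 + (1.0 + m * n) * (m * m + 1.0 / (m * n))
    return 6.0 * eps * (1.0 + m) ** 2 / (h * denom)
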