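"""Kinematics of inflation–extension of a residually stressed artery.

The reference configuration is the zero-stress state (ZSS): a radially
cut-open sector of the vessel wall characterized by inner/outer radii
``R_i``, ``R_o`` and opening angle ``Θ``.  Closing the sector and loading
it into a cylinder of outer radius ``r_o`` at axial stretch ``λ_z`` is an
axisymmetric, incompressible map, so the loaded radius of a material
point and the principal stretches follow in closed form.

Conventions used throughout the package:

* cylindrical basis ordered ``(θ, r, z)`` — index 0 circumferential,
  1 radial, 2 axial;
* angles measured from the circumferential direction;
* lengths in mm, stresses in MPa, pressures exposed in mmHg.

Under pure distension–extension the deformation gradient is diagonal in
this basis and all shear strain components vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferenceGeometry",
    "LoadedConfiguration",
    "DeformationPoint",
    "InvalidConfigurationError",
    "loaded_radius",
    "inner_radius",
    "stretches_at",
    "green_lagrange",
    "fiber_strain",
    "deformation_point",
]

#: θθ, rr, zz positions in the diagonal-tensor storage order.
I_THETA, I_R, I_Z = 0, 1, 2


class InvalidConfigurationError(ValueError):
    """Raised when a loaded configuration is kinematically inadmissible,

    e.g. the imposed outer radius is too small for the imposed axial
    stretch so the incompressible map would require negative r²."""


@dataclass(frozen=True)
class ReferenceGeometry:
    """Zero-stress-state sector geometry of the vessel wall.

    Parameters
    ----------
    r_outer, r_inner
        Outer and inner radii of the cut-open sector (mm).
    opening_angle
        Opening angle Θ of the sector (rad), in ``[0, π)``.
    length_ref
        Axial length L of the reference segment (mm).
    """

    r_outer: float
    r_inner: float
    opening_angle: float
    length_ref: float

    def __post_init__(self) -> None:
        if not (self.r_outer > self.r_inner > 0.0):
            raise ValueError(
                f"require R_outer > R_inner > 0, got {self.r_outer}, {self.r_inner}"
            )
        if not (0.0 <= self.opening_angle < np.pi):
            raise ValueError(f"opening angle must lie in [0, π), got {self.opening_angle}")
        if not self.length_ref > 0.0:
            raise ValueError("reference length must be positive")

    @property
    def wall_thickness(self) -> float:
        return self.r_outer - self.r_inner

    @property
    def sector_factor(self) -> float:
        """(π − Θ)/π — the circumferential closing factor of the sector."""
        return (np.pi - self.opening_angle) / np.pi


def loaded_radius(R_ref, geom: ReferenceGeometry, lam_z: float, r_outer: float):
    """Loaded radius r(R) of the material point at reference radius ``R_ref``.

    Incompressibility of the sector-to-cylinder map gives

        r(R) = sqrt( r_o² − (R_o² − R²)·(π − Θ)/(λ_z π) ).

    Accepts scalars or arrays.  Raises :class:`InvalidConfigurationError`
    when the square-root argument is negative (the imposed ``r_outer`` is
    too small for the imposed axial stretch).
    """
    R = np.asarray(R_ref, dtype=float)
    if np.any(R < geom.r_inner - 1e-12) or np.any(R > geom.r_outer + 1e-12):
        raise ValueError("R_ref outside the reference wall [R_inner, R_outer]")
    if lam_z <= 0.0:
        raise ValueError("axial stretch must be positive")
    arg = r_outer**2 - (geom.r_outer**2 - R**2) * geom.sector_factor / lam_z
    if np.any(arg < 0.0):
        raise InvalidConfigurationError(
            "negative squared radius: r_outer too small for the imposed axial stretch"
        )
    r = np.sqrt(arg)
    return r if r.ndim else float(r)


def inner_radius(geom: ReferenceGeometry, lam_z: float, r_outer: float) -> float:
    """Loaded inner radius r_i implied by incompressibility."""
    return float(loaded_radius(geom.r_inner, geom, lam_z, r_outer))


def stretches_at(R_ref, geom: ReferenceGeometry, lam_z: float, r_outer: float):
    """Principal stretches (λ_θ, λ_r, λ_z) at reference radius ``R_ref``.

    λ_θ = (π/(π−Θ))·r/R and λ_r = ∂r/∂R = R·(π−Θ)/(λ_z π r); the product
    λ_θ·λ_r·λ_z is identically 1 (incompressibility).
    """
    R = np.asarray(R_ref, dtype=float)
    if np.any(R <= 0.0):
        raise ValueError("reference radius must be positive")
    r = np.asarray(loaded_radius(R, geom, lam_z, r_outer))
    lam_t = r / (R * geom.sector_factor)
    lam_r = R * geom.sector_factor / (lam_z * r)
    lam_zz = np.full_like(lam_t, lam_z)
    if lam_t.ndim:
        return lam_t, lam_r, lam_zz
    return float(lam_t), float(lam_r), float(lam_zz)


def green_lagrange(stretches) -> np.ndarray:
    """Green–Lagrange strain tensor E = ½(FᵀF − I) for diagonal F.

    ``stretches`` is (λ_θ, λ_r, λ_z); the result is the full 3×3 tensor in
    the (θ, r, z) basis, diagonal with entries (λ²−1)/2.
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,):
        raise ValueError("expected three principal stretches")
    if np.any(lam <= 0.0):
        raise ValueError("stretches must be positive")
    return np.diag((lam**2 - 1.0) / 2.0)


def green_lagrange_diag(lam_t, lam_r, lam_z) -> np.ndarray:
    """Vectorized diagonal Green–Lagrange entries, shape (..., 3)."""
    lam = np.stack(np.broadcast_arrays(
        np.asarray(lam_t, float), np.asarray(lam_r, float), np.asarray(lam_z, float)
    ), axis=-1)
    return (lam**2 - 1.0) / 2.0


def fiber_strain(E, angle, plane: str = "circ-axial"):
    """Uniaxial strain e = E : N⊗N of a fiber at ``angle`` from circumferential.

    ``plane`` selects the plane containing the unit fiber direction N:
    ``"circ-axial"`` (θ–z, where adventitial/medial fibers and SMCs lie) or
    ``"circ-radial"`` (θ–r, where inter-lamellar elastin disperses).  Under
    the diagonal strain states produced by distension–extension the shear
    terms of the contraction vanish.
    """
    E = np.asarray(E, dtype=float)
    th = np.asarray(angle, dtype=float)
    c2, s2 = np.cos(th) ** 2, np.sin(th) ** 2
    if E.shape[-2:] == (3, 3):
        Ett, Err, Ezz = E[..., 0, 0], E[..., 1, 1], E[..., 2, 2]
    elif E.shape[-1] == 3:
        Ett, Err, Ezz = E[..., 0], E[..., 1], E[..., 2]
    else:
        raise ValueError("E must be a 3×3 tensor or a length-3 diagonal")
    if plane == "circ-axial":
        e = Ett * c2 + Ezz * s2
    elif plane == "circ-radial":
        e = Ett * c2 + Err * s2
    else:
        raise ValueError(f"unknown plane {plane!r}")
    return e if np.ndim(e) else float(e)


@dataclass(frozen=True)
class LoadedConfiguration:
    """A loaded cylindrical state: outer radius, axial stretch, derived inner radius."""

    r_outer: float
    axial_stretch: float
    r_inner: float
    length_loaded: float

    @classmethod
    def from_geometry(cls, geom: ReferenceGeometry, lam_z: float, r_outer: float
                      ) -> "LoadedConfiguration":
        return cls(
            r_outer=float(r_outer),
            axial_stretch=float(lam_z),
            r_inner=inner_radius(geom, lam_z, r_outer),
            length_loaded=float(lam_z * geom.length_ref),
        )


@dataclass(frozen=True)
class DeformationPoint:
    """Full kinematic state of one transmural material point."""

    R_ref: float
    r_cur: float
    stretches: tuple
    def_gradient: np.ndarray
    green_strain: np.ndarray


def deformation_point(R_ref: float, geom: ReferenceGeometry, lam_z: float,
                      r_outer: float) -> DeformationPoint:
    """Assemble the deformation state (F, E, stretches) at one point."""
    lam = stretches_at(R_ref, geom, lam_z, r_outer)
    return DeformationPoint(
        R_ref=float(R_ref),
        r_cur=float(loaded_radius(R_ref, geom, lam_z, r_outer)),
        stretches=lam,
        def_gradient=np.diag(lam),
        green_strain=green_lagrange(lam),
    )
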