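"""Triaxial active stress of contracting vascular smooth muscle cells.

A single SMC generates stress along three cell axes:

* longitudinal (major axis, lying in the θ–z plane at angle θ from
  circumferential): an asymmetric bell-shaped length–tension law

      σ(λ) = A·[ ½ρ₁ (λ_max^ρ₂ − λ^ρ₂ − 2)(λ − λ_max)² + σ_max ]

  peaking at σ_max when λ = λ_max; ρ₁ sets the curvature and ρ₂ the
  asymmetry (ρ₂ = 0 gives a symmetric curve, ρ₂ > 0 a gentler rise
  below the optimum than the fall above it);
* transverse (in-plane minor axis): the same law scaled by the
  dimensionless ratio τ;
* radial (out-of-plane minor axis): a linear simplification
  σ″ = A·k_SMC·λ_r, since radially the cells are compressed and the
  bell-shaped law would be evaluated far outside its calibrated range.

``A ∈ [0, 1]`` is the activation level (0 passive, 1 maximal K⁺-induced
contraction); every axis is gated by it so passive tissue carries no
active stress.  Far from λ_max the bell-shaped law can turn negative; by
default it is clamped at zero (a contracting cell is not assigned active
compression), switchable via ``clamp_negative``.

The cell-population 2nd Piola-Kirchhoff contribution averages, over the
mirrored SMC orientation family, the chain-rule terms
σ·∂λ/∂E + σ′·∂λ′/∂E + σ″·∂λ″/∂E with ∂λ/∂E = N⊗N/λ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .microstructure import MicrostructureConfig

__all__ = [
    "SMCActiveParams",
    "smc_longitudinal_stress",
    "smc_transverse_stress",
    "smc_radial_stress",
    "smc_second_pk",
]


@dataclass(frozen=True)
class SMCActiveParams:
    """Parameters of the triaxial SMC contraction laws.

    rho1 (MPa) and rho2 (–) shape the longitudinal length–tension curve;
    lam_max is the optimal stretch at which the peak stress sigma_max
    (MPa) is generated; tau scales the transverse law; k_smc_radial (MPa)
    is the linear radial stiffness; activation A ∈ [0, 1].
    """

    rho1: float
    rho2: float
    lam_max: float
    sigma_max: float
    tau: float
    k_smc_radial: float
    activation: float = 1.0
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.rho1 < 0.0 or self.sigma_max < 0.0 or self.k_smc_radial < 0.0:
            raise ValueError("rho1, sigma_max and k_smc_radial must be nonnegative")
        if not self.lam_max > 0.0:
            raise ValueError("optimal stretch lam_max must be positive")
        if self.tau < 0.0:
            raise ValueError("transverse ratio tau must be nonnegative")
        if not 0.0 <= self.activation <= 1.0:
            raise ValueError("activation must lie in [0, 1]")

    def with_activation(self, A: float) -> "SMCActiveParams":
        return replace(self, activation=float(A))


def _bell(lam, p: SMCActiveParams):
    lam = np.asarray(lam, dtype=float)
    bracket = p.lam_max**p.rho2 - lam**p.rho2 - 2.0
    s = 0.5 * p.rho1 * bracket * (lam - p.lam_max) ** 2 + p.sigma_max
    if p.clamp_negative:
        s = np.maximum(s, 0.0)
    return s


def smc_longitudinal_stress(lam, p: SMCActiveParams):
    """Active stress (MPa) along the cell major axis at stretch ``lam``."""
    if np.any(np.asarray(lam) <= 0.0):
        raise ValueError("stretch must be positive")
    out = p.activation * _bell(lam, p)
    return out if np.ndim(lam) else float(out)


def smc_transverse_stress(lam_t, p: SMCActiveParams):
    """Active stress (MPa) along the in-plane minor axis: τ times the
    longitudinal law at the transverse stretch."""
    if np.any(np.asarray(lam_t) <= 0.0):
        raise ValueError("stretch must be positive")
    out = p.tau * p.activation * _bell(lam_t, p)
    return out if np.ndim(lam_t) else float(out)


def smc_radial_stress(lam_r, p: SMCActiveParams):
    """Linear active radial stress σ″ = A·k_SMC·λ_r (MPa)."""
    if np.any(np.asarray(lam_r) <= 0.0):
        raise ValueError("stretch must be positive")
    out = p.activation * p.k_smc_radial * np.asarray(lam_r, dtype=float)
    return out if np.ndim(lam_r) else float(out)


def smc_second_pk_diag(E_diag: np.ndarray, micro: MicrostructureConfig,
                       p: SMCActiveParams, n_angle: int = 64) -> np.ndarray:
    """Vectorized SMC 2nd PK diagonal for stacked diagonal strains (..., 3).

    Cells lie in the θ–z plane with mirrored orientation families; under
    diagonal strain both mirrored halves contribute identically, so the
    expectation runs over the [0, π/2] family.  The radial cell stretch
    equals the wall radial stretch λ_r.
    """
    E_diag = np.asarray(E_diag, dtype=float)
    if p.activation == 0.0:
        return np.zeros(E_diag.shape[:-1] + (3,))
    th, w = micro.media_smc.quad(n_angle)
    c2, s2 = np.cos(th) ** 2, np.sin(th) ** 2
    Ctt = 1.0 + 2.0 * E_diag[..., 0]
    Crr = 1.0 + 2.0 * E_diag[..., 1]
    Czz = 1.0 + 2.0 * E_diag[..., 2]
    if np.any(Ctt <= 0.0) or np.any(Crr <= 0.0) or np.any(Czz <= 0.0):
        raise ValueError("strain state implies nonpositive squared stretch")
    lam = np.sqrt(Ctt[..., None] * c2 + Czz[..., None] * s2)     # n direction
    lam_t = np.sqrt(Ctt[..., None] * s2 + Czz[..., None] * c2)   # n′ direction
    lam_r = np.sqrt(Crr)
    sig_over_lam = p.activation * _bell(lam, p) / lam
    sigt_over_lam = p.tau * p.activation * _bell(lam_t, p) / lam_t
    out = np.zeros(E_diag.shape[:-1] + (3,))
    out[..., 0] = (sig_over_lam * c2 + sigt_over_lam * s2) @ w
    out[..., 2] = (sig_over_lam * s2 + sigt_over_lam * c2) @ w
    # radial: σ″·∂λ_r/∂E_rr = (A·k_SMC·λ_r)·(1/λ_r) = A·k_SMC, orientation-independent
    out[..., 1] = p.activation * p.k_smc_radial
    return out


def smc_second_pk(E, micro: MicrostructureConfig, p: SMCActiveParams,
                  n_angle: int = 64) -> np.ndarray:
    """SMC active 2nd Piola-Kirchhoff stress as a 3×3 tensor (MPa)."""
    E = np.asarray(E, dtype=float)
    if E.shape == (3, 3):
        diag = np.diagonal(E)
    elif E.shape == (3,):
        diag = E
    else:
        raise ValueError("E must be a 3×3 tensor or a length-3 diagonal")
    return np.diag(smc_second_pk_diag(diag, micro, p, n_angle))
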