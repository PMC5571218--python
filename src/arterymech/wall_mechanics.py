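"""Thick-walled tube mechanics of the two-layer artery wall.

Assembles the total 2nd Piola-Kirchhoff stress (volume-weighted sum of
passive fiber and active SMC contributions, layer-dependent), pushes it
forward to the extra Cauchy stress σ̂ = F·S·Fᵀ, and integrates radial
equilibrium

    dσ_rr/dr + (σ_rr − σ_θθ)/r = 0,  σ_rr(r_o) = 0,  σ_rr(r_i) = −p_i

across the deformed wall.  The hydrostatic Lagrange multiplier p of the
incompressibility constraint cancels from every measurable quantity
(luminal pressure, axial force, stress differences); it is recovered
pointwise only when full transmural Cauchy profiles are requested.

Radial integrals use Gauss–Legendre quadrature on the reference radius
per layer (the integrand jumps at the media/adventitia interface), with
``dr = λ_r dR``.  The reduced axial force is

    F = π ∫ (2σ_zz − σ_θθ − σ_rr) r dr,     N = F + p_i π r_i²

for the closed-tube axial tension N.

Units: mm, MPa internally; pressures exposed in mmHg, forces in mN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Optional

import numpy as np
from scipy.optimize import brentq

from .kinematics import (
    ReferenceGeometry, loaded_radius, inner_radius, stretches_at,
    green_lagrange_diag, InvalidConfigurationError,
)
from .microstructure import MicrostructureConfig, WallComposition, statistical_default_config
from .fiber_constitutive import (
    PassiveFiberParams, QuadratureSpec, layer_passive_second_pk_diag,
)
from .smc_active import SMCActiveParams, smc_second_pk_diag

__all__ = [
    "MMHG_TO_MPA", "WallQuadrature", "ArteryModel", "StressState",
    "PredictionRecord", "total_second_pk", "luminal_pressure", "axial_force",
    "transmural_profile", "solve_outer_radius", "simulate_protocol",
    "default_model", "NoSolutionError",
]

#: declared unit conversion — the single place mmHg meets MPa
MMHG_TO_MPA = 1.333224e-4


class NoSolutionError(RuntimeError):
    """The inverse pressure→radius problem has no root in the search bracket."""


@dataclass(frozen=True)
class WallQuadrature:
    """Node counts: per-angle and per-recruitment integrals, radial per layer."""

    n_angle: int = 64
    n_recruit: int = 32
    n_radial: int = 32

    @property
    def spec(self) -> QuadratureSpec:
        return QuadratureSpec(self.n_angle, self.n_recruit)


@dataclass(frozen=True)
class ArteryModel:
    """Complete parameterization of the two-layer artery wall model."""

    geometry: ReferenceGeometry
    micro: MicrostructureConfig
    composition: WallComposition
    passive: PassiveFiberParams
    smc: SMCActiveParams
    quadrature: WallQuadrature = WallQuadrature()

    @property
    def interface_radius(self) -> float:
        """Reference radius of the media/adventitia interface."""
        g = self.geometry
        return g.r_inner + self.composition.media_fraction_of_thickness * g.wall_thickness

    def layer_of(self, R_ref: float) -> str:
        g = self.geometry
        if not (g.r_inner - 1e-12 <= R_ref <= g.r_outer + 1e-12):
            raise ValueError("reference radius outside the wall")
        return "media" if R_ref <= self.interface_radius else "adventitia"

    def with_activation(self, A: float) -> "ArteryModel":
        return replace(self, smc=self.smc.with_activation(A))


@dataclass(frozen=True)
class StressState:
    """Stress decomposition at a material point (MPa, (θ, r, z) basis)."""

    second_pk: np.ndarray
    cauchy_extra: np.ndarray
    hydrostatic: float
    cauchy: np.ndarray


@dataclass(frozen=True)
class PredictionRecord:
    """One simulated loading point of the distension–extension protocol."""

    pressure: float        # mmHg
    outer_radius: float    # mm
    axial_force: float     # mN (reduced force F)
    axial_tension: float   # mN (closed-tube tension N = F + p_i π r_i²)
    axial_stretch: float
    state: str             # "passive" | "full"


# ---------------------------------------------------------------------------
# stress assembly
# ---------------------------------------------------------------------------

def _second_pk_diag(model: ArteryModel, E_diag: np.ndarray, layer: str,
                    activation: float) -> np.ndarray:
    comp = model.composition.media if layer == "media" else model.composition.adventitia
    s = layer_passive_second_pk_diag(
        E_diag, layer, model.micro, comp, model.passive, model.quadrature.spec)
    if layer == "media" and comp.f_SMC > 0.0 and activation > 0.0:
        s = s + comp.f_SMC * smc_second_pk_diag(
            E_diag, model.micro, model.smc.with_activation(activation),
            model.quadrature.n_angle)
    return s


def total_second_pk(model: ArteryModel, E, R_ref: float,
                    activation: Optional[float] = None) -> np.ndarray:
    """Total 2nd Piola-Kirchhoff stress tensor at reference radius ``R_ref``.

    The layer (media below the interface radius, adventitia above) sets
    which constituents contribute; the SMC term exists only in the media.
    ``activation`` defaults to the model's own activation level.
    """
    if activation is None:
        activation = model.smc.activation
    E = np.asarray(E, dtype=float)
    diag = np.diagonal(E) if E.shape == (3, 3) else E
    layer = model.layer_of(R_ref)
    return np.diag(_second_pk_diag(model, np.asarray(diag, float), layer, activation))


# ---------------------------------------------------------------------------
# radial quadrature over the deformed wall
# ---------------------------------------------------------------------------

_GL_CACHE: dict = {}


def _leggauss(n: int):
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def _layer_nodes(lo: float, hi: float, n: int):
    x, w = _leggauss(n)
    mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    return mid + half * x, half * w


_NODE_CACHE: dict = {}


def _radial_tables(model: ArteryModel):
    """Cached per-layer radial nodes with precomputed geometric factors."""
    g = model.geometry
    key = (g.r_inner, g.r_outer, g.opening_angle,
           model.composition.media_fraction_of_thickness,
           model.quadrature.n_radial)
    hit = _NODE_CACHE.get(key)
    if hit is None:
        R_int = model.interface_radius
        n = model.quadrature.n_radial
        sector = g.sector_factor
        tables = []
        for lo, hi, layer in ((g.r_inner, R_int, "media"),
                              (R_int, g.r_outer, "adventitia")):
            R, w = _layer_nodes(lo, hi, n)
            # annulus deficit (R_o² − R²)·sector and hoop factor R·sector
            tables.append((layer, w, (g.r_outer**2 - R**2) * sector,
                           R * sector))
        hit = tables
        _NODE_CACHE[key] = hit
        if len(_NODE_CACHE) > 64:
            _NODE_CACHE.pop(next(iter(_NODE_CACHE)))
    return hit


def _wall_state(model: ArteryModel, lam_z: float, r_outer: float,
                activation: float):
    """Per-node kinematics and extra Cauchy stress diagonals across the wall.

    Returns (r, w_R·λ_r, σ̂_diag) with nodes split per layer so the
    composition jump at the interface never crosses a quadrature panel.
    """
    r_sq = r_outer * r_outer
    lam_z2 = lam_z * lam_z
    out_r, out_wr, out_sig = [], [], []
    for layer, w, deficit, hoop in _radial_tables(model):
        arg = r_sq - deficit / lam_z
        if arg[0] <= 0.0:  # innermost node has the smallest loaded radius
            raise InvalidConfigurationError(
                "negative squared radius: r_outer too small for the imposed "
                "axial stretch")
        r = np.sqrt(arg)
        lam_t = r / hoop
        lam_r = hoop / (lam_z * r)
        lam_t2 = lam_t * lam_t
        lam_r2 = lam_r * lam_r
        E_diag = np.empty((len(r), 3))
        E_diag[:, 0] = 0.5 * (lam_t2 - 1.0)
        E_diag[:, 1] = 0.5 * (lam_r2 - 1.0)
        E_diag[:, 2] = 0.5 * (lam_z2 - 1.0)
        S = _second_pk_diag(model, E_diag, layer, activation)
        S[:, 0] *= lam_t2
        S[:, 1] *= lam_r2
        S[:, 2] *= lam_z2
        out_r.append(r)
        out_wr.append(w * lam_r)
        out_sig.append(S)
    return (np.concatenate(out_r), np.concatenate(out_wr),
            np.concatenate(out_sig, axis=0))


def luminal_pressure(model: ArteryModel, lam_z: float, r_outer: float,
                     activation: Optional[float] = None) -> float:
    """Luminal pressure (mmHg) sustaining the given loaded configuration.

    p_i = ∫_{r_i}^{r_o} (σ_θθ − σ_rr)/r dr; the integrand uses extra
    stresses since the hydrostatic multiplier cancels in the difference.
    """
    if activation is None:
        activation = model.smc.activation
    r, wr, sig = _wall_state(model, lam_z, r_outer, activation)
    p_mpa = float(np.sum(wr * (sig[:, 0] - sig[:, 1]) / r))
    return p_mpa / MMHG_TO_MPA


def axial_force(model: ArteryModel, lam_z: float, r_outer: float,
                activation: Optional[float] = None):
    """Reduced axial force F and closed-tube tension N (both mN).

    F = π ∫ (2σ_zz − σ_θθ − σ_rr) r dr is hydrostatic-free;
    N = F + p_i π r_i² adds the pressure-on-cap term.
    """
    if activation is None:
        activation = model.smc.activation
    r, wr, sig = _wall_state(model, lam_z, r_outer, activation)
    F_n = np.pi * float(np.sum(wr * (2.0 * sig[:, 2] - sig[:, 0] - sig[:, 1]) * r))
    p_mpa = float(np.sum(wr * (sig[:, 0] - sig[:, 1]) / r))
    r_i = inner_radius(model.geometry, lam_z, r_outer)
    N_n = F_n + p_mpa * np.pi * r_i**2
    return F_n * 1e3, N_n * 1e3  # N → mN


# ---------------------------------------------------------------------------
# transmural profiles
# ---------------------------------------------------------------------------

def transmural_profile(model: ArteryModel, lam_z: float, r_outer: float,
                       activation: Optional[float] = None,
                       n_points: int = 50) -> np.ndarray:
    """Transmural Cauchy stress profile under the given loading.

    Returns an array of rows (r, σ_rr, σ_θθ, σ_zz) at ``n_points`` evenly
    spaced loaded radii.  σ_rr is integrated inward from the traction-free
    outer surface with panel-wise Gauss–Legendre (panels split at the
    layer interface); the hydrostatic pressure is then recovered pointwise
    as p = σ̂_rr − σ_rr and subtracted from the extra stresses.
    """
    if activation is None:
        activation = model.smc.activation
    g = model.geometry
    r_i = inner_radius(g, lam_z, r_outer)
    r_pts = np.linspace(r_i, r_outer, n_points)

    # map loaded radii back to reference radii (exact inverse of the radius map)
    def to_R(r):
        return np.sqrt(g.r_outer**2 - (r_outer**2 - r**2) * lam_z / g.sector_factor)

    R_pts = to_R(r_pts)
    R_int = model.interface_radius
    # panel boundaries: the output radii plus the layer interface
    R_bounds = np.unique(np.concatenate([R_pts, [R_int]]))
    x, wq = _leggauss(12)

    def integrand(R, layer):
        lam_t, lam_r, lam_zz = stretches_at(R, g, lam_z, r_outer)
        E_diag = green_lagrange_diag(lam_t, lam_r, lam_zz)
        S = _second_pk_diag(model, E_diag, layer, activation)
        sig_tt = lam_t**2 * S[:, 0]
        sig_rr = lam_r**2 * S[:, 1]
        r = loaded_radius(R, g, lam_z, r_outer)
        return (sig_tt - sig_rr) / r * lam_r

    panel = np.zeros(len(R_bounds) - 1)
    for k in range(len(R_bounds) - 1):
        a, b = R_bounds[k], R_bounds[k + 1]
        layer = "media" if 0.5 * (a + b) <= R_int else "adventitia"
        Rq = 0.5 * (a + b) + 0.5 * (b - a) * x
        panel[k] = 0.5 * (b - a) * float(integrand(Rq, layer) @ wq)
    # cumulative integral G(R_k) = ∫_{R_k}^{R_o} → σ_rr = −G
    G = np.concatenate([np.cumsum(panel[::-1])[::-1], [0.0]])
    G_at = dict(zip(R_bounds, G))
    sig_rr_pts = -np.array([G_at[R] for R in R_pts])

    lam_t, lam_r, lam_zz = stretches_at(R_pts, g, lam_z, r_outer)
    E_diag = green_lagrange_diag(lam_t, lam_r, lam_zz)
    layers = np.where(R_pts <= R_int, "media", "adventitia")
    S = np.empty((n_points, 3))
    for layer in ("media", "adventitia"):
        m = layers == layer
        if m.any():
            S[m] = _second_pk_diag(model, E_diag[m], layer, activation)
    sig_hat = np.stack([lam_t**2, lam_r**2, lam_zz**2], axis=-1) * S
    p = sig_hat[:, 1] - sig_rr_pts
    return np.column_stack([
        r_pts, sig_rr_pts, sig_hat[:, 0] - p, sig_hat[:, 2] - p,
    ])


def stress_state_at(model: ArteryModel, lam_z: float, r_outer: float,
                    R_ref: float, activation: Optional[float] = None) -> StressState:
    """Full stress decomposition (S, σ̂, p, σ) at one transmural point."""
    if activation is None:
        activation = model.smc.activation
    g = model.geometry
    lam = stretches_at(R_ref, g, lam_z, r_outer)
    E_diag = green_lagrange_diag(*lam)
    layer = model.layer_of(R_ref)
    S = _second_pk_diag(model, E_diag[None, :], layer, activation)[0]
    sig_hat = np.array(lam) ** 2 * S
    prof = transmural_profile(model, lam_z, r_outer, activation, n_points=80)
    r = loaded_radius(R_ref, g, lam_z, r_outer)
    sig_rr = float(np.interp(r, prof[:, 0], prof[:, 1]))
    p = float(sig_hat[1] - sig_rr)
    return StressState(
        second_pk=np.diag(S),
        cauchy_extra=np.diag(sig_hat),
        hydrostatic=p,
        cauchy=np.diag(sig_hat - p),
    )


# ---------------------------------------------------------------------------
# inverse problem and protocol simulation
# ---------------------------------------------------------------------------

def _min_outer_radius(model: ArteryModel, lam_z: float) -> float:
    g = model.geometry
    return float(np.sqrt((g.r_outer**2 - g.r_inner**2) * g.sector_factor / lam_z))


def solve_outer_radius(model: ArteryModel, lam_z: float, target_pressure: float,
                       activation: Optional[float] = None,
                       bracket: Optional[tuple] = None,
                       xtol: float = 1e-10) -> float:
    """Loaded outer radius at which the luminal pressure equals the target.

    Safeguarded root bracketing on the monotone pressure–radius relation;
    the residual at the returned radius is below 1e-6 mmHg.  ``bracket``
    may supply a warm-start interval (expanded if it does not straddle
    the target); raises :class:`NoSolutionError` when no sign change is
    found in the admissible radius range.
    """
    if activation is None:
        activation = model.smc.activation

    def f(r_o):
        return luminal_pressure(model, lam_z, r_o, activation) - target_pressure

    r_min = _min_outer_radius(model, lam_z) * 1.0001 + 1e-9
    r_max = 3.0 * model.geometry.r_outer
    if bracket is not None:
        lo = max(bracket[0], r_min)
        hi = min(bracket[1], r_max)
    else:
        lo, hi = r_min, r_max
    flo, fhi = f(lo), f(hi)
    # grow a warm-start bracket outward before resorting to a full scan
    if bracket is not None:
        for _ in range(6):
            if flo * fhi <= 0.0:
                break
            if flo > 0.0:  # both above target: stretch downward
                lo = max(r_min, lo - 1.5 * (hi - lo))
                flo = f(lo)
            else:          # both below target: stretch upward
                hi = min(r_max, hi + 1.5 * (hi - lo))
                fhi = f(hi)
    if flo * fhi > 0.0:
        grid = np.geomspace(r_min, r_max, 40)
        vals = np.array([f(r) for r in grid])
        sign = np.sign(vals)
        idx = np.nonzero(sign[:-1] * sign[1:] <= 0.0)[0]
        if len(idx) == 0:
            raise NoSolutionError(
                f"no radius in [{r_min:.4g}, {r_max:.4g}] mm attains "
                f"{target_pressure:.4g} mmHg at lam_z={lam_z}"
            )
        lo, hi = grid[idx[0]], grid[idx[0] + 1]
    root = brentq(f, lo, hi, xtol=xtol, rtol=4e-15)
    return float(root)


def simulate_protocol(model: ArteryModel, pressures: Sequence[float],
                      stretches: Sequence[float], states: Sequence[str],
                      ) -> list:
    """Forward-simulate the distension–extension protocol.

    One :class:`PredictionRecord` per (pressure, stretch, state)
    combination; within each (stretch, state) sweep the pressures are
    solved in ascending order with warm-started brackets and the records
    are returned in the caller's requested order.
    """
    for s in states:
        if s not in ("passive", "full"):
            raise ValueError(f"unknown activation state {s!r}")
    records = {}
    for state in states:
        A = 1.0 if state == "full" else 0.0
        for lam_z in stretches:
            order = np.argsort(pressures, kind="stable")
            bracket = None
            for k in order:
                p = pressures[k]
                r_o = solve_outer_radius(model, lam_z, p, A, bracket=bracket)
                bracket = (r_o * 0.999, r_o * 1.15)
                F, N = axial_force(model, lam_z, r_o, A)
                records[(p, lam_z, state)] = PredictionRecord(
                    pressure=float(p), outer_radius=r_o, axial_force=F,
                    axial_tension=N, axial_stretch=float(lam_z), state=state,
                )
    return [records[(p, lz, st)] for st in states for lz in stretches
            for p in pressures]


DEFAULT_PRESSURES = tuple(range(0, 161, 20))
DEFAULT_STRETCHES = (1.3, 1.5)
DEFAULT_STATES = ("passive", "full")


def default_model(quadrature: WallQuadrature = WallQuadrature()) -> ArteryModel:
    """Packaged default artery model.

    Microstructure statistics are the published population averages for
    porcine LAD arteries; material parameters are the published refined-
    fit averages.  The reference geometry, volume fractions and layer
    split are documented package assumptions (the source measurements are
    not part of the published statistics).
    """
    from .microstructure import LayerComposition
    return ArteryModel(
        geometry=ReferenceGeometry(
            r_outer=2.5, r_inner=1.85, opening_angle=1.2, length_ref=10.0),
        micro=statistical_default_config(),
        composition=WallComposition(
            media_fraction_of_thickness=2.0 / 3.0,
            media=LayerComposition(f_IL=0.15, f_E=0.15, f_C=0.25, f_SMC=0.45),
            adventitia=LayerComposition(f_IL=0.0, f_E=0.35, f_C=0.65, f_SMC=0.0),
        ),
        passive=PassiveFiberParams(k_IL=0.18, k_E=0.27, k_C=29.5, M_C=5.23),
        smc=SMCActiveParams(rho1=0.31, rho2=1.43, lam_max=1.34, sigma_max=0.09,
                            tau=0.23, k_smc_radial=0.01, activation=1.0),
        quadrature=quadrature,
    )
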