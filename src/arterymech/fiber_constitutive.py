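"""Passive fiber laws and layer-level strain energy / 2nd Piola-Kirchhoff stress.

Single-fiber laws (tension-only, strain measured along the fiber):

* elastin (and inter-lamellar elastin):  w = ½ k e²  for e > 0;
* collagen, wavy with straightening strain e₀:
  w = k_C (e − e₀)^{1+M_C} / (1+M_C)  for e > e₀.

Layer quantities are orientation expectations of the single-fiber laws,
with collagen additionally averaged over the straightening-strain
(recruitment) distribution.  The adventitia carries two-component
elastin and collagen orientation mixtures in the circumferential–axial
plane; the media carries a mirrored fiber family shared by elastin and
collagen plus an isotropic inter-lamellar elastin network in the
circumferential–radial plane.  All integrals are density-weighted
Gauss–Legendre sums supplied by the microstructure layer, so the
degenerate point-mass mode reduces every expectation to a single
evaluation exactly.

Stress kernels operate on diagonal Green–Lagrange strains stacked as
``(..., 3)`` arrays in the (θ, r, z) basis and are fully vectorized over
leading axes; thin 3×3-tensor wrappers provide the public single-point
interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .microstructure import MicrostructureConfig, LayerComposition

__all__ = [
    "PassiveFiberParams",
    "elastin_energy_stress",
    "collagen_energy_stress",
    "layer_passive_energy",
    "layer_passive_second_pk",
    "QuadratureSpec",
]


@dataclass(frozen=True)
class PassiveFiberParams:
    """Material parameters of the passive fiber laws (MPa, dimensionless).

    k_IL: inter-lamellar elastin stiffness; k_E: elastin fiber stiffness;
    k_C, M_C: collagen power-law coefficient and exponent.  Identical in
    both wall layers.
    """

    k_IL: float
    k_E: float
    k_C: float
    M_C: float

    def __post_init__(self) -> None:
        if min(self.k_IL, self.k_E, self.k_C) < 0.0:
            raise ValueError("fiber stiffnesses must be nonnegative")
        if not self.M_C > 0.0:
            raise ValueError("collagen exponent M_C must be positive")


@dataclass(frozen=True)
class QuadratureSpec:
    """Node counts for the layer integrals.

    ``n_angle`` nodes per orientation(-mixture component) integral,
    ``n_recruit`` per straightening-strain integral.
    """

    n_angle: int = 64
    n_recruit: int = 32

    def __post_init__(self) -> None:
        if self.n_angle < 1 or self.n_recruit < 1:
            raise ValueError("quadrature node counts must be >= 1")


def elastin_energy_stress(e, k: float):
    """Energy and fiber stress of linear tension-only elastin."""
    if k < 0.0:
        raise ValueError("elastin stiffness must be nonnegative")
    ep = np.maximum(np.asarray(e, dtype=float), 0.0)
    w = 0.5 * k * ep**2
    s = k * ep
    if np.ndim(e):
        return w, s
    return float(w), float(s)


def collagen_energy_stress(e, params: PassiveFiberParams, e0):
    """Energy and fiber stress of wavy collagen recruited beyond strain e0."""
    if np.any(np.asarray(e0) < 0.0):
        raise ValueError("straightening strain must be nonnegative")
    x = np.maximum(np.asarray(e, dtype=float) - np.asarray(e0, dtype=float), 0.0)
    w = params.k_C * x ** (1.0 + params.M_C) / (1.0 + params.M_C)
    s = params.k_C * x**params.M_C
    if np.ndim(e) or np.ndim(e0):
        return w, s
    return float(w), float(s)


# ---------------------------------------------------------------------------
# cached quadrature tables per (micro, quad) pair
# ---------------------------------------------------------------------------

class _LayerTables:
    """Precomputed nodes/weights and direction factors for one configuration.

    For each orientation family: density-weighted angle weights ``w`` and
    squared direction cosines ``c2``/``s2`` giving the dyad N⊗N diagonal.
    Planar (θ–z) families map (c2, 0, s2); the circ–radial IL network maps
    (c2, s2, 0).
    """

    def __init__(self, micro: MicrostructureConfig, quad: QuadratureSpec):
        def prep(nodes_weights):
            th, w = nodes_weights
            return w, np.cos(th) ** 2, np.sin(th) ** 2

        self.adv_elastin = prep(micro.adv_elastin.quad(quad.n_angle))
        self.adv_collagen = prep(micro.adv_collagen.quad(quad.n_angle))
        self.media_fiber = prep(micro.media_fiber.quad(quad.n_angle))
        self.media_smc = prep(micro.media_smc.quad(quad.n_angle))
        self.adv_e0 = micro.adv_recruitment.quad(quad.n_recruit)
        self.media_e0 = micro.media_recruitment.quad(quad.n_recruit)


_TABLE_CACHE: dict = {}


def _tables(micro: MicrostructureConfig, quad: QuadratureSpec) -> _LayerTables:
    key = (id(micro), quad.n_angle, quad.n_recruit)
    hit = _TABLE_CACHE.get(key)
    if hit is None or hit[0] is not micro:
        hit = (micro, _LayerTables(micro, quad))
        _TABLE_CACHE[key] = hit
        if len(_TABLE_CACHE) > 64:
            _TABLE_CACHE.pop(next(iter(_TABLE_CACHE)))
    return hit[1]


def _family_strain(E_diag: np.ndarray, c2: np.ndarray, s2: np.ndarray,
                   plane_idx: Tuple[int, int]) -> np.ndarray:
    """Fiber strain e = E:N⊗N over (..., angle) for a planar family."""
    i, j = plane_idx
    return E_diag[..., i, None] * c2 + E_diag[..., j, None] * s2


def _elastin_family(E_diag, table, k, plane_idx, want_energy):
    w, c2, s2 = table
    e = _family_strain(E_diag, c2, s2, plane_idx)
    if want_energy:
        return 0.5 * k * np.maximum(e, 0.0) ** 2 @ w
    sig = k * np.maximum(e, 0.0)
    return _assemble_diag(sig * w, c2, s2, plane_idx)


def _collagen_family(E_diag, table, e0_table, params, plane_idx, want_energy):
    w, c2, s2 = table
    e0, w0 = e0_table
    e = _family_strain(E_diag, c2, s2, plane_idx)
    x = np.maximum(e[..., None] - e0, 0.0)  # (..., angle, e0)
    if want_energy:
        wbar = (x ** (1.0 + params.M_C) @ w0) * (params.k_C / (1.0 + params.M_C))
        return wbar @ w
    sig = (x**params.M_C @ w0) * params.k_C  # recruitment-averaged fiber stress
    return _assemble_diag(sig * w, c2, s2, plane_idx)


def _il_elastin(E_diag, k, want_energy):
    """Isotropic inter-lamellar elastin in the θ–r plane, in closed form.

    The network is uniform over angle (density 1/π on (−π/2, π/2); by
    symmetry 2/π on (0, π/2)) and the fiber law is quadratic, so the
    tension-only angular integrals over the region e(θ) > 0, with
    e = E_θθcos²θ + E_rr sin²θ, reduce to elementary antiderivatives of
    cos⁴, cos²sin² and sin⁴ between the zero crossings of e.
    """
    a = np.asarray(E_diag[..., 0], dtype=float)
    b = np.asarray(E_diag[..., 1], dtype=float)

    # tension region [lo, hi] ⊆ [0, π/2] where a·cos² + b·sin² > 0
    ratio = np.where(a * b < 0.0, -np.divide(a, b, out=np.ones_like(a),
                                             where=b != 0.0), 1.0)
    theta_star = np.arctan(np.sqrt(np.clip(ratio, 0.0, np.inf)))
    lo = np.where((a <= 0.0) & (b > 0.0), theta_star, 0.0)
    hi = np.where((a > 0.0) & (b < 0.0), theta_star, np.pi / 2.0)
    hi = np.where((a <= 0.0) & (b <= 0.0), 0.0, hi)  # fully slack

    def anti(th):
        s2t, s4t = np.sin(2.0 * th), np.sin(4.0 * th)
        i_c4 = 3.0 * th / 8.0 + s2t / 4.0 + s4t / 32.0
        i_s4 = 3.0 * th / 8.0 - s2t / 4.0 + s4t / 32.0
        i_c2s2 = th / 8.0 - s4t / 32.0
        return i_c4, i_s4, i_c2s2

    c4h, s4h, c2s2h = anti(hi)
    c4l, s4l, c2s2l = anti(lo)
    I_c4, I_s4, I_c2s2 = c4h - c4l, s4h - s4l, c2s2h - c2s2l
    if want_energy:
        # (2/π)·½k ∫ e² dθ with e² = a²cos⁴ + 2ab cos²sin² + b²sin⁴
        return (k / np.pi) * (a**2 * I_c4 + 2 * a * b * I_c2s2 + b**2 * I_s4)
    out = np.zeros(np.broadcast(a, b).shape + (3,))
    out[..., 0] = (2.0 * k / np.pi) * (a * I_c4 + b * I_c2s2)
    out[..., 1] = (2.0 * k / np.pi) * (a * I_c2s2 + b * I_s4)
    return out


def _assemble_diag(sw, c2, s2, plane_idx):
    """Contract angle axis into the diagonal (θ, r, z) stress components."""
    i, j = plane_idx
    out = np.zeros(sw.shape[:-1] + (3,))
    out[..., i] = sw @ c2
    out[..., j] = sw @ s2
    return out


_PLANE_TZ = (0, 2)  # θ–z plane: (cos²θ, 0, sin²θ)
_PLANE_TR = (0, 1)  # θ–r plane: (cos²θ, sin²θ, 0)


def _layer_passive(E_diag: np.ndarray, layer: str, micro: MicrostructureConfig,
                   comp: LayerComposition, params: PassiveFiberParams,
                   quad: QuadratureSpec, want_energy: bool):
    t = _tables(micro, quad)
    if layer == "adventitia":
        out = comp.f_E * _elastin_family(
            E_diag, t.adv_elastin, params.k_E, _PLANE_TZ, want_energy)
        out = out + comp.f_C * _collagen_family(
            E_diag, t.adv_collagen, t.adv_e0, params, _PLANE_TZ, want_energy)
        return out
    if layer == "media":
        out = comp.f_E * _elastin_family(
            E_diag, t.media_fiber, params.k_E, _PLANE_TZ, want_energy)
        out = out + comp.f_C * _collagen_family(
            E_diag, t.media_fiber, t.media_e0, params, _PLANE_TZ, want_energy)
        out = out + comp.f_IL * _il_elastin(E_diag, params.k_IL, want_energy)
        return out
    raise ValueError(f"unknown layer {layer!r}")


def layer_passive_energy(E, layer: str, micro: MicrostructureConfig,
                         comp: LayerComposition, params: PassiveFiberParams,
                         quad: QuadratureSpec = QuadratureSpec()):
    """Volume-fraction-weighted passive strain energy density (MPa) of a layer."""
    E_diag = _as_diag(E)
    out = _layer_passive(E_diag, layer, micro, comp, params, quad, True)
    return out if np.ndim(out) else float(out)


def layer_passive_second_pk(E, layer: str, micro: MicrostructureConfig,
                            comp: LayerComposition, params: PassiveFiberParams,
                            quad: QuadratureSpec = QuadratureSpec()) -> np.ndarray:
    """Passive 2nd Piola-Kirchhoff stress ∂W/∂E of a layer as a 3×3 tensor."""
    E_diag = _as_diag(E)
    s = _layer_passive(E_diag, layer, micro, comp, params, quad, False)
    if s.ndim == 1:
        return np.diag(s)
    return s  # vectorized callers receive diagonal stacks


def layer_passive_second_pk_diag(E_diag: np.ndarray, layer: str,
                                 micro: MicrostructureConfig,
                                 comp: LayerComposition,
                                 params: PassiveFiberParams,
                                 quad: QuadratureSpec) -> np.ndarray:
    """Vectorized kernel: diagonal stresses for stacked diagonal strains."""
    return _layer_passive(np.asarray(E_diag, float), layer, micro, comp, params,
                          quad, False)


def _as_diag(E) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.shape[-2:] == (3, 3):
        off = E - E * np.eye(3)
        if np.any(np.abs(off) > 1e-12):
            raise ValueError("layer stress kernels require diagonal strain states")
        return np.diagonal(E, axis1=-2, axis2=-1)
    if E.shape[-1] == 3:
        return E
    raise ValueError("E must be a 3×3 tensor or a length-3 diagonal")
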