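"""Geometric statistics of arterial wall constituents.

Fiber and smooth-muscle-cell (SMC) orientations are described by
truncated-normal densities (and mixtures of two of them in the
adventitia); collagen waviness enters through a straightening-strain
("recruitment") distribution — beta in the adventitia, uniform in the
media.  Every distribution exposes Gauss–Legendre quadrature nodes and
weights pre-multiplied by its density so expectation integrals reduce to
weighted sums; the nodes are placed on the distribution's essential
support (its central quantile range intersected with the support bounds)
so that modest node counts resolve even sharply peaked densities.

A degenerate ``point`` mode collapses any distribution onto its mean:
the mean-value model of the vessel wall, in which every orientation and
recruitment integral becomes a single evaluation.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = [
    "OrientationDistribution",
    "OrientationMixture",
    "RecruitmentDistribution",
    "MicrostructureConfig",
    "LayerComposition",
    "WallComposition",
    "moment_match_beta",
    "truncated_normal_density",
    "mixture_density",
    "recruitment_density",
    "statistical_default_config",
]

_QUANTILE_CLIP = 1e-12  # essential-support quantile for quadrature placement


def _gauss_legendre(lo: float, hi: float, n: int) -> Tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    return mid + half * x, half * w


_WINDOW_SDS = 8.0  # essential-mass window half-width for peaked densities


@functools.lru_cache(maxsize=512)
def _orientation_quad(dist: "OrientationDistribution", n: int):
    """Density-weighted Gauss–Legendre nodes for orientation expectations.

    Nodes are placed on the essential-mass window μ ± 8σ intersected with
    the support, so sharply peaked densities are resolved as well as
    broad ones (the normal mass outside 8σ is ~1e-15).
    """
    if dist.is_point:
        return np.array([dist.mean_angle]), np.array([1.0])
    lo, hi = dist.support
    a = max(lo, dist.mean_angle - _WINDOW_SDS * dist.sd_angle)
    b = min(hi, dist.mean_angle + _WINDOW_SDS * dist.sd_angle)
    x, w = _gauss_legendre(a, b, n)
    return x, w * dist.density(x)


@functools.lru_cache(maxsize=512)
def _norm_weight(mean: float, sd: float, lo: float, hi: float) -> float:
    z = stats.norm(mean, sd)
    return float(z.cdf(hi) - z.cdf(lo))


#: beyond this shape size a beta is effectively Gaussian and Jacobi-node
#: computation becomes fragile; switch to a windowed normal-style rule
_JACOBI_SHAPE_LIMIT = 200.0


@functools.lru_cache(maxsize=512)
def _recruitment_quad(dist: "RecruitmentDistribution", n: int):
    """Expectation nodes/weights over the straightening-strain law.

    Beta laws use Gauss–Jacobi quadrature (the orthogonal family of the
    beta weight), exact for polynomial integrands of degree 2n−1; the
    weights are normalized so they sum to 1 exactly.  Extremely
    concentrated betas (huge shapes) fall back to a density-weighted
    Gauss–Legendre rule on the mean ± 8 sd window.
    """
    if dist.kind == "point":
        return np.array([dist.point_value]), np.array([1.0])
    if dist.kind == "uniform":
        x, w = _gauss_legendre(dist.lower, dist.upper, n)
        return x, w / (dist.upper - dist.lower)
    if max(dist.shape1, dist.shape2) <= _JACOBI_SHAPE_LIMIT:
        from scipy.special import roots_jacobi
        t, w = roots_jacobi(n, dist.shape2 - 1.0, dist.shape1 - 1.0)
        x = dist.lower + (t + 1.0) * 0.5 * (dist.upper - dist.lower)
        return x, w / w.sum()
    fz = dist._frozen()
    m, s = dist.mean, dist.sd
    a = max(dist.lower, m - _WINDOW_SDS * s)
    b = min(dist.upper, m + _WINDOW_SDS * s)
    x, w = _gauss_legendre(a, b, n)
    w = w * fz.pdf(x)
    return x, w / w.sum()


@dataclass(frozen=True)
class OrientationDistribution:
    """Truncated normal orientation density on ``support``.

    ``mean_angle`` and ``sd_angle`` are the untruncated normal's moments
    (rad); the density is normal_pdf/K on the support, with K the normal
    mass falling inside it.  ``sd_angle = 0`` denotes a point mass at the
    mean (the mean-value degenerate mode).
    """

    mean_angle: float
    sd_angle: float
    support: Tuple[float, float] = (0.0, math.pi)

    def __post_init__(self) -> None:
        lo, hi = self.support
        if self.sd_angle < 0.0:
            raise ValueError("orientation sd must be >= 0")
        if hi <= lo:
            raise ValueError("empty orientation support")
        if self.is_point and not (lo <= self.mean_angle <= hi):
            raise ValueError("point-mass angle outside support")
        if not self.is_point and self.norm_weight <= 0.0:
            raise ValueError("truncated-normal mass on support is zero")

    @property
    def is_point(self) -> bool:
        return self.sd_angle == 0.0

    @property
    def norm_weight(self) -> float:
        """K — untruncated normal mass on the support."""
        if self.is_point:
            return 1.0
        return _norm_weight(self.mean_angle, self.sd_angle, *self.support)

    def density(self, angle):
        """Density (1/rad); zero outside the support."""
        if self.is_point:
            raise ValueError("point-mass orientation has no density function")
        lo, hi = self.support
        th = np.asarray(angle, dtype=float)
        z = (th - self.mean_angle) / self.sd_angle
        pdf = np.exp(-0.5 * z * z) / (self.sd_angle * math.sqrt(2.0 * math.pi))
        out = np.where((th >= lo) & (th <= hi), pdf / self.norm_weight, 0.0)
        return out if out.ndim else float(out)

    def quad(self, n: int) -> Tuple[np.ndarray, np.ndarray]:
        """Nodes and density-weighted weights: Σ w_k f(θ_k) ≈ E[f(θ)]."""
        return _orientation_quad(self, n)

    def collapse(self) -> "OrientationDistribution":
        """Point-mass version at the truncated distribution's mean angle."""
        if self.is_point:
            return self
        lo, hi = self.support
        a = (lo - self.mean_angle) / self.sd_angle
        b = (hi - self.mean_angle) / self.sd_angle
        m = float(stats.truncnorm(a, b, loc=self.mean_angle, scale=self.sd_angle).mean())
        return replace(self, mean_angle=m, sd_angle=0.0)


@dataclass(frozen=True)
class OrientationMixture:
    """Weighted mixture of truncated-normal orientation components."""

    components: Tuple[OrientationDistribution, ...]
    weights: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights) or not self.components:
            raise ValueError("components and weights must be nonempty and matched")
        if any(w < 0.0 for w in self.weights):
            raise ValueError("mixture weights must be nonnegative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def density(self, angle):
        th = np.asarray(angle, dtype=float)
        out = sum(w * c.density(th) for c, w in zip(self.components, self.weights))
        return out if np.ndim(out) else float(out)

    def quad(self, n: int) -> Tuple[np.ndarray, np.ndarray]:
        """Per-component adapted nodes, concatenated with mixture weights folded in."""
        xs, ws = [], []
        for c, w in zip(self.components, self.weights):
            x, wq = c.quad(n)
            xs.append(x)
            ws.append(w * wq)
        return np.concatenate(xs), np.concatenate(ws)

    def collapse(self) -> "OrientationMixture":
        return OrientationMixture(
            tuple(c.collapse() for c in self.components), self.weights
        )


def moment_match_beta(target_mean: float, target_sd: float, a: float = 0.0,
                      b: float = 1.0) -> Tuple[float, float]:
    """Shape parameters (α₁, α₂) of a beta on [a, b] with the given moments.

    Standard inversion: with m = (mean−a)/(b−a) and v = sd²/(b−a)²,
    α₁ = m(m(1−m)/v − 1), α₂ = (1−m)(m(1−m)/v − 1).  Raises when the
    target variance is infeasible for a beta on the interval.
    """
    if not a < target_mean < b:
        raise ValueError("target mean must lie strictly inside (a, b)")
    if target_sd <= 0.0:
        raise ValueError("target sd must be positive")
    m = (target_mean - a) / (b - a)
    v = (target_sd / (b - a)) ** 2
    if v >= m * (1.0 - m):
        raise ValueError(
            "infeasible moments: sd² must be < (mean−a)(b−mean) for a beta law"
        )
    common = m * (1.0 - m) / v - 1.0
    return m * common, (1.0 - m) * common


@dataclass(frozen=True)
class RecruitmentDistribution:
    """Collagen straightening-strain (recruitment) distribution.

    ``kind``:
      * ``"beta"`` — beta(α₁, α₂) rescaled to [lower, upper];
      * ``"uniform"`` — uniform on [lower, upper];
      * ``"point"`` — all mass at ``point_value`` (mean-value mode).
    """

    kind: str
    shape1: float = float("nan")
    shape2: float = float("nan")
    lower: float = 0.0
    upper: float = 1.0
    point_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind == "beta":
            if not (self.shape1 > 0.0 and self.shape2 > 0.0):
                raise ValueError("beta shapes must be positive")
            if not self.upper > self.lower >= 0.0:
                raise ValueError("require upper > lower >= 0")
        elif self.kind == "uniform":
            if not self.upper > self.lower:
                raise ValueError("require upper > lower")
        elif self.kind == "point":
            if not np.isfinite(self.point_value) or self.point_value < 0.0:
                raise ValueError("point recruitment needs a nonnegative point_value")
        else:
            raise ValueError(f"unknown recruitment kind {self.kind!r}")

    @classmethod
    def from_moments(cls, mean: float, sd: float, lower: float = 0.0,
                     upper: float = 1.0) -> "RecruitmentDistribution":
        a1, a2 = moment_match_beta(mean, sd, lower, upper)
        return cls("beta", shape1=a1, shape2=a2, lower=lower, upper=upper)

    def _frozen(self):
        scale = self.upper - self.lower
        if self.kind == "beta":
            return stats.beta(self.shape1, self.shape2, loc=self.lower, scale=scale)
        return stats.uniform(loc=self.lower, scale=scale)

    @property
    def mean(self) -> float:
        if self.kind == "point":
            return self.point_value
        return float(self._frozen().mean())

    @property
    def sd(self) -> float:
        if self.kind == "point":
            return 0.0
        return float(self._frozen().std())

    def density(self, e0):
        if self.kind == "point":
            raise ValueError("point recruitment has no density function")
        x = np.asarray(e0, dtype=float)
        out = self._frozen().pdf(x)
        return out if np.ndim(out) else float(out)

    def quad(self, n: int) -> Tuple[np.ndarray, np.ndarray]:
        """Nodes/weights for expectations over the straightening strain."""
        return _recruitment_quad(self, n)

    def collapse(self) -> "RecruitmentDistribution":
        if self.kind == "point":
            return self
        return RecruitmentDistribution("point", point_value=self.mean)


# density wrappers matching the operation-level vocabulary --------------------

def truncated_normal_density(angle, dist: OrientationDistribution):
    return dist.density(angle)


def mixture_density(angle, mix: OrientationMixture):
    return mix.density(angle)


def recruitment_density(e0, dist: RecruitmentDistribution):
    if dist.kind == "point":
        raise ValueError("point recruitment has no density function")
    return dist.density(e0)


# wall composition ------------------------------------------------------------

@dataclass(frozen=True)
class LayerComposition:
    """Volume fractions of the mechanically active constituents in one layer."""

    f_IL: float
    f_E: float
    f_C: float
    f_SMC: float

    def __post_init__(self) -> None:
        for name in ("f_IL", "f_E", "f_C", "f_SMC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.f_IL + self.f_E + self.f_C + self.f_SMC > 1.0 + 1e-9:
            raise ValueError("layer volume fractions exceed 1")


@dataclass(frozen=True)
class WallComposition:
    """Two-layer wall composition and media share of the wall thickness.

    The media occupies the inner ``media_fraction_of_thickness`` of the
    reference wall; SMCs and inter-lamellar (IL) elastin reside in the
    media only.
    """

    media_fraction_of_thickness: float
    media: LayerComposition
    adventitia: LayerComposition

    def __post_init__(self) -> None:
        if not 0.0 < self.media_fraction_of_thickness < 1.0:
            raise ValueError("media thickness fraction must lie in (0, 1)")
        if self.adventitia.f_SMC != 0.0:
            raise ValueError("SMCs reside in the media; adventitia f_SMC must be 0")
        if self.adventitia.f_IL != 0.0:
            raise ValueError("IL elastin resides in the media; adventitia f_IL must be 0")


# full microstructure configuration -------------------------------------------

HALF_PLANE = (0.0, math.pi / 2.0)
FULL_PLANE = (0.0, math.pi)


@dataclass(frozen=True)
class MicrostructureConfig:
    """All orientation and recruitment statistics of the wall constituents.

    Adventitial elastin and collagen orientations are two-component
    mixtures on [0, π]; medial fibers and SMCs form symmetric families
    mirrored about the circumferential direction, represented by a single
    truncated normal on [0, π/2] (the two mirrored halves are equivalent
    under the diagonal strain states of distension–extension); medial IL
    elastin is isotropic in the circumferential–radial plane.
    """

    adv_elastin: OrientationMixture
    adv_collagen: OrientationMixture
    adv_recruitment: RecruitmentDistribution
    media_fiber: OrientationDistribution
    media_smc: OrientationDistribution
    media_recruitment: RecruitmentDistribution
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in ("full", "mean_value"):
            raise ValueError(f"unknown microstructure mode {self.mode!r}")
        if self.mode == "mean_value":
            degenerate = (
                all(c.is_point for c in self.adv_elastin.components)
                and all(c.is_point for c in self.adv_collagen.components)
                and self.media_fiber.is_point
                and self.media_smc.is_point
                and self.adv_recruitment.kind == "point"
                and self.media_recruitment.kind == "point"
            )
            if not degenerate:
                raise ValueError("mean_value mode requires all point-mass distributions")

    def collapse_to_mean_value(self) -> "MicrostructureConfig":
        """Degenerate configuration with every distribution at its mean."""
        return MicrostructureConfig(
            adv_elastin=self.adv_elastin.collapse(),
            adv_collagen=self.adv_collagen.collapse(),
            adv_recruitment=self.adv_recruitment.collapse(),
            media_fiber=self.media_fiber.collapse(),
            media_smc=self.media_smc.collapse(),
            media_recruitment=self.media_recruitment.collapse(),
            mode="mean_value",
        )


#: Population-average orientation/recruitment statistics for porcine LAD
#: coronary arteries (adventitial mixtures, medial families, collagen
#: straightening-strain moments), as published for this vessel type.
STATISTICAL_AVERAGES = {
    "mu_E1": 0.25, "sd_E1": 0.17, "mu_E2": 1.84, "sd_E2": 0.38,
    "mu_C1": 0.32, "sd_C1": 0.23, "mu_C2": 1.81, "sd_C2": 0.33,
    "mu_M": 0.23, "sd_M": 0.19,
    "mu_SMC": 0.24, "sd_SMC": 0.21,
    "e0_mean": 0.35, "e0_sd": 0.051,
    "e_02": 0.35,
}


def statistical_default_config(weights: Tuple[float, float] = (0.5, 0.5),
                               e0_bounds: Tuple[float, float] = (0.0, 1.0),
                               ) -> MicrostructureConfig:
    """Microstructure configuration from the published statistical averages.

    Adventitial mixture weights and the beta recruitment bounds are not
    part of the published statistics; they default to equal weights and
    [0, 1] with the beta shapes moment-matched to the published
    straightening-strain mean and SD.
    """
    s = STATISTICAL_AVERAGES
    adv_elastin = OrientationMixture(
        (OrientationDistribution(s["mu_E1"], s["sd_E1"], FULL_PLANE),
         OrientationDistribution(s["mu_E2"], s["sd_E2"], FULL_PLANE)),
        weights,
    )
    adv_collagen = OrientationMixture(
        (OrientationDistribution(s["mu_C1"], s["sd_C1"], FULL_PLANE),
         OrientationDistribution(s["mu_C2"], s["sd_C2"], FULL_PLANE)),
        weights,
    )
    return MicrostructureConfig(
        adv_elastin=adv_elastin,
        adv_collagen=adv_collagen,
        adv_recruitment=RecruitmentDistribution.from_moments(
            s["e0_mean"], s["e0_sd"], *e0_bounds
        ),
        media_fiber=OrientationDistribution(s["mu_M"], s["sd_M"], HALF_PLANE),
        media_smc=OrientationDistribution(s["mu_SMC"], s["sd_SMC"], HALF_PLANE),
        media_recruitment=RecruitmentDistribution(
            "uniform", lower=0.0, upper=s["e_02"]
        ),
    )
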