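"""Joint passive+active parameter estimation from biaxial-test records.

The objective is the studentized sum of squared residuals over the full
factorial protocol (n pressures × m axial stretches), with four channels
per grid point — outer radius and axial force, each in the passive and
the fully activated state:

    SSE = (1/nm) Σ_{i,j} [ (Δr_o^P/σ_r^P)² + (ΔF^P/σ_F^P)²
                         + (Δr_o^F/σ_r^F)² + (ΔF^F/σ_F^F)² ]

where the σ are the measurement standard deviations of each channel and
state.  Fitting both states jointly avoids the bias of the two-stage
(passive-then-active) approach, in which passive parameters are never
validated in the low-stretch range that dominates the active response;
the two-stage route is still available as an option.

The global search is a population-based differential-evolution
optimizer (the same algorithmic class as a genetic algorithm) with a
mandatory seed, so a fit is bit-reproducible.  Three modes mirror the
three ways the microstructure can enter the fit:

* ``statistical_fixed`` — orientation/recruitment statistics pinned at
  the packaged population averages; only material parameters are free;
* ``refined_geometry`` — geometric parameters are additionally
  estimated inside box constraints centered on the statistical means
  (half-width a configurable multiple of the statistical SDs);
* ``mean_value`` — every distribution collapses to a point mass and the
  mean angles plus the straightening strains are estimated directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .microstructure import (
    MicrostructureConfig, OrientationDistribution, OrientationMixture,
    RecruitmentDistribution, FULL_PLANE, HALF_PLANE,
)
from .wall_mechanics import (
    ArteryModel, WallQuadrature, solve_outer_radius, luminal_pressure,
    NoSolutionError,
)
from .kinematics import InvalidConfigurationError

__all__ = [
    "NoiseScales", "FitConfig", "FitResult",
    "sse_objective", "r_squared", "fit_parameters",
    "MATERIAL_PARAMETERS", "GEOMETRIC_PARAMETERS",
]

#: names of the material parameters the optimizer may free
MATERIAL_PARAMETERS = (
    "k_IL", "k_E", "k_C", "M_C",
    "rho1", "rho2", "lam_max", "sigma_max", "tau", "k_smc_radial",
)

#: geometric parameters adjustable in refined_geometry / mean_value modes,
#: with their statistical (mean, sd) used to center the constraint boxes
GEOMETRIC_PARAMETERS = {
    "mu_E1": (0.25, 0.05), "sd_E1": (0.17, 0.07),
    "mu_E2": (1.84, 0.11), "sd_E2": (0.38, 0.11),
    "mu_C1": (0.32, 0.07), "sd_C1": (0.23, 0.06),
    "mu_C2": (1.81, 0.23), "sd_C2": (0.33, 0.10),
    "mu_M": (0.23, 0.06), "sd_M": (0.19, 0.08),
    "mu_SMC": (0.24, 0.04), "sd_SMC": (0.21, 0.07),
    "e0_mean": (0.35, 0.051), "e0_sd": (0.051, 0.02),
    "e_02": (0.35, 0.05),
    "e_01": (0.26, 0.03),  # mean-value adventitial straightening strain
}

#: default search bounds for material parameters (MPa / dimensionless);
#: generous physical ranges, overridable per fit
DEFAULT_MATERIAL_BOUNDS = {
    "k_IL": (0.0, 1.0), "k_E": (0.01, 1.0), "k_C": (1.0, 120.0),
    "M_C": (1.0, 10.0), "rho1": (0.0, 2.0), "rho2": (-2.0, 3.0),
    "lam_max": (1.0, 1.8), "sigma_max": (0.01, 0.3), "tau": (0.0, 1.5),
    "k_smc_radial": (0.0, 0.2),
}


@dataclass(frozen=True)
class NoiseScales:
    """Measurement SDs per channel and activation state (mm, mN)."""

    radius_passive: float
    force_passive: float
    radius_full: float
    force_full: float

    def __post_init__(self) -> None:
        if min(self.radius_passive, self.force_passive,
               self.radius_full, self.force_full) <= 0.0:
            raise ValueError("noise scales must be positive")


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one estimation run.

    ``free`` lists the material parameters to estimate with their bounds
    (defaults to all ten with the packaged physical ranges);
    ``geometry_halfwidth_sds`` sets the refined-mode box half-width in
    multiples of the statistical SDs.  ``seed`` fixes the optimizer
    trajectory completely.  ``quadrature`` is the forward-model
    resolution used inside the objective; ``solver_xtol`` the radius
    tolerance of the inner pressure→radius solves.

    The search stops at whichever comes first: the generation cap
    (``maxiter``), scipy's population-convergence test (``tol``), the
    best objective dropping below ``objective_floor`` (the SSE is
    noise-normalized, so a value this small means every residual is far
    below measurement precision), or stagnation — ``stall_generations``
    consecutive generations improving the best objective by less than
    ``stall_tol`` relative to ``max(best, objective_floor)``.  The final
    polish then refines the best member locally in every case.
    """

    mode: str = "statistical_fixed"
    free: Optional[Dict[str, Tuple[float, float]]] = None
    geometric_free: Optional[Sequence[str]] = None
    geometry_halfwidth_sds: float = 2.0
    popsize: int = 15
    maxiter: int = 300
    tol: float = 0.01
    stall_generations: int = 15
    stall_tol: float = 1e-3
    objective_floor: float = 1e-3
    seed: int = 0
    polish: bool = True
    two_stage: bool = False
    quadrature: WallQuadrature = WallQuadrature(16, 8, 8)
    solver_xtol: float = 1e-7

    def __post_init__(self) -> None:
        if self.mode not in ("statistical_fixed", "refined_geometry", "mean_value"):
            raise ValueError(f"unknown fit mode {self.mode!r}")
        if self.free is not None:
            for name, (lo, hi) in self.free.items():
                if name not in MATERIAL_PARAMETERS:
                    raise ValueError(f"unknown material parameter {name!r}")
                if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                    raise ValueError(f"bad bounds for {name!r}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a fit: parameters, objective, goodness of fit, trace."""

    parameters: Dict[str, float]
    sse: float
    r2: Dict[str, float]          # e.g. r2_radius_passive, r2_force_full, ...
    trace: Tuple[float, ...]      # per-generation best objective
    n_evaluations: int
    converged: bool
    mode: str
    seed: int


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need >= 2 paired observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined: observations have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("pressure_mmHg", "lambda_z", "state",
                     "r_outer_mm", "axial_force_mN")


def _check_dataset(df: pd.DataFrame) -> None:
    for c in _REQUIRED_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"dataset is missing column {c!r}")
    states = set(df["state"])
    if not {"passive", "full"} <= states:
        missing = {"passive", "full"} - states
        raise ValueError(f"dataset lacks required activation state(s): {missing}")


def _grid(df: pd.DataFrame):
    pressures = np.sort(df["pressure_mmHg"].unique())
    stretches = np.sort(df["lambda_z"].unique())
    return pressures, stretches


def _predict_table(model: ArteryModel, pressures, stretches,
                   solver_xtol: float = 1e-10,
                   radius_cache: Optional[dict] = None) -> pd.DataFrame:
    """Forward predictions over the protocol grid.

    ``radius_cache`` maps (pressure, stretch, state) to the radius found
    on a previous call (e.g. the preceding optimizer trial); those radii
    seed tight root brackets, as do secant extrapolations along each
    ascending pressure sweep.
    """
    from .wall_mechanics import axial_force
    recs = []
    for state, A in (("passive", 0.0), ("full", 1.0)):
        for lam_z in stretches:
            prev = []  # (pressure, radius) history for secant warm starts
            for p in pressures:
                cached = None if radius_cache is None else \
                    radius_cache.get((p, lam_z, state))
                r_o = None
                if cached is not None:
                    r_o = _secant_radius(model, lam_z, p, A, cached,
                                         solver_xtol)
                if r_o is None:
                    if cached is not None:
                        bracket = (cached * 0.98, cached * 1.02)
                    elif len(prev) >= 2 and prev[-1][1] > prev[-2][1]:
                        (p0, r0), (p1, r1) = prev[-2], prev[-1]
                        guess = r1 + (r1 - r0) * (p - p1) / max(p1 - p0, 1e-9)
                        bracket = (min(r1, guess * 0.98), guess * 1.05)
                    elif prev:
                        bracket = (prev[-1][1] * 0.999, prev[-1][1] * 1.15)
                    else:
                        bracket = None
                    r_o = solve_outer_radius(model, lam_z, p, A,
                                             bracket=bracket, xtol=solver_xtol)
                prev.append((p, r_o))
                if radius_cache is not None:
                    radius_cache[(p, lam_z, state)] = r_o
                F, N = axial_force(model, lam_z, r_o, A)
                recs.append((p, lam_z, state, r_o, F, N))
    return pd.DataFrame(recs, columns=["pressure_mmHg", "lambda_z", "state",
                                       "r_outer_mm", "axial_force_mN",
                                       "axial_tension_mN"])


def _secant_radius(model: ArteryModel, lam_z: float, target: float, A: float,
                   x0: float, xtol: float, max_iter: int = 12):
    """Unsafeguarded secant iteration from a warm start; None on failure.

    Used inside the fit objective where the previous trial's radius is an
    excellent initial guess; any breakdown falls back to the bracketed
    solver.
    """
    try:
        f0 = luminal_pressure(model, lam_z, x0, A) - target
        x1 = x0 * (1.0 + 1e-4)
        f1 = luminal_pressure(model, lam_z, x1, A) - target
        for _ in range(max_iter):
            denom = f1 - f0
            if denom == 0.0:
                return None
            x2 = x1 - f1 * (x1 - x0) / denom
            if not (0.0 < x2 < 4.0 * model.geometry.r_outer) or \
                    abs(x2 - x1) > 0.3 * x1:
                return None
            if abs(x2 - x1) < xtol:
                return float(x2)
            x0, f0, x1 = x1, f1, x2
            f1 = luminal_pressure(model, lam_z, x1, A) - target
        return None
    except (InvalidConfigurationError, ValueError, FloatingPointError):
        return None


def sse_objective(model: ArteryModel, dataset: pd.DataFrame, noise: NoiseScales,
                  solver_xtol: float = 1e-10) -> float:
    """Studentized SSE of the model against a passive+full biaxial dataset."""
    _check_dataset(dataset)
    pressures, stretches = _grid(dataset)
    pred = _predict_table(model, pressures, stretches, solver_xtol)
    return _sse_from_tables(dataset, pred, noise, len(pressures), len(stretches))


def _sse_from_tables(dataset: pd.DataFrame, pred: pd.DataFrame,
                     noise: NoiseScales, n: int, m: int) -> float:
    key = ["pressure_mmHg", "lambda_z", "state"]
    merged = dataset.merge(pred, on=key, suffixes=("", "_model"))
    if len(merged) < len(dataset):
        raise ValueError("model predictions do not cover every data record")
    sd_r = np.where(merged["state"] == "passive",
                    noise.radius_passive, noise.radius_full)
    sd_f = np.where(merged["state"] == "passive",
                    noise.force_passive, noise.force_full)
    zr = (merged["r_outer_mm"] - merged["r_outer_mm_model"]) / sd_r
    zf = (merged["axial_force_mN"] - merged["axial_force_mN_model"]) / sd_f
    return float((zr**2 + zf**2).sum()) / (n * m)


# ---------------------------------------------------------------------------
# parameter application
# ---------------------------------------------------------------------------

def _apply_material(model: ArteryModel, values: Dict[str, float]) -> ArteryModel:
    pas = {k: v for k, v in values.items() if k in ("k_IL", "k_E", "k_C", "M_C")}
    act = {k: v for k, v in values.items()
           if k in ("rho1", "rho2", "lam_max", "sigma_max", "tau", "k_smc_radial")}
    if pas:
        model = replace(model, passive=replace(model.passive, **pas))
    if act:
        model = replace(model, smc=replace(model.smc, **act))
    return model


def _geometry_values(micro: MicrostructureConfig) -> Dict[str, float]:
    g = {}
    for pref, mix in (("E", micro.adv_elastin), ("C", micro.adv_collagen)):
        for j, comp in enumerate(mix.components, start=1):
            g[f"mu_{pref}{j}"] = comp.mean_angle
            g[f"sd_{pref}{j}"] = comp.sd_angle
    g["mu_M"], g["sd_M"] = micro.media_fiber.mean_angle, micro.media_fiber.sd_angle
    g["mu_SMC"], g["sd_SMC"] = micro.media_smc.mean_angle, micro.media_smc.sd_angle
    if micro.adv_recruitment.kind == "point":
        g["e_01"] = micro.adv_recruitment.point_value
    else:
        g["e0_mean"] = micro.adv_recruitment.mean
        g["e0_sd"] = micro.adv_recruitment.sd
    if micro.media_recruitment.kind == "point":
        g["e_02"] = micro.media_recruitment.point_value
    else:
        g["e_02"] = micro.media_recruitment.upper
    return g


def _build_micro(base: MicrostructureConfig, g: Dict[str, float]
                 ) -> MicrostructureConfig:
    """Rebuild a microstructure configuration from named geometric values."""
    mean_value = base.mode == "mean_value"

    def fam(mu, sd, support):
        return OrientationDistribution(mu, 0.0 if mean_value else sd, support)

    adv_elastin = OrientationMixture(
        (fam(g["mu_E1"], g.get("sd_E1", 0.0), FULL_PLANE),
         fam(g["mu_E2"], g.get("sd_E2", 0.0), FULL_PLANE)),
        base.adv_elastin.weights)
    adv_collagen = OrientationMixture(
        (fam(g["mu_C1"], g.get("sd_C1", 0.0), FULL_PLANE),
         fam(g["mu_C2"], g.get("sd_C2", 0.0), FULL_PLANE)),
        base.adv_collagen.weights)
    if mean_value:
        adv_rec = RecruitmentDistribution("point", point_value=g["e_01"])
        media_rec = RecruitmentDistribution("point", point_value=g["e_02"])
    else:
        adv_rec = RecruitmentDistribution.from_moments(
            g["e0_mean"], g["e0_sd"],
            base.adv_recruitment.lower, base.adv_recruitment.upper)
        media_rec = RecruitmentDistribution("uniform", lower=0.0, upper=g["e_02"])
    return MicrostructureConfig(
        adv_elastin=adv_elastin, adv_collagen=adv_collagen,
        adv_recruitment=adv_rec,
        media_fiber=fam(g["mu_M"], g.get("sd_M", 0.0), HALF_PLANE),
        media_smc=fam(g["mu_SMC"], g.get("sd_SMC", 0.0), HALF_PLANE),
        media_recruitment=media_rec,
        mode=base.mode,
    )


def _geometric_parameter_set(cfg: FitConfig) -> list:
    if cfg.geometric_free is not None:
        return list(cfg.geometric_free)
    if cfg.mode == "refined_geometry":
        return ["mu_E1", "sd_E1", "mu_E2", "sd_E2",
                "mu_C1", "sd_C1", "mu_C2", "sd_C2",
                "mu_M", "sd_M", "mu_SMC", "sd_SMC",
                "e0_mean", "e0_sd", "e_02"]
    if cfg.mode == "mean_value":
        return ["mu_E1", "mu_E2", "mu_C1", "mu_C2", "mu_M", "mu_SMC",
                "e_01", "e_02"]
    return []


def _geometric_bounds(names, halfwidth_sds: float) -> Dict[str, Tuple[float, float]]:
    out = {}
    for name in names:
        mean, sd = GEOMETRIC_PARAMETERS[name]
        lo, hi = mean - halfwidth_sds * sd, mean + halfwidth_sds * sd
        if name.startswith(("sd_",)) or name.startswith("e0") or name.startswith("e_"):
            lo = max(lo, 1e-3)
        else:
            lo = max(lo, 0.0)
        out[name] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------

_PENALTY = 1e8


def fit_parameters(dataset: pd.DataFrame, model: ArteryModel, noise: NoiseScales,
                   fit_config: FitConfig = FitConfig(),
                   x0: Optional[Dict[str, float]] = None) -> FitResult:
    """Estimate material (and optionally geometric) parameters from data.

    ``model`` supplies the fixed quantities (geometry, composition) and
    the starting microstructure; ``x0``, if given, is a parameter set
    injected into the initial population (used e.g. to seed a refined-
    geometry run with a fixed-mode optimum, making the nested-model
    inequality hold by construction).  Deterministic given
    ``fit_config.seed``.
    """
    _check_dataset(dataset)
    cfg = fit_config
    pressures, stretches = _grid(dataset)
    n, m = len(pressures), len(stretches)

    base_micro = model.micro
    if cfg.mode == "mean_value" and base_micro.mode != "mean_value":
        base_micro = base_micro.collapse_to_mean_value()
    work_model = replace(model, micro=base_micro, quadrature=cfg.quadrature)

    free_mat = dict(cfg.free) if cfg.free is not None else dict(DEFAULT_MATERIAL_BOUNDS)
    geo_names = _geometric_parameter_set(cfg)
    geo_bounds = _geometric_bounds(geo_names, cfg.geometry_halfwidth_sds)
    names = list(free_mat) + geo_names
    bounds = [free_mat[k] for k in free_mat] + [geo_bounds[k] for k in geo_names]
    base_geo = _geometry_values(base_micro)

    def make_model(x: np.ndarray) -> ArteryModel:
        vals = dict(zip(names, x))
        mdl = _apply_material(work_model, vals)
        if geo_names:
            g = dict(base_geo)
            g.update({k: vals[k] for k in geo_names})
            mdl = replace(mdl, micro=_build_micro(base_micro, g))
        return mdl

    n_eval = [0]
    radius_cache: dict = {}

    def objective(x: np.ndarray) -> float:
        n_eval[0] += 1
        try:
            mdl = make_model(x)
            pred = _predict_table(mdl, pressures, stretches, cfg.solver_xtol,
                                  radius_cache)
            return _sse_from_tables(dataset, pred, noise, n, m)
        except (NoSolutionError, InvalidConfigurationError, ValueError):
            return _PENALTY

    trace: list = []

    def callback(xk, convergence=None):
        trace.append(objective_best[0])
        cur = trace[-1]
        # floor stop: residuals already far below measurement precision
        if cur < cfg.objective_floor:
            return True
        # stagnation stop: no meaningful best-value improvement over the
        # last `stall_generations` generations (polish still runs after)
        k = cfg.stall_generations
        if k > 0 and len(trace) > k:
            prev = trace[-k - 1]
            if prev - cur <= cfg.stall_tol * max(cur, cfg.objective_floor):
                return True
        return False

    objective_best = [np.inf]

    def tracking_objective(x):
        v = objective(x)
        if v < objective_best[0]:
            objective_best[0] = v
        return v

    init = "latinhypercube"
    if x0 is not None:
        rng = np.random.default_rng(cfg.seed)
        dim = len(names)
        n_pop = max(cfg.popsize * dim, 5)
        pop = rng.uniform(size=(n_pop, dim))
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        pop = lo + pop * (hi - lo)
        seeded = np.array([np.clip(x0.get(k, base_geo.get(k, np.nan)), *b)
                           for k, b in zip(names, bounds)])
        if np.any(np.isnan(seeded)):
            missing = [k for k, v in zip(names, seeded) if np.isnan(v)]
            raise ValueError(f"x0 lacks values for {missing}")
        pop[0] = seeded
        init = pop

    result = differential_evolution(
        tracking_objective, bounds, seed=cfg.seed, popsize=cfg.popsize,
        maxiter=cfg.maxiter, tol=cfg.tol, polish=cfg.polish, init=init,
        updating="immediate", callback=callback,
    )

    best = dict(zip(names, result.x))
    best_model = make_model(result.x)
    pred = _predict_table(best_model, pressures, stretches, cfg.solver_xtol)
    r2 = _per_channel_r2(dataset, pred, best_model)

    all_params = {k: getattr(best_model.passive, k) for k in
                  ("k_IL", "k_E", "k_C", "M_C")}
    all_params.update({k: getattr(best_model.smc, k) for k in
                       ("rho1", "rho2", "lam_max", "sigma_max", "tau",
                        "k_smc_radial")})
    all_params.update({k: v for k, v in best.items() if k in geo_names})
    return FitResult(
        parameters=all_params,
        sse=float(result.fun),
        r2=r2,
        trace=tuple(trace),
        n_evaluations=n_eval[0],
        converged=bool(result.success),
        mode=cfg.mode,
        seed=cfg.seed,
    )


def _per_channel_r2(dataset: pd.DataFrame, pred: pd.DataFrame,
                    model: ArteryModel) -> Dict[str, float]:
    """R² for radius and force per state, plus pressure recovered from the
    measured radii (the forward pressure at each observed radius)."""
    key = ["pressure_mmHg", "lambda_z", "state"]
    merged = dataset.merge(pred, on=key, suffixes=("", "_model"))
    out = {}
    for state in ("passive", "full"):
        sub = merged[merged["state"] == state]
        A = 1.0 if state == "full" else 0.0
        out[f"r2_radius_{state}"] = r_squared(sub["r_outer_mm"],
                                              sub["r_outer_mm_model"])
        out[f"r2_force_{state}"] = r_squared(sub["axial_force_mN"],
                                             sub["axial_force_mN_model"])
        try:
            p_pred = [luminal_pressure(model, lz, r, A)
                      for lz, r in zip(sub["lambda_z"], sub["r_outer_mm"])]
            out[f"r2_pressure_{state}"] = r_squared(sub["pressure_mmHg"], p_pred)
        except (InvalidConfigurationError, ValueError):
            out[f"r2_pressure_{state}"] = float("nan")
    return out


def two_stage_fit(dataset: pd.DataFrame, model: ArteryModel, noise: NoiseScales,
                  fit_config: FitConfig = FitConfig()) -> FitResult:
    """Passive-then-active fitting (optional alternative to the joint fit).

    Stage 1 estimates the passive fiber parameters against the passive
    records only; stage 2 freezes them and estimates the SMC parameters
    against the full records.  The joint objective is reported for the
    combined optimum so results are comparable with ``fit_parameters``.
    """
    free = dict(fit_config.free) if fit_config.free is not None \
        else dict(DEFAULT_MATERIAL_BOUNDS)
    passive_free = {k: v for k, v in free.items()
                    if k in ("k_IL", "k_E", "k_C", "M_C")}
    active_free = {k: v for k, v in free.items() if k not in passive_free}

    # stage 1: passive channels only — duplicate passive rows as both states
    # so the joint machinery applies with the active channels neutralized
    passive_rows = dataset[dataset["state"] == "passive"]
    stage1 = pd.concat([passive_rows,
                        passive_rows.assign(state="full")], ignore_index=True)
    cfg1 = replace(fit_config, free=passive_free)
    res1 = fit_parameters(stage1, model, noise, cfg1)
    model1 = _apply_material(model, {k: res1.parameters[k] for k in passive_free})

    cfg2 = replace(fit_config, free=active_free)
    res2 = fit_parameters(dataset, model1, noise, cfg2)
    return replace(res2, trace=res1.trace + res2.trace,
                   n_evaluations=res1.n_evaluations + res2.n_evaluations)
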