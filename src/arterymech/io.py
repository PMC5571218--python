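"""Configuration parsing and tabular file I/O.

Run configurations are YAML (JSON is a subset and parses identically)
with strict key checking; experiment datasets travel as a CSV of records
plus a JSON sidecar carrying geometry, noise scales, truth parameters
and seed.  Every file the package writes embeds the tool version, a hash
of the resolved configuration, and the seed, as ``#``-prefixed comment
lines that pandas skips on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinematics import ReferenceGeometry
from .microstructure import (
    MicrostructureConfig, OrientationDistribution, OrientationMixture,
    RecruitmentDistribution, LayerComposition, WallComposition,
    statistical_default_config, FULL_PLANE, HALF_PLANE,
)
from .fiber_constitutive import PassiveFiberParams
from .smc_active import SMCActiveParams
from .wall_mechanics import (
    ArteryModel, WallQuadrature, DEFAULT_PRESSURES, DEFAULT_STRETCHES,
    DEFAULT_STATES,
)
from .estimation import NoiseScales, FitConfig
from .synthetic_data import ExperimentDataset

__all__ = [
    "RunConfig", "load_run_config", "default_run_config", "config_hash",
    "load_experiment_table", "save_experiment_dataset", "load_experiment_dataset",
    "save_predictions", "save_profile", "save_fit_report",
]

EXPERIMENT_COLUMNS = ("pressure_mmHg", "lambda_z", "state",
                      "r_outer_mm", "axial_force_mN")


class ConfigError(ValueError):
    """A run configuration failed validation."""


def _take(d: dict, context: str, **fields):
    """Pop known fields with defaults; reject unknown keys."""
    d = dict(d)
    out = {}
    for name, default in fields.items():
        out[name] = d.pop(name, default)
    if d:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(d)}")
    return out


_REQ = object()


def _need(vals: dict, context: str):
    missing = [k for k, v in vals.items() if v is _REQ]
    if missing:
        raise ConfigError(f"missing key(s) in {context}: {missing}")
    return vals


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration."""

    model: ArteryModel
    protocol_pressures: tuple
    protocol_stretches: tuple
    protocol_states: tuple
    noise: Optional[NoiseScales]
    fit: FitConfig
    seed: int


def _parse_geometry(block: dict) -> ReferenceGeometry:
    v = _need(_take(block, "geometry", r_outer=_REQ, r_inner=_REQ,
                    opening_angle=_REQ, length_ref=10.0), "geometry")
    return ReferenceGeometry(**v)


def _parse_mixture(block: dict, context: str, support) -> OrientationMixture:
    v = _need(_take(block, context, mu1=_REQ, sd1=_REQ, mu2=_REQ, sd2=_REQ,
                    weight1=0.5), context)
    return OrientationMixture(
        (OrientationDistribution(v["mu1"], v["sd1"], support),
         OrientationDistribution(v["mu2"], v["sd2"], support)),
        (v["weight1"], 1.0 - v["weight1"]),
    )


def _parse_recruitment(block: dict, context: str) -> RecruitmentDistribution:
    kind = block.get("kind", "beta")
    if kind == "beta":
        v = _need(_take(block, context, kind="beta", mean=_REQ, sd=_REQ,
                        lower=0.0, upper=1.0), context)
        return RecruitmentDistribution.from_moments(
            v["mean"], v["sd"], v["lower"], v["upper"])
    if kind == "uniform":
        v = _need(_take(block, context, kind="uniform", lower=0.0, upper=_REQ),
                  context)
        return RecruitmentDistribution("uniform", lower=v["lower"], upper=v["upper"])
    if kind == "point":
        v = _need(_take(block, context, kind="point", value=_REQ), context)
        return RecruitmentDistribution("point", point_value=v["value"])
    raise ConfigError(f"unknown recruitment kind {kind!r} in {context}")


def _parse_family(block: dict, context: str) -> OrientationDistribution:
    v = _need(_take(block, context, mu=_REQ, sd=_REQ), context)
    return OrientationDistribution(v["mu"], v["sd"], HALF_PLANE)


def _parse_micro(block: Optional[dict]) -> MicrostructureConfig:
    if block is None:
        return statistical_default_config()
    v = _take(block, "microstructure", mode="full", adventitia_elastin=None,
              adventitia_collagen=None, adventitia_recruitment=None,
              media_fiber=None, media_smc=None, media_recruitment=None)
    base = statistical_default_config()
    micro = MicrostructureConfig(
        adv_elastin=_parse_mixture(v["adventitia_elastin"],
                                   "adventitia_elastin", FULL_PLANE)
        if v["adventitia_elastin"] else base.adv_elastin,
        adv_collagen=_parse_mixture(v["adventitia_collagen"],
                                    "adventitia_collagen", FULL_PLANE)
        if v["adventitia_collagen"] else base.adv_collagen,
        adv_recruitment=_parse_recruitment(v["adventitia_recruitment"],
                                           "adventitia_recruitment")
        if v["adventitia_recruitment"] else base.adv_recruitment,
        media_fiber=_parse_family(v["media_fiber"], "media_fiber")
        if v["media_fiber"] else base.media_fiber,
        media_smc=_parse_family(v["media_smc"], "media_smc")
        if v["media_smc"] else base.media_smc,
        media_recruitment=_parse_recruitment(v["media_recruitment"],
                                             "media_recruitment")
        if v["media_recruitment"] else base.media_recruitment,
        mode="full",
    )
    if v["mode"] == "mean_value":
        micro = micro.collapse_to_mean_value()
    elif v["mode"] != "full":
        raise ConfigError(f"unknown microstructure mode {v['mode']!r}")
    return micro


def _parse_composition(block: Optional[dict]) -> WallComposition:
    if block is None:
        from .wall_mechanics import default_model
        return default_model().composition
    v = _need(_take(block, "composition", media_fraction=_REQ, media=_REQ,
                    adventitia=_REQ), "composition")

    def layer(b, ctx):
        lv = _need(_take(b, ctx, f_IL=0.0, f_E=_REQ, f_C=_REQ, f_SMC=0.0), ctx)
        return LayerComposition(**lv)

    return WallComposition(
        media_fraction_of_thickness=v["media_fraction"],
        media=layer(v["media"], "composition.media"),
        adventitia=layer(v["adventitia"], "composition.adventitia"),
    )


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("run configuration must be a mapping")
    v = _take(raw, "run config", seed=0, geometry=None, microstructure=None,
              composition=None, passive=None, active=None, protocol=None,
              noise=None, fit=None, quadrature=None)
    from .wall_mechanics import default_model
    base = default_model()
    geometry = _parse_geometry(v["geometry"]) if v["geometry"] else base.geometry
    passive = PassiveFiberParams(**_need(_take(
        v["passive"] or {}, "passive", k_IL=base.passive.k_IL,
        k_E=base.passive.k_E, k_C=base.passive.k_C, M_C=base.passive.M_C),
        "passive"))
    act = _need(_take(v["active"] or {}, "active",
                      rho1=base.smc.rho1, rho2=base.smc.rho2,
                      lam_max=base.smc.lam_max, sigma_max=base.smc.sigma_max,
                      tau=base.smc.tau, k_smc_radial=base.smc.k_smc_radial,
                      activation=1.0), "active")
    quad = WallQuadrature(**_need(_take(
        v["quadrature"] or {}, "quadrature", n_angle=64, n_recruit=32,
        n_radial=32), "quadrature"))
    model = ArteryModel(
        geometry=geometry, micro=_parse_micro(v["microstructure"]),
        composition=_parse_composition(v["composition"]), passive=passive,
        smc=SMCActiveParams(**act), quadrature=quad,
    )
    proto = _need(_take(v["protocol"] or {}, "protocol",
                        pressures_mmHg=list(DEFAULT_PRESSURES),
                        stretches=list(DEFAULT_STRETCHES),
                        states=list(DEFAULT_STATES)), "protocol")
    noise = None
    if v["noise"]:
        nv = _need(_take(v["noise"], "noise", radius_passive=_REQ,
                         force_passive=_REQ, radius_full=_REQ,
                         force_full=_REQ), "noise")
        noise = NoiseScales(**nv)
    fv = _need(_take(v["fit"] or {}, "fit", mode="statistical_fixed",
                     free=None, geometry_halfwidth_sds=2.0, popsize=15,
                     maxiter=300, tol=0.01, stall_generations=15,
                     stall_tol=1e-3, objective_floor=1e-3,
                     seed=v["seed"], two_stage=False),
               "fit")
    if fv["free"] is not None:
        fv["free"] = {k: tuple(b) for k, b in fv["free"].items()}
    fit = FitConfig(**fv)
    return RunConfig(
        model=model, protocol_pressures=tuple(proto["pressures_mmHg"]),
        protocol_stretches=tuple(proto["stretches"]),
        protocol_states=tuple(proto["states"]), noise=noise, fit=fit,
        seed=v["seed"],
    )


def default_run_config(seed: int = 0) -> RunConfig:
    """The packaged defaults as a resolved RunConfig."""
    from .wall_mechanics import default_model
    return RunConfig(
        model=default_model(), protocol_pressures=DEFAULT_PRESSURES,
        protocol_stretches=DEFAULT_STRETCHES, protocol_states=DEFAULT_STATES,
        noise=None, fit=FitConfig(seed=seed), seed=seed,
    )


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration view."""
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(seed, cfg_hash) -> str:
    return (f"# arterymech {__version__}\n"
            f"# config_hash: {cfg_hash}\n"
            f"# seed: {seed}\n")


def _write_csv(df: pd.DataFrame, path, seed, cfg_hash) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_stamp(seed, cfg_hash))
        df.to_csv(fh, index=False)


def load_experiment_table(path) -> pd.DataFrame:
    """Read and validate a CSV of biaxial experiment records.

    Errors name the offending column or cell; pressures must lie in
    [0, 160] mmHg and states must be ``passive``/``full``.
    """
    df = pd.read_csv(path, comment="#")
    for col in EXPERIMENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in ("pressure_mmHg", "lambda_z", "r_outer_mm", "axial_force_mN"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(f"{path}: non-numeric value in column {col!r}, "
                             f"row {row}")
        df[col] = vals
    bad_state = ~df["state"].isin(["passive", "full"])
    if bad_state.any():
        row = int(bad_state.idxmax())
        raise ValueError(f"{path}: invalid state in row {row}")
    out_of_range = (df["pressure_mmHg"] < 0) | (df["pressure_mmHg"] > 160)
    if out_of_range.any():
        row = int(out_of_range.idxmax())
        raise ValueError(f"{path}: pressure out of [0, 160] mmHg in row {row}")
    return df


def save_experiment_dataset(ds: ExperimentDataset, csv_path) -> None:
    """Write records CSV plus a JSON sidecar with geometry/noise/truth/seed."""
    cfg = {"geometry": dataclasses.asdict(ds.geometry),
           "noise": dataclasses.asdict(ds.noise), "truth": ds.truth,
           "seed": ds.seed}
    h = config_hash(cfg)
    _write_csv(ds.records, csv_path, ds.seed, h)
    sidecar = Path(csv_path).with_suffix(".meta.json")
    cfg["version"] = __version__
    cfg["config_hash"] = h
    sidecar.write_text(json.dumps(cfg, indent=2, sort_keys=True))


def load_experiment_dataset(csv_path) -> ExperimentDataset:
    """Round-trip companion of :func:`save_experiment_dataset`."""
    records = load_experiment_table(csv_path)
    meta = json.loads(Path(csv_path).with_suffix(".meta.json").read_text())
    return ExperimentDataset(
        records=records,
        geometry=ReferenceGeometry(**meta["geometry"]),
        noise=NoiseScales(**meta["noise"]),
        seed=meta["seed"],
        truth=meta.get("truth"),
    )


def save_predictions(records, path, seed, cfg_hash) -> None:
    df = pd.DataFrame(
        [(r.pressure, r.axial_stretch, r.state, r.outer_radius,
          r.axial_force, r.axial_tension) for r in records],
        columns=["pressure_mmHg", "lambda_z", "state", "r_outer_mm",
                 "axial_force_mN", "axial_tension_mN"],
    )
    _write_csv(df, path, seed, cfg_hash)


def save_profile(profile: np.ndarray, path, seed, cfg_hash) -> None:
    df = pd.DataFrame(profile, columns=["r_mm", "sigma_rr_MPa",
                                        "sigma_tt_MPa", "sigma_zz_MPa"])
    _write_csv(df, path, seed, cfg_hash)


def save_fit_report(result, csv_path, json_path, seed, cfg_hash) -> None:
    """Fit report: parameter CSV plus a structured JSON summary."""
    df = pd.DataFrame(sorted(result.parameters.items()),
                      columns=["parameter", "estimate"])
    _write_csv(df, csv_path, seed, cfg_hash)
    summary = {
        "version": __version__, "config_hash": cfg_hash, "seed": seed,
        "mode": result.mode, "sse": result.sse, "r2": result.r2,
        "parameters": result.parameters, "converged": result.converged,
        "n_evaluations": result.n_evaluations,
        "trace": list(result.trace),
    }
    Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True))
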