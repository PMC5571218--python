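"""Pseudo-experimental biaxial datasets for the distension–extension protocol.

Emulates the bench protocol the estimation stage assumes: intravascular
pressure swept 0→160 mmHg in 20 mmHg increments at axial stretches 1.3
and 1.5, once fully relaxed (passive) and once under maximal K⁺-induced
smooth-muscle contraction (full), with additive zero-mean Gaussian
measurement noise on the outer-radius and axial-force channels.  The
generating parameter set (the "truth") travels with the dataset so
recovery experiments can be scored.

Reference geometries are drawn from documented porcine LAD-scale ranges
(the source studies do not publish their specimens' zero-stress-state
dimensions, so these are declared synthetic defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinematics import ReferenceGeometry
from .wall_mechanics import (
    ArteryModel, simulate_protocol, DEFAULT_PRESSURES, DEFAULT_STRETCHES,
    DEFAULT_STATES,
)
from .estimation import NoiseScales

__all__ = [
    "ExperimentDataset", "generate_reference_geometry", "generate_experiment",
    "add_measurement_noise", "default_noise_scales",
]

#: plausible porcine LAD zero-stress-state ranges (synthetic defaults)
_GEOM_RANGES = {
    "outer_radius": (2.0, 3.0),        # mm
    "wall_to_outer_ratio": (0.2, 0.35),
    "opening_angle": (0.5, 2.5),       # rad
    "length": (8.0, 12.0),             # mm
}

#: default measurement noise as a fraction of each channel's signal range
DEFAULT_NOISE_FRACTION = 0.02


@dataclass(frozen=True)
class ExperimentDataset:
    """Records plus the provenance needed to reproduce or score them."""

    records: pd.DataFrame
    geometry: ReferenceGeometry
    noise: NoiseScales
    seed: int
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        grid = self.records.groupby(["lambda_z", "state"])["pressure_mmHg"].count()
        if grid.nunique() > 1:
            raise ValueError("records do not cover a full factorial schedule")


def generate_reference_geometry(seed: int) -> ReferenceGeometry:
    """Draw a plausible zero-stress-state geometry, deterministic per seed."""
    rng = np.random.default_rng(seed)
    r_o = rng.uniform(*_GEOM_RANGES["outer_radius"])
    wall = r_o * rng.uniform(*_GEOM_RANGES["wall_to_outer_ratio"])
    return ReferenceGeometry(
        r_outer=r_o,
        r_inner=r_o - wall,
        opening_angle=rng.uniform(*_GEOM_RANGES["opening_angle"]),
        length_ref=rng.uniform(*_GEOM_RANGES["length"]),
    )


def _truth_dict(model: ArteryModel) -> dict:
    t = {k: getattr(model.passive, k) for k in ("k_IL", "k_E", "k_C", "M_C")}
    t.update({k: getattr(model.smc, k) for k in
              ("rho1", "rho2", "lam_max", "sigma_max", "tau", "k_smc_radial")})
    return t


def _simulate_table(model: ArteryModel, pressures, stretches, states
                    ) -> pd.DataFrame:
    recs = simulate_protocol(model, list(pressures), list(stretches), list(states))
    return pd.DataFrame(
        [(r.pressure, r.axial_stretch, r.state, r.outer_radius,
          r.axial_force, r.axial_tension) for r in recs],
        columns=["pressure_mmHg", "lambda_z", "state", "r_outer_mm",
                 "axial_force_mN", "axial_tension_mN"],
    )


def default_noise_scales(signal: pd.DataFrame,
                         fraction: float = DEFAULT_NOISE_FRACTION) -> NoiseScales:
    """Noise SDs as a fraction of each channel's range, per state."""
    def rng_of(col, state):
        v = signal.loc[signal["state"] == state, col]
        return float(v.max() - v.min())

    return NoiseScales(
        radius_passive=fraction * rng_of("r_outer_mm", "passive"),
        force_passive=fraction * rng_of("axial_force_mN", "passive"),
        radius_full=fraction * rng_of("r_outer_mm", "full"),
        force_full=fraction * rng_of("axial_force_mN", "full"),
    )


def add_measurement_noise(signal: pd.DataFrame, noise: NoiseScales,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Independent zero-mean Gaussian noise on the radius/force channels."""
    out = signal.copy()
    passive = (out["state"] == "passive").to_numpy()
    sd_r = np.where(passive, noise.radius_passive, noise.radius_full)
    sd_f = np.where(passive, noise.force_passive, noise.force_full)
    out["r_outer_mm"] = out["r_outer_mm"] + rng.normal(0.0, 1.0, len(out)) * sd_r
    out["axial_force_mN"] = (out["axial_force_mN"]
                             + rng.normal(0.0, 1.0, len(out)) * sd_f)
    return out


def generate_experiment(model: ArteryModel, noise: Optional[NoiseScales] = None,
                        seed: int = 0,
                        pressures: Sequence[float] = DEFAULT_PRESSURES,
                        stretches: Sequence[float] = DEFAULT_STRETCHES,
                        states: Sequence[str] = DEFAULT_STATES,
                        n_replicates: int = 1,
                        noiseless: bool = False) -> ExperimentDataset:
    """Simulate the full protocol on ``model`` and add measurement noise.

    ``model`` carries the truth parameters and geometry.  When ``noise``
    is omitted the SDs default to 2 % of each channel's noiseless range.
    ``noiseless=True`` (or zero-variance would-be scales) returns the
    forward-model outputs exactly.  A generation failure at any grid
    point names the offending (pressure, stretch, state).
    """
    try:
        signal = _simulate_table(model, pressures, stretches, states)
    except Exception as ex:  # annotate which grid point failed
        raise RuntimeError(f"forward solve failed while generating the "
                           f"protocol grid: {ex}") from ex
    if noise is None:
        noise = default_noise_scales(signal)
    rng = np.random.default_rng(seed)
    reps = []
    for rep in range(n_replicates):
        tbl = signal.copy() if noiseless else add_measurement_noise(
            signal, noise, rng)
        tbl.insert(0, "replicate", rep)
        reps.append(tbl)
    records = pd.concat(reps, ignore_index=True)
    return ExperimentDataset(
        records=records, geometry=model.geometry, noise=noise, seed=seed,
        truth=_truth_dict(model),
    )
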