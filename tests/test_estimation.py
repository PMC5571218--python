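"""Objective function, goodness of fit, and the global fitting machinery.

Full-budget recovery runs live in the acceptance suite; here the
optimizer is exercised with small populations and generation budgets on
reduced protocols, which is enough to verify the contracts (determinism,
nested-model inequality, bound handling) without long runtimes.
"""

from dataclasses import replace

import numpy as np
import pytest

from arterymech.estimation import (
    NoiseScales, FitConfig, fit_parameters, r_squared, sse_objective,
    two_stage_fit, _sse_from_tables,
)
from arterymech.wall_mechanics import WallQuadrature
from arterymech.synthetic_data import generate_experiment

SMALL_PRESSURES = (0.0, 40.0, 80.0, 120.0, 160.0)
SMALL_FIT = FitConfig(popsize=6, maxiter=12, tol=0.05, seed=7,
                      quadrature=WallQuadrature(16, 8, 8))


@pytest.fixture(scope="module")
def small_dataset(fast_model):
    ds = generate_experiment(fast_model, seed=11, noiseless=True,
                             pressures=SMALL_PRESSURES, stretches=(1.3,))
    return ds


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 2.0])


class TestObjective:
    def test_zero_for_self_consistent_data(self, fast_model, small_dataset):
        val = sse_objective(fast_model, small_dataset.records,
                            small_dataset.noise, solver_xtol=1e-9)
        assert val < 1e-6

    def test_one_sigma_residual_everywhere_gives_four(self, small_dataset):
        """Shifting every channel by exactly 1 SD → SSE = 4 by hand."""
        noise = small_dataset.noise
        pred = small_dataset.records.rename(columns={})
        shifted = pred.copy()
        passive = shifted["state"] == "passive"
        shifted["r_outer_mm"] += np.where(passive, noise.radius_passive,
                                          noise.radius_full)
        shifted["axial_force_mN"] += np.where(passive, noise.force_passive,
                                              noise.force_full)
        n = shifted["pressure_mmHg"].nunique()
        m = shifted["lambda_z"].nunique()
        val = _sse_from_tables(shifted, pred.assign(axial_tension_mN=0.0),
                               noise, n, m)
        assert val == pytest.approx(4.0, rel=1e-12)

    def test_doubling_noise_quarters_objective(self, small_dataset):
        pred = small_dataset.records.copy()
        data = pred.copy()
        data["r_outer_mm"] += 0.01
        data["axial_force_mN"] += 1.0
        n = data["pressure_mmHg"].nunique()
        m = data["lambda_z"].nunique()
        noise = small_dataset.noise
        double = NoiseScales(*(2 * np.array([
            noise.radius_passive, noise.force_passive,
            noise.radius_full, noise.force_full])))
        v1 = _sse_from_tables(data, pred.assign(axial_tension_mN=0.0),
                              noise, n, m)
        v2 = _sse_from_tables(data, pred.assign(axial_tension_mN=0.0),
                              double, n, m)
        assert v1 == pytest.approx(4 * v2, rel=1e-12)

    def test_order_invariance(self, fast_model, small_dataset):
        shuffled = small_dataset.records.sample(frac=1.0, random_state=0)
        v1 = sse_objective(fast_model, small_dataset.records,
                           small_dataset.noise)
        v2 = sse_objective(fast_model, shuffled, small_dataset.noise)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_missing_state_rejected(self, fast_model, small_dataset):
        only_passive = small_dataset.records.query("state == 'passive'")
        with pytest.raises(ValueError, match="full"):
            sse_objective(fast_model, only_passive, small_dataset.noise)


class TestFit:
    def test_same_seed_bitwise_identical(self, fast_model, small_dataset):
        cfg = replace(SMALL_FIT, free={"k_E": (0.05, 1.0)}, maxiter=4)
        r1 = fit_parameters(small_dataset.records, fast_model,
                            small_dataset.noise, cfg)
        r2 = fit_parameters(small_dataset.records, fast_model,
                            small_dataset.noise, cfg)
        assert r1.parameters == r2.parameters
        assert r1.sse == r2.sse
        assert r1.trace == r2.trace

    def test_single_parameter_recovery_from_perturbed_start(
            self, fast_model, small_dataset):
        """A 1-D noiseless fit should land on the generating k_E."""
        model = replace(fast_model,
                        passive=replace(fast_model.passive, k_E=0.5))
        cfg = replace(SMALL_FIT, free={"k_E": (0.05, 1.0)}, maxiter=25)
        res = fit_parameters(small_dataset.records, model,
                             small_dataset.noise, cfg)
        assert res.parameters["k_E"] == pytest.approx(0.27, rel=0.02)
        assert res.sse < 1e-3

    def test_refined_mode_nested_within_fixed_mode(self, fast_model,
                                                   small_dataset):
        """Seeding the refined run with the fixed-mode optimum guarantees
        SSE_refined ≤ SSE_fixed on identical data/budget/seed."""
        free = {"k_E": (0.05, 1.0), "sigma_max": (0.02, 0.25)}
        cfg_fixed = replace(SMALL_FIT, free=free, maxiter=6)
        res_fixed = fit_parameters(small_dataset.records, fast_model,
                                   small_dataset.noise, cfg_fixed)
        cfg_ref = replace(SMALL_FIT, free=free, maxiter=6,
                          mode="refined_geometry",
                          geometric_free=("mu_SMC", "e_02"))
        res_ref = fit_parameters(small_dataset.records, fast_model,
                                 small_dataset.noise, cfg_ref,
                                 x0=res_fixed.parameters)
        assert res_ref.sse <= res_fixed.sse + 1e-12
        # refined geometric estimates stay inside their constraint boxes
        assert 0.24 - 2 * 0.04 <= res_ref.parameters["mu_SMC"] <= 0.24 + 2 * 0.04
        assert 0.35 - 2 * 0.05 <= res_ref.parameters["e_02"] <= 0.35 + 2 * 0.05

    def test_mean_value_mode_estimates_point_angles(self, fast_model,
                                                    small_dataset):
        cfg = replace(SMALL_FIT, free={"k_E": (0.05, 1.0)}, maxiter=3,
                      mode="mean_value", geometric_free=("mu_SMC", "e_01"))
        res = fit_parameters(small_dataset.records, fast_model,
                             small_dataset.noise, cfg)
        assert "mu_SMC" in res.parameters and "e_01" in res.parameters
        assert res.mode == "mean_value"

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(free={"bogus": (0.0, 1.0)})

    def test_two_stage_fit_runs_and_reports(self, fast_model, small_dataset):
        cfg = replace(SMALL_FIT, maxiter=3,
                      free={"k_E": (0.05, 1.0), "sigma_max": (0.02, 0.25)})
        res = two_stage_fit(small_dataset.records, fast_model,
                            small_dataset.noise, cfg)
        assert res.sse >= 0.0
        assert "k_E" in res.parameters and "sigma_max" in res.parameters


class TestRecoveryRobustness:
    def test_bias_small_over_noisy_replicates(self, fast_model):
        """Estimator bias across noisy replicates stays below 15 % for the
        identifiable trio (k_E, λ_max, σ_max) at 2 % channel noise."""
        truth = {"k_E": 0.27, "lam_max": 1.34, "sigma_max": 0.09}
        free = {"k_E": (0.05, 1.0), "lam_max": (1.05, 1.7),
                "sigma_max": (0.02, 0.25)}
        estimates = {k: [] for k in truth}
        base = generate_experiment(fast_model, seed=100, noiseless=True,
                                   pressures=SMALL_PRESSURES, stretches=(1.3,))
        from arterymech.synthetic_data import add_measurement_noise
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            noisy = add_measurement_noise(base.records, base.noise, rng)
            cfg = replace(SMALL_FIT, free=free, popsize=5, maxiter=10,
                          seed=rep)
            res = fit_parameters(noisy, fast_model, base.noise, cfg)
            for k in truth:
                estimates[k].append(res.parameters[k])
        for k, v in truth.items():
            bias = abs(np.mean(estimates[k]) - v) / v
            assert bias < 0.15, (k, estimates[k])
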