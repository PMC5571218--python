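"""Single-fiber laws and layer-level energy/stress integrals."""

import numpy as np
import pytest

from arterymech.fiber_constitutive import (
    PassiveFiberParams, QuadratureSpec, elastin_energy_stress,
    collagen_energy_stress, layer_passive_energy, layer_passive_second_pk,
)
from arterymech.microstructure import (
    RecruitmentDistribution, statistical_default_config, LayerComposition,
)

PARAMS = PassiveFiberParams(k_IL=0.18, k_E=0.27, k_C=29.5, M_C=5.23)
ADV = LayerComposition(f_IL=0.0, f_E=0.35, f_C=0.65, f_SMC=0.0)
MED = LayerComposition(f_IL=0.15, f_E=0.15, f_C=0.25, f_SMC=0.45)


class TestElastinLaw:
    @pytest.mark.parametrize("e,expected", [
        (0.0, (0.0, 0.0)),
        (-0.1, (0.0, 0.0)),                       # compression carries no load
        (0.2, (0.5 * 0.27 * 0.04, 0.27 * 0.2)),   # ½ke², ke at k = 0.27
    ])
    def test_closed_form(self, e, expected):
        assert elastin_energy_stress(e, 0.27) == pytest.approx(expected)

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ValueError):
            elastin_energy_stress(0.1, -1.0)


class TestCollagenLaw:
    def test_recruitment_threshold(self):
        assert collagen_energy_stress(0.3, PARAMS, 0.3) == (0.0, 0.0)
        assert collagen_energy_stress(0.1, PARAMS, 0.3) == (0.0, 0.0)

    def test_linear_special_case(self):
        p = PassiveFiberParams(0.0, 0.0, 2.0, 1.0)
        w, s = collagen_energy_stress(0.4, p, 0.3)
        assert (w, s) == pytest.approx((0.01, 0.2))

    def test_stress_is_energy_derivative(self, rng):
        for _ in range(20):
            e0 = rng.uniform(0.0, 0.4)
            e = e0 + rng.uniform(0.05, 0.6)
            p = PassiveFiberParams(0.0, 0.0, rng.uniform(5, 60),
                                   rng.uniform(2, 8))
            h = 1e-6
            wp, _ = collagen_energy_stress(e + h, p, e0)
            wm, _ = collagen_energy_stress(e - h, p, e0)
            _, s = collagen_energy_stress(e, p, e0)
            assert s == pytest.approx((wp - wm) / (2 * h), rel=1e-6)

    def test_stress_continuous_at_recruitment(self):
        eps = 1e-9
        _, s = collagen_energy_stress(0.3 + eps, PARAMS, 0.3)
        assert s < 1e-8


def random_tension_strain(rng):
    """Diagonal strain with positive in-plane entries (typical loading)."""
    return np.diag([rng.uniform(0.05, 0.9), rng.uniform(-0.3, 0.0),
                    rng.uniform(0.05, 0.7)])


class TestLayerStress:
    micro = statistical_default_config()

    def test_zero_strain_gives_zero(self):
        for layer, comp in (("adventitia", ADV), ("media", MED)):
            S = layer_passive_second_pk(np.zeros((3, 3)), layer, self.micro,
                                        comp, PARAMS)
            assert np.allclose(S, 0.0)
            assert layer_passive_energy(np.zeros(3), layer, self.micro,
                                        comp, PARAMS) == 0.0

    def test_energy_nonnegative(self, rng):
        for _ in range(20):
            E = np.diag(rng.uniform(-0.3, 0.9, 3))
            for layer, comp in (("adventitia", ADV), ("media", MED)):
                assert layer_passive_energy(E, layer, self.micro, comp,
                                            PARAMS) >= 0.0

    def test_stress_is_energy_gradient(self, rng):
        """∂W/∂E finite-difference oracle on random strain states."""
        quad = QuadratureSpec(64, 32)
        for _ in range(25):
            E = random_tension_strain(rng)
            for layer, comp in (("adventitia", ADV), ("media", MED)):
                S = layer_passive_second_pk(E, layer, self.micro, comp,
                                            PARAMS, quad)
                for i in range(3):
                    h = 1e-6
                    Ep, Em = E.copy(), E.copy()
                    Ep[i, i] += h
                    Em[i, i] -= h
                    fd = (layer_passive_energy(Ep, layer, self.micro, comp,
                                               PARAMS, quad)
                          - layer_passive_energy(Em, layer, self.micro, comp,
                                                 PARAMS, quad)) / (2 * h)
                    assert S[i, i] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_degenerate_sds_match_hand_coded_mean_value_sum(self):
        """Point-mass limit equals an independently coded two-angle sum."""
        mv = self.micro.collapse_to_mean_value()
        E = np.diag([0.5, -0.2, 0.3])
        S = layer_passive_second_pk(E, "adventitia", mv, ADV, PARAMS)

        def dyad(th):
            return np.diag([np.cos(th) ** 2, 0.0, np.sin(th) ** 2])

        expected = np.zeros((3, 3))
        e01 = mv.adv_recruitment.point_value
        for mix, frac, law in (
            (mv.adv_elastin, ADV.f_E,
             lambda e: PARAMS.k_E * max(e, 0.0)),
            (mv.adv_collagen, ADV.f_C,
             lambda e: PARAMS.k_C * max(e - e01, 0.0) ** PARAMS.M_C),
        ):
            for comp, w in zip(mix.components, mix.weights):
                th = comp.mean_angle
                e = E[0, 0] * np.cos(th) ** 2 + E[2, 2] * np.sin(th) ** 2
                expected += frac * w * law(e) * dyad(th)
        assert np.allclose(S, expected, rtol=1e-12, atol=1e-14)

    def test_point_recruitment_equals_single_evaluation(self):
        """With point recruitment the e₀ expectation is exact, no quadrature."""
        micro_pt = statistical_default_config()
        from dataclasses import replace
        micro_pt = replace(micro_pt, adv_recruitment=RecruitmentDistribution(
            "point", point_value=0.2))
        E = np.diag([0.6, -0.2, 0.4])
        S_few = layer_passive_second_pk(E, "adventitia", micro_pt, ADV, PARAMS,
                                        QuadratureSpec(64, 1))
        S_many = layer_passive_second_pk(E, "adventitia", micro_pt, ADV, PARAMS,
                                         QuadratureSpec(64, 32))
        assert np.allclose(S_few, S_many, rtol=0, atol=0)

    def test_beta_recruitment_matches_monte_carlo(self, rng):
        """Quadrature over the recruitment density vs 1e5 random draws."""
        from scipy import stats
        micro = self.micro
        d = micro.adv_recruitment
        E = np.diag([0.7, -0.2, 0.3])
        e = 0.7  # circumferential fiber strain for a θ=0 fiber
        draws = stats.beta(d.shape1, d.shape2).rvs(10**5, random_state=rng)
        sample = PARAMS.k_C * np.maximum(e - draws, 0.0) ** PARAMS.M_C
        mc, se = sample.mean(), sample.std() / np.sqrt(len(sample))
        x, w = d.quad(32)
        quad_val = float((PARAMS.k_C * np.maximum(e - x, 0.0) ** PARAMS.M_C) @ w)
        assert abs(quad_val - mc) < 3 * se

    def test_monotone_in_circumferential_strain(self):
        Es = [np.diag([x, -0.1, 0.3]) for x in np.linspace(0.0, 0.9, 10)]
        s = [layer_passive_second_pk(E, "adventitia", self.micro, ADV,
                                     PARAMS)[0, 0] for E in Es]
        assert np.all(np.diff(s) >= 0)

    def test_quadrature_convergence(self):
        E = np.diag([0.6, -0.15, 0.35])
        for layer, comp in (("adventitia", ADV), ("media", MED)):
            S64 = layer_passive_second_pk(E, layer, self.micro, comp, PARAMS,
                                          QuadratureSpec(64, 32))
            S128 = layer_passive_second_pk(E, layer, self.micro, comp, PARAMS,
                                           QuadratureSpec(128, 64))
            scale = np.abs(S128).max()
            assert np.abs(S64 - S128).max() < 1e-6 * scale

    def test_off_diagonal_strain_rejected(self):
        E = np.diag([0.5, -0.2, 0.3])
        E[0, 1] = 0.1
        with pytest.raises(ValueError):
            layer_passive_second_pk(E, "adventitia", self.micro, ADV, PARAMS)
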