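"""Equilibrium of the inflated tube: pressure, force, transmural profiles."""

from dataclasses import replace

import numpy as np
import pytest

from arterymech.kinematics import ReferenceGeometry, inner_radius
from arterymech.wall_mechanics import (
    WallQuadrature, MMHG_TO_MPA, total_second_pk,
    luminal_pressure, axial_force, transmural_profile, solve_outer_radius,
    simulate_protocol, default_model, NoSolutionError,
)
from arterymech.fiber_constitutive import layer_passive_second_pk
from arterymech.smc_active import smc_second_pk


class TestTotalSecondPK:
    def test_zero_strain_zero_activation_gives_zero(self, model):
        R_mid = 0.5 * (model.geometry.r_inner + model.geometry.r_outer)
        S = total_second_pk(model, np.zeros((3, 3)), R_mid, activation=0.0)
        assert np.allclose(S, 0.0)

    def test_adventitia_carries_no_smc_stress(self, model):
        R_adv = model.geometry.r_outer - 1e-3
        E = np.diag([0.4, -0.1, 0.3])
        S0 = total_second_pk(model, E, R_adv, activation=0.0)
        S1 = total_second_pk(model, E, R_adv, activation=1.0)
        assert np.allclose(S0, S1)

    def test_additivity_of_constituents(self, model):
        """Total equals the independently computed constituent sum."""
        R_med = model.geometry.r_inner + 1e-3
        E = np.diag([0.35, -0.1, 0.3])
        comp = model.composition.media
        S_pas = layer_passive_second_pk(E, "media", model.micro, comp,
                                        model.passive, model.quadrature.spec)
        S_smc = smc_second_pk(E, model.micro, model.smc.with_activation(1.0),
                              model.quadrature.n_angle)
        total = total_second_pk(model, E, R_med, activation=1.0)
        assert np.allclose(total, S_pas + comp.f_SMC * S_smc, atol=1e-12)

    def test_outside_wall_rejected(self, model):
        with pytest.raises(ValueError):
            total_second_pk(model, np.zeros((3, 3)), 10.0)


class TestLuminalPressure:
    def test_thin_wall_laplace_limit(self):
        """p ≈ σ_θθ·h/r for a vanishing-thickness isotropic-ish wall."""
        R_o, h = 3.0, 3.0e-3
        geom = ReferenceGeometry(R_o, R_o - h, 0.0, 10.0)
        base = default_model()
        model = replace(base, geometry=geom)
        lam_z, r_o = 1.0, 1.15 * R_o
        p_mmHg = luminal_pressure(model, lam_z, r_o, 0.0)
        prof = transmural_profile(model, lam_z, r_o, 0.0, n_points=10)
        sig_tt = prof[:, 2].mean()
        r_mid = prof[:, 0].mean()
        h_cur = prof[-1, 0] - prof[0, 0]
        laplace = sig_tt * h_cur / r_mid / MMHG_TO_MPA
        assert p_mmHg == pytest.approx(laplace, rel=5e-3)

    def test_radial_quadrature_convergence(self, model):
        p64 = luminal_pressure(model, 1.3, 2.0, 0.0)
        p128 = luminal_pressure(
            replace(model, quadrature=WallQuadrature(64, 32, 64)),
            1.3, 2.0, 0.0)
        assert abs(p64 - p128) < 1e-6 * abs(p128)

    def test_pressure_monotone_in_radius(self, fast_model):
        radii = np.linspace(1.6, 2.4, 15)
        p = [luminal_pressure(fast_model, 1.3, r, 0.0) for r in radii]
        assert np.all(np.diff(p) > 0)


class TestTransmuralProfile:
    def test_outer_surface_traction_free(self, model):
        prof = transmural_profile(model, 1.3, 2.0, 0.0)
        assert prof[-1, 1] == pytest.approx(0.0, abs=1e-15)

    def test_inner_radial_stress_equals_minus_pressure(self, model):
        """Two-route equivalence: equilibrium integration vs pressure integral."""
        for A in (0.0, 1.0):
            p_mpa = luminal_pressure(model, 1.3, 2.0, A) * MMHG_TO_MPA
            prof = transmural_profile(model, 1.3, 2.0, A, n_points=40)
            assert prof[0, 1] == pytest.approx(-p_mpa, abs=1e-8)

    def test_interior_radial_stress_compressive_under_inflation(self, model):
        prof = transmural_profile(model, 1.3, 2.0, 0.0)
        assert np.all(prof[:-1, 1] < 0.0)

    def test_radial_magnitude_small_vs_circumferential(self, model):
        prof = transmural_profile(model, 1.3, 2.0, 1.0)
        assert np.abs(prof[:, 1]).max() < 0.2 * np.abs(prof[:, 2]).max()


class TestAxialForce:
    def test_stress_free_configuration(self):
        g = ReferenceGeometry(2.5, 1.85, 0.0, 10.0)
        model = replace(default_model(), geometry=g)
        F, N = axial_force(model, 1.0, g.r_outer, 0.0)
        assert F == pytest.approx(0.0, abs=1e-10)
        assert N == pytest.approx(0.0, abs=1e-10)

    def test_closed_tube_identity(self, model):
        """N − F = p_i π r_i² to high relative accuracy."""
        r_o = 2.0
        F, N = axial_force(model, 1.3, r_o, 1.0)
        p_mpa = luminal_pressure(model, 1.3, r_o, 1.0) * MMHG_TO_MPA
        r_i = inner_radius(model.geometry, 1.3, r_o)
        cap = p_mpa * np.pi * r_i**2 * 1e3
        assert N - F == pytest.approx(cap, rel=1e-10)

    def test_two_route_equivalence_via_sigma_rr_profile(self, model):
        """F from the reduced integrand equals 2π∫σ_zz r dr − p_i π r_i².

        σ_zz(r) jumps at the media/adventitia interface, so the
        independent trapezoid route integrates each layer separately."""
        from arterymech.kinematics import loaded_radius
        r_o, lam_z = 2.0, 1.3
        F, N = axial_force(model, lam_z, r_o, 0.0)
        prof = transmural_profile(model, lam_z, r_o, 0.0, n_points=3000)
        r, sig_zz = prof[:, 0], prof[:, 3]
        r_int = loaded_radius(model.interface_radius, model.geometry,
                              lam_z, r_o)
        integral = 0.0
        for mask in (r <= r_int, r > r_int):
            rs, fs = r[mask], (sig_zz * r)[mask]
            integral += np.trapezoid(fs, rs)
            # extend to the interface from within this layer
            if mask[0]:  # media side: append interface on the right
                slope = (fs[-1] - fs[-2]) / (rs[-1] - rs[-2])
                f_int = fs[-1] + slope * (r_int - rs[-1])
                integral += 0.5 * (fs[-1] + f_int) * (r_int - rs[-1])
            else:        # adventitia side: prepend interface on the left
                slope = (fs[1] - fs[0]) / (rs[1] - rs[0])
                f_int = fs[0] + slope * (r_int - rs[0])
                integral += 0.5 * (f_int + fs[0]) * (rs[0] - r_int)
        N_alt = 2 * np.pi * integral * 1e3
        assert N_alt == pytest.approx(N, rel=1e-5)
        p_mpa = luminal_pressure(model, lam_z, r_o, 0.0) * MMHG_TO_MPA
        r_i = prof[0, 0]
        F_alt = N_alt - p_mpa * np.pi * r_i**2 * 1e3
        assert F_alt == pytest.approx(F, rel=1e-4)


class TestSolveOuterRadius:
    def test_round_trip_inverse_identity(self, fast_model):
        r_star = 2.05
        p = luminal_pressure(fast_model, 1.3, r_star, 0.0)
        r_back = solve_outer_radius(fast_model, 1.3, p, 0.0)
        assert r_back == pytest.approx(r_star, abs=1e-8)

    def test_zero_pressure_passive_solution(self, fast_model):
        r0 = solve_outer_radius(fast_model, 1.3, 0.0, 0.0)
        resid = luminal_pressure(fast_model, 1.3, r0, 0.0)
        assert abs(resid) < 1e-6
        # below the unloaded outer radius once stretched axially
        assert r0 < fast_model.geometry.r_outer

    def test_active_radius_below_passive_radius(self, fast_model):
        for p in (20.0, 60.0, 100.0):
            r_pas = solve_outer_radius(fast_model, 1.3, p, 0.0)
            r_act = solve_outer_radius(fast_model, 1.3, p, 1.0)
            assert r_act < r_pas

    def test_unattainable_pressure_raises(self, fast_model):
        with pytest.raises(NoSolutionError):
            solve_outer_radius(fast_model, 1.3, 1e12, 0.0)


@pytest.fixture(scope="module")
def records(fast_model):
    return simulate_protocol(fast_model, list(range(0, 161, 20)),
                             [1.3, 1.5], ["passive", "full"])


class TestProtocol:

    def test_full_factorial_count(self, records):
        assert len(records) == 9 * 2 * 2

    def test_higher_axial_stretch_raises_passive_force(self, records):
        by = {(r.pressure, r.axial_stretch): r for r in records
              if r.state == "passive"}
        for p in range(0, 161, 20):
            assert by[(p, 1.5)].axial_force > by[(p, 1.3)].axial_force
            assert by[(p, 1.5)].outer_radius < by[(p, 1.3)].outer_radius

    def test_activation_raises_force(self, records):
        passive = {(r.pressure, r.axial_stretch): r for r in records
                   if r.state == "passive"}
        full = {(r.pressure, r.axial_stretch): r for r in records
                if r.state == "full"}
        for key in passive:
            assert full[key].axial_force >= passive[key].axial_force

    def test_closed_tube_identity_on_each_record(self, records, fast_model):
        for r in records:
            r_i = inner_radius(fast_model.geometry, r.axial_stretch,
                               r.outer_radius)
            cap = r.pressure * MMHG_TO_MPA * np.pi * r_i**2 * 1e3
            assert r.axial_tension - r.axial_force == pytest.approx(
                cap, abs=1e-6 + 1e-8 * abs(cap))


class TestDegenerateLimitEquivalence:
    def test_full_model_tends_to_mean_value_model(self, fast_model):
        """Shrinking every dispersion parameter reproduces the point-mass
        (mean-value) model's pressure and force within 0.1 %."""
        from arterymech.microstructure import (
            OrientationDistribution, OrientationMixture,
            RecruitmentDistribution,
        )
        mv_micro = fast_model.micro.collapse_to_mean_value()
        mv_model = replace(fast_model, micro=mv_micro)

        eps = 1e-4
        shrunk = replace(
            fast_model.micro,
            adv_elastin=OrientationMixture(
                tuple(OrientationDistribution(c.mean_angle, eps, c.support)
                      for c in mv_micro.adv_elastin.components),
                mv_micro.adv_elastin.weights),
            adv_collagen=OrientationMixture(
                tuple(OrientationDistribution(c.mean_angle, eps, c.support)
                      for c in mv_micro.adv_collagen.components),
                mv_micro.adv_collagen.weights),
            adv_recruitment=RecruitmentDistribution.from_moments(
                mv_micro.adv_recruitment.point_value, eps / 10),
            media_fiber=OrientationDistribution(
                mv_micro.media_fiber.mean_angle, eps, (0.0, np.pi / 2)),
            media_smc=OrientationDistribution(
                mv_micro.media_smc.mean_angle, eps, (0.0, np.pi / 2)),
            media_recruitment=RecruitmentDistribution(
                "uniform",
                lower=mv_micro.media_recruitment.point_value - eps,
                upper=mv_micro.media_recruitment.point_value + eps),
        )
        narrow_model = replace(fast_model, micro=shrunk)
        for lam_z, r_o, A in [(1.3, 2.0, 0.0), (1.3, 1.9, 1.0),
                              (1.5, 1.95, 0.0)]:
            p_mv = luminal_pressure(mv_model, lam_z, r_o, A)
            p_nw = luminal_pressure(narrow_model, lam_z, r_o, A)
            assert p_nw == pytest.approx(p_mv, rel=1e-3)
            F_mv, _ = axial_force(mv_model, lam_z, r_o, A)
            F_nw, _ = axial_force(narrow_model, lam_z, r_o, A)
            assert F_nw == pytest.approx(F_mv, rel=1e-3, abs=1e-3)
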