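"""Two-mass model core: scaling, forces, dynamics, integration."""

import numpy as np
import pytest

from glottifit import (
    CMH2O_TO_INTERNAL,
    FitVariables,
    ModelState,
    StandardParameters,
    apply_scaling,
    derivatives,
    driving_force,
    glottal_areas,
    impact_accelerations,
    simulate,
    visible_edge_trajectory,
)
from glottifit.errors import DomainError, IntegrationBlowupError
from glottifit.model import _integrate


class TestStandardParameters:
    def test_table_values_are_self_consistent(self, std):
        assert std.c1_0 == pytest.approx(3 * std.k1_0)
        assert std.c2_0 == pytest.approx(3 * std.k2_0)
        # rest areas match the rectangular-glottis identity within 1%
        assert std.a01 == pytest.approx(2 * std.l * std.x01, rel=0.01)

    def test_rejects_inconsistent_geometry(self):
        with pytest.raises(DomainError):
            StandardParameters(a01=0.2)

    def test_rejects_non_positive_mass(self):
        with pytest.raises(DomainError):
            StandardParameters(m1_0=0.0)

    def test_json_round_trip(self, std):
        assert StandardParameters.from_json(std.to_json()) == std


class TestApplyScaling:
    def test_identity_scaling_reproduces_standard_values(self, std):
        eff = apply_scaling(std, FitVariables(1.0, 1.0, 8.0))
        assert eff.m1l == std.m1_0
        assert eff.k1l == std.k1_0
        assert eff.kcr == std.kc_0
        assert eff.ps_internal == pytest.approx(8 * CMH2O_TO_INTERNAL)
        assert eff.ps_internal == pytest.approx(0.00784532, rel=1e-5)

    @pytest.mark.parametrize(
        "ql,qr,attr,expected",
        [
            (2.0, 1.0, "m1l", 0.0625),
            (2.0, 1.0, "k1l", 0.16),
            (2.0, 1.0, "kcl", 0.05),
            (2.0, 1.0, "c1l", 0.48),
            (1.0, 0.5, "m1r", 0.25),
            (1.0, 0.5, "k1r", 0.04),
        ],
    )
    def test_q_scaling_arithmetic(self, std, ql, qr, attr, expected):
        eff = apply_scaling(std, FitVariables(ql, qr, 8.0))
        assert getattr(eff, attr) == pytest.approx(expected)

    def test_mass_stiffness_reciprocity(self, std):
        for q in (0.7, 1.3, 2.9):
            eff = apply_scaling(std, FitVariables(q, q, 8.0))
            assert eff.m1l * eff.k1l == pytest.approx(std.m1_0 * std.k1_0)

    def test_rejects_non_positive_fit_variables(self):
        with pytest.raises(DomainError):
            FitVariables(0.0, 1.0, 8.0)
        with pytest.raises(DomainError):
            FitVariables(1.0, 1.0, -1.0)


class TestGlottalAreas:
    def test_rest_state_gives_rest_areas(self, effective_std):
        a1, a2 = glottal_areas(ModelState(), effective_std)
        assert a1 == pytest.approx(0.05)
        assert a2 == pytest.approx(0.05)

    def test_closure_onset(self, effective_std):
        state = ModelState(x1l=-0.01786, x1r=-0.01786)
        a1, _ = glottal_areas(state, effective_std)
        assert a1 == pytest.approx(0.0, abs=1e-4)

    def test_open_glottis_arithmetic(self, effective_std):
        state = ModelState(x1l=0.01, x1r=0.02)
        a1, _ = glottal_areas(state, effective_std)
        assert a1 == pytest.approx(0.05 + 1.4 * 0.03)


class TestDrivingForce:
    def test_rectangular_open_glottis_gives_zero(self, effective_std):
        assert driving_force(0.05, 0.05, effective_std) == 0.0

    def test_upper_closed_gives_full_pressure(self, effective_std):
        force = driving_force(0.05, -0.01, effective_std)
        assert force == pytest.approx(8 * CMH2O_TO_INTERNAL * 1.4 * 0.25)
        assert force == pytest.approx(2.746e-3, rel=1e-3)

    def test_lower_closed_gives_zero(self, effective_std):
        assert driving_force(-0.01, 0.05, effective_std) == 0.0

    def test_convergent_glottis_is_driven(self, effective_std):
        # a1 > a2 > 0: pressure partially recovered, force positive
        assert driving_force(0.06, 0.03, effective_std) > 0.0


class TestImpactAccelerations:
    def test_open_glottis_no_impact(self, effective_std):
        assert impact_accelerations(0.05, 0.05, effective_std) == (0, 0, 0, 0)

    def test_restoring_magnitude(self, effective_std):
        i1l, i1r, _, _ = impact_accelerations(-0.014, 0.05, effective_std)
        assert i1l == pytest.approx(0.0096)
        assert i1l == i1r

    def test_symmetric_parameters_give_symmetric_impacts(self, effective_std):
        _, _, i2l, i2r = impact_accelerations(0.05, -0.01, effective_std)
        assert i2l == i2r
        assert i2l > 0.0


class TestDerivatives:
    def test_equilibrium_at_rest_without_pressure(self, std):
        eff = apply_scaling(std, FitVariables(1.0, 1.0, 1e-12))
        dy = derivatives(ModelState(), eff)
        assert np.allclose(dy, 0.0, atol=1e-15)

    def test_rest_state_rectangular_glottis_feels_no_pressure(self, effective_std):
        # a1 = a2 at rest, so the Bernoulli bracket annihilates the force
        dy = derivatives(ModelState(), effective_std)
        assert np.allclose(dy, 0.0, atol=1e-15)

    def test_spring_restoring_acceleration(self, std):
        eff = apply_scaling(std, FitVariables(1.0, 1.0, 1e-12))
        dy = derivatives(ModelState(x1l=0.01), eff)
        # dv1l = -(k1 + kc)/m1 * x1l
        assert dy[1] == pytest.approx(-(0.08 + 0.025) / 0.125 * 0.01)
        # coupling spring accelerates the upper mass
        assert dy[3] == pytest.approx(0.025 * 0.01 / 0.025)

    def test_jitted_step_matches_reference_derivatives(self, std):
        eff = apply_scaling(std, FitVariables(1.3, 0.9, 12.0))
        y0 = np.array([0.011, 0.0, 0.009, 0.0, 0.012, 0.0, 0.008, 0.0])
        dt = 0.01
        out, blow = _integrate(y0, eff.as_vector(), dt, 2, 1, 0.0)
        k1 = derivatives(y0, eff)
        k2 = derivatives(y0 + dt / 2 * k1, eff)
        k3 = derivatives(y0 + dt / 2 * k2, eff)
        k4 = derivatives(y0 + dt * k3, eff)
        expected = y0 + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert blow < 0
        assert np.allclose(out[1], expected, atol=1e-14)


class TestSimulate:
    def test_passive_oscillation_decays(self):
        sim = simulate(FitVariables(1.0, 1.0, 1e-9))
        tail = sim.states[-200:, [0, 2, 4, 6]]
        assert np.max(np.abs(tail)) < 1e-6

    def test_below_threshold_pressure_decays(self):
        sim = simulate(FitVariables(1.0, 1.0, 0.5))
        assert np.ptp(sim.t_ml) < 1e-6

    def test_standard_pressure_sustains_oscillation(self, standard_sim):
        assert np.ptp(standard_sim.t_ml) > 1e-2

    def test_symmetric_configuration_gives_identical_sides(self, standard_sim):
        assert np.max(np.abs(standard_sim.t_ml - standard_sim.t_mr)) < 1e-9
        left = standard_sim.states[:, :4]
        right = standard_sim.states[:, 4:]
        assert np.max(np.abs(left - right)) < 1e-9

    def test_area_consistency_at_every_sample(self, asymmetric_sim):
        p = asymmetric_sim.params
        y = asymmetric_sim.states
        a1 = p.a01 + p.l * (y[:, 0] + y[:, 4])
        a2 = p.a02 + p.l * (y[:, 2] + y[:, 6])
        assert np.allclose(a1, asymmetric_sim.a1, atol=1e-14)
        assert np.allclose(a2, asymmetric_sim.a2, atol=1e-14)

    def test_output_shape_and_time_grid(self, standard_sim):
        assert standard_sim.t_ml.shape == (400,)
        assert standard_sim.time[0] == pytest.approx(400.0)
        assert np.allclose(np.diff(standard_sim.time), 0.25)

    def test_deterministic(self):
        a = simulate(FitVariables(1.4, 1.2, 14.0))
        b = simulate(FitVariables(1.4, 1.2, 14.0))
        assert np.array_equal(a.t_ml, b.t_ml)

    def test_blowup_reports_failure_time(self, std):
        with pytest.raises(IntegrationBlowupError) as exc:
            simulate(FitVariables(1.0, 1.0, 1e6), std)
        assert 0 < exc.value.time_ms <= 500.0

    def test_rejects_transient_exceeding_duration(self):
        with pytest.raises(DomainError):
            simulate(FitVariables(1.0, 1.0, 8.0), total_ms=100.0, transient_ms=200.0)

    def test_oscillation_onset_threshold_is_bracketed(self):
        # a pressure threshold separates decay from sustained oscillation
        amp = lambda ps: np.ptp(simulate(FitVariables(1.0, 1.0, ps)).t_ml)
        assert amp(0.5) < 1e-6
        assert amp(8.0) > 1e-2


class TestVisibleEdge:
    def test_more_medial_mass_is_visible(self, effective_std):
        # lower edge at 0.03 cm, upper at 0.05 cm -> lower mass seen
        state = np.array([[0.03 - 0.0179, 0, 0.05 - 0.0179, 0,
                           0.03 - 0.0179, 0, 0.05 - 0.0179, 0]])
        t_ml, t_mr = visible_edge_trajectory(state, effective_std)
        assert t_ml[0] == pytest.approx(0.03)

    def test_full_closure_clamps_to_midline(self, effective_std):
        state = np.array([[-0.1, 0, -0.1, 0, -0.1, 0, -0.1, 0]])
        t_ml, t_mr = visible_edge_trajectory(state, effective_std)
        assert t_ml[0] == 0.0
        assert t_mr[0] == 0.0

    def test_symmetric_state_gives_equal_sides(self, effective_std):
        state = np.array([[0.01, 0, 0.02, 0, 0.01, 0, 0.02, 0]])
        t_ml, t_mr = visible_edge_trajectory(state, effective_std)
        assert t_ml[0] == t_mr[0]
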