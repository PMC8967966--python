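"""Hill-curve values, activation dynamics, and the excitation inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import elbowsim as es
from elbowsim.model import default_muscle_fixture
from elbowsim.muscle import (
    MuscleState,
    activation_derivative,
    active_force_length,
    evaluate_geometry,
    excitation_from_activation,
    fiber_force,
    force_velocity,
    muscle_force,
    passive_force_length,
)

MUSCLES = default_muscle_fixture()
BICEPS = MUSCLES[0]


def _state(lnorm=1.0, vnorm=0.0, a=0.0, phi=0.0, lopt=0.1):
    return MuscleState(
        fiber_length=lnorm * lopt,
        norm_fiber_length=lnorm,
        fiber_velocity=vnorm,
        norm_fiber_velocity=vnorm,
        pennation=phi,
        moment_arm=0.03,
        activation=a,
    )


class TestForceCurves:
    def test_active_optimum_and_symmetry(self):
        assert active_force_length(1.0) == pytest.approx(1.0)
        assert active_force_length(0.5) == pytest.approx(active_force_length(1.5))

    def test_active_gaussian_value(self):
        assert active_force_length(1.3) == pytest.approx(math.exp(-0.2), rel=1e-12)

    def test_fv_isometric_and_max_shortening(self):
        assert force_velocity(0.0) == pytest.approx(1.0)
        assert force_velocity(-1.0) == pytest.approx(0.0)

    def test_fv_monotone_and_eccentric_asymptote(self):
        grid = np.linspace(-1.0, 1.0, 200)
        vals = force_velocity(grid)
        assert np.all(np.diff(vals) >= -1e-12)
        assert force_velocity(50.0) == pytest.approx(1.4, abs=0.02)

    def test_passive_below_slack_and_increasing(self):
        assert passive_force_length(0.8) == 0.0
        assert passive_force_length(1.0 + 1e-9) < 1e-6  # continuity at slack
        grid = np.linspace(1.0, 1.6, 100)
        assert np.all(np.diff(passive_force_length(grid)) > 0)
        assert passive_force_length(1.6) == pytest.approx(1.0)


class TestMuscleForce:
    def test_zero_activation_no_passive(self):
        assert muscle_force(BICEPS, _state(lnorm=1.0, a=0.0)) == 0.0

    def test_full_activation_optimal_isometric_is_fmax(self):
        f = muscle_force(BICEPS, _state(lnorm=1.0, a=1.0))
        assert f == pytest.approx(BICEPS.max_isometric_force)

    def test_linear_in_activation_at_optimum(self):
        import dataclasses

        m = dataclasses.replace(BICEPS, max_isometric_force=1000.0)
        assert muscle_force(m, _state(a=0.5)) == pytest.approx(500.0)

    def test_force_nonnegative_over_state_grid(self):
        for lnorm in (0.6, 1.0, 1.4):
            for vnorm in (-1.5, -0.5, 0.0, 0.5):
                for a in (0.0, 0.5, 1.0):
                    assert muscle_force(BICEPS, _state(lnorm, vnorm, a)) >= 0.0

    def test_pennation_projects_fiber_force(self):
        tri = next(m for m in MUSCLES if m.name == "triceps_long")
        st_ = _state(a=1.0, phi=tri.pennation_at_optimal)
        assert muscle_force(tri, st_) == pytest.approx(
            fiber_force(tri, st_) * math.cos(tri.pennation_at_optimal)
        )


class TestGeometry:
    def test_no_joint_motion_zero_fiber_velocity(self):
        st_ = evaluate_geometry(BICEPS, 0.5, 0.0)
        assert st_.fiber_velocity == 0.0

    def test_flexor_shortens_with_flexion(self):
        ext = evaluate_geometry(BICEPS, 0.0)
        flex = evaluate_geometry(BICEPS, math.pi / 2)
        assert flex.fiber_length < ext.fiber_length

    def test_flexion_rate_shortens_flexor_lengthens_extensor(self):
        for m in MUSCLES:
            st_ = evaluate_geometry(m, 0.7, 2.0)
            assert st_.fiber_velocity * m.sign < 0

    def test_out_of_range_angle_clamped(self):
        clamped = evaluate_geometry(BICEPS, 3.0)
        edge = evaluate_geometry(BICEPS, 1.8)
        assert clamped.fiber_length == pytest.approx(edge.fiber_length)


class TestActivationDynamics:
    def test_fixed_point(self):
        assert activation_derivative(0.3, 0.3, BICEPS) == 0.0

    def test_activation_branch_rate(self):
        # (1 - 0) / (0.01 * 0.5) = 200
        assert activation_derivative(0.0, 1.0, BICEPS) == pytest.approx(200.0)

    def test_deactivation_branch_rate(self):
        # (0 - 1) / (0.04 / 2.0) = -50
        assert activation_derivative(1.0, 0.0, BICEPS) == pytest.approx(-50.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            activation_derivative(1.2, 0.5, BICEPS)
        with pytest.raises(ValueError):
            activation_derivative(0.5, -0.1, BICEPS)

    def test_rise_faster_than_decay(self):
        """kact < kdeact: the step response rises faster than it decays."""
        from scipy.integrate import solve_ivp

        clip = lambda v: min(max(v, 0.0), 1.0)
        up = solve_ivp(
            lambda t, y: [activation_derivative(clip(y[0]), 1.0, BICEPS)], (0, 0.05), [0.0]
        )
        down = solve_ivp(
            lambda t, y: [activation_derivative(clip(y[0]), 0.0, BICEPS)], (0, 0.05), [1.0]
        )
        assert up.y[0, -1] > 1.0 - down.y[0, -1]

    @pytest.mark.parametrize("a0", [0.0, 1.0])
    @pytest.mark.parametrize("u", [0.0, 0.37, 1.0])
    def test_forward_invariance_of_unit_interval(self, a0, u):
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, y: [activation_derivative(min(max(y[0], 0.0), 1.0), u, BICEPS)],
            (0, 0.5),
            [a0],
            max_step=1e-3,
        )
        assert np.all(sol.y[0] >= -1e-9)
        assert np.all(sol.y[0] <= 1.0 + 1e-9)


class TestExcitationInversion:
    def test_zero_rate_fixed_point(self):
        assert excitation_from_activation(0.4, 0.0, BICEPS) == pytest.approx(0.4)

    def test_clamped_at_unit_bound(self):
        assert excitation_from_activation(0.9, 1e6, BICEPS) == 1.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.floats(0.05, 0.95),
        dadt=st.floats(-30.0, 30.0),
    )
    def test_roundtrip_recovers_rate(self, a, dadt):
        """activation_derivative(a, invert(a, d)) == d when u is unclamped."""
        u = excitation_from_activation(a, dadt, BICEPS)
        if 0.0 < u < 1.0:
            assert activation_derivative(a, u, BICEPS) == pytest.approx(
                dadt, rel=1e-9, abs=1e-9
            )
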