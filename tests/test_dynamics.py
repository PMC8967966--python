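"""Inverse/forward dynamics, energy conservation, and joint reactions."""

import copy
import math

import numpy as np
import pytest

import elbowsim as es
from elbowsim.dynamics import (
    JointState,
    forward_step,
    gravity_moment,
    inverse_dynamics_moment,
    joint_reaction,
    mass_about_elbow,
)
from elbowsim.exosuit import ControlFrame


def _frame(u=0.0, t1=0.0, t2=0.0):
    return ControlFrame(
        excitations=np.full(6, float(u)),
        flexor_tension=t1,
        extensor_tension=t2,
        assist_moment=0.0,
    )


def _passive_free(model):
    """Copy whose muscles develop no force (long optimal fibers, a=0)."""
    m = copy.deepcopy(model)
    for musc in m.muscles:
        musc.optimal_fiber_length = 10.0  # fibers far below slack: fl~0, fp=0
    return m


class TestInertiaAndGravity:
    def test_inertia_values_and_zero_load_limit(self, model):
        assert mass_about_elbow(model.with_load(0)) == pytest.approx(0.02)
        assert mass_about_elbow(model.with_load(2)) == pytest.approx(0.265)
        m = model.with_load(0, load_distance=0.7)
        assert mass_about_elbow(m) == pytest.approx(0.02)

    def test_gravity_moment_values(self, model):
        assert gravity_moment(model, 0.0) == 0.0
        assert gravity_moment(model.with_load(2), math.pi / 2) == pytest.approx(
            1.53 * 9.81 * 0.18 + 2 * 9.81 * 0.35, rel=1e-9
        )
        assert gravity_moment(model.with_load(0), math.pi / 2) == pytest.approx(
            2.702, abs=1e-3
        )


class TestInverseDynamics:
    def test_static_hold_equals_gravity_moment(self, model):
        th = 0.8
        tau = inverse_dynamics_moment(
            model, (th, 0.0, 0.0), JointState(th, 0.0), assist_moment=0.0
        )
        assert tau == pytest.approx(gravity_moment(model, th), rel=1e-12)

    def test_perfect_gravity_compensation_zeroes_demand(self, model):
        th = 0.8
        tau = inverse_dynamics_moment(
            model,
            (th, 0.0, 0.0),
            JointState(th, 0.0),
            assist_moment=gravity_moment(model, th),
        )
        assert tau == pytest.approx(0.0, abs=1e-12)

    def test_pure_inertial_demand_without_gravity(self, model):
        m = copy.deepcopy(model)
        m.gravity = 0.0
        tau = inverse_dynamics_moment(m, (0.5, 0.0, 1.0), JointState(0.5, 0.0))
        assert tau == pytest.approx(0.02, rel=1e-12)

    def test_pd_feedback_terms(self, model):
        m = copy.deepcopy(model)
        m.gravity = 0.0
        tau = inverse_dynamics_moment(m, (0.5, 0.0, 0.0), JointState(0.4, -0.1))
        assert tau == pytest.approx(0.02 * (900 * 0.1 + 60 * 0.1), rel=1e-9)


class TestForwardStep:
    def test_equilibrium_without_forces(self, model):
        m = _passive_free(model)
        m.gravity = 0.0
        state, acts = forward_step(m, JointState(0.5, 0.0), np.zeros(6), _frame(), 0.008)
        assert state.theta == pytest.approx(0.5, abs=1e-10)
        assert state.thetadot == pytest.approx(0.0, abs=1e-10)

    def test_gravity_pulls_toward_extension(self, model):
        m = _passive_free(model)
        state, _ = forward_step(m, JointState(0.1, 0.0), np.zeros(6), _frame(), 0.008)
        assert state.thetadot < 0.0

    def test_activation_trace_matches_dense_euler(self, model):
        """ODE oracle: constant u=0.5 activation rise vs dt=1e-5 Euler."""
        from elbowsim.muscle import activation_derivative

        m = _passive_free(model)
        m.gravity = 0.0
        acts = np.zeros(6)
        state = JointState(0.5, 0.0)
        for _ in range(12):  # ~0.1 s
            state, acts = forward_step(m, state, acts, _frame(u=0.5), 0.008)
        a_ref = 0.0
        musc = m.muscles[0]
        for _ in range(int(0.096 / 1e-5)):
            a_ref += 1e-5 * activation_derivative(min(a_ref, 1.0), 0.5, musc)
        assert acts[0] == pytest.approx(a_ref, abs=1e-4)

    def test_energy_conserved_in_free_swing(self, model):
        """Mechanical energy drift < 0.1% over 1 s of passive pendulum swing."""
        m = _passive_free(model.with_load(2))
        inertia = mass_about_elbow(m)
        first_moment = 1.53 * 0.18 + 2 * 0.35

        def energy(state):
            return (
                0.5 * inertia * state.thetadot**2
                - first_moment * m.gravity * math.cos(state.theta)
            )

        state = JointState(0.18, 0.0)  # swing stays inside the soft stops
        e0 = energy(state)
        acts = np.zeros(6)
        for _ in range(121):
            state, acts = forward_step(m, state, acts, _frame(), 1 / 121)
        scale = first_moment * m.gravity  # energy scale of the swing
        assert abs(energy(state) - e0) / scale < 1e-3

    def test_soft_stop_breach_reports_diagnostics(self, model):
        m = _passive_free(model.with_load(5))
        state = JointState(1.9, 3.0)  # heading past the soft stop
        with pytest.raises(es.SimulationError, match="soft-stop"):
            for _ in range(20):
                state, _ = forward_step(m, state, np.zeros(6), _frame(), 1 / 121)


class TestJointReaction:
    def test_rest_without_forces_is_zero(self, model):
        m = _passive_free(model)
        m.gravity = 0.0
        r = joint_reaction(m, JointState(0.3, 0.0), np.zeros(6))
        assert r.magnitude == pytest.approx(0.0, abs=1e-9)

    def test_static_hang_transmits_weight(self, model):
        """At theta=0 gravity needs no muscle force; the joint carries it all."""
        m = _passive_free(model.with_load(2))
        r = joint_reaction(m, JointState(0.0, 0.0), np.zeros(6))
        assert r.magnitude == pytest.approx((1.53 + 2) * 9.81, rel=1e-9)
        assert r.fy > 0  # upper arm holds the forearm up

    def test_assistance_reduces_static_reaction(self, model):
        """Cable carrying the GC moment unloads the elbow at a 90-deg hold."""
        from elbowsim import exosuit as exo
        from elbowsim import redundancy as so

        m = model.with_load(2)
        th = math.pi / 2
        state = JointState(th, 0.0)
        demand = gravity_moment(m, th)

        def forces_for(tau):
            prob = so.build_problem(m, th, 0.0, tau)
            a, _ = so.solve(prob)
            out = np.empty(6)
            from elbowsim import muscle as mm

            for j, musc in enumerate(m.muscles):
                stt = mm.evaluate_geometry(musc, th, 0.0)
                stt.activation = float(a[j])
                out[j] = mm.muscle_force(musc, stt)
            return out

        r_off = joint_reaction(m, state, forces_for(demand), thetaddot=0.0)
        geo = exo.cable_geometry(m.exosuit, th)
        t1, _ = exo.cable_tensions(demand, geo.r_flexor, geo.r_extensor)
        cable = exo.cable_force_on_forearm(m.exosuit, th, t1, 0.0)
        r_on = joint_reaction(m, state, forces_for(0.0), cable, thetaddot=0.0)
        assert r_on.magnitude < r_off.magnitude


def test_step_size_robustness_within_documented_range(model):
    """RMS joint moment varies < 2% across integrator step bounds."""
    from elbowsim import pipeline as pl

    traj = es.make_min_jerk(0.0, 1.57, 1.0, 121)
    rms_vals = []
    for step in (0.004, 0.008, 0.02):
        m = copy.deepcopy(model.with_load(2))
        m.settings.integrator_max_step = step
        res = pl.run(pl.RunSpec(model=m, trajectory=traj, assist=False, label="x"))
        rms_vals.append(pl.rms(res.tau_required))
    spread = (max(rms_vals) - min(rms_vals)) / min(rms_vals)
    assert spread < 0.02
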