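"""Single-DOF rigid dynamics: inverse dynamics, forward integration, reactions.

The forearm (plus any hand-held load) rotates about the elbow with
total rotational inertia ``I = I_forearm + M * ll^2``.  The equation of
motion is

    I * thetaddot = tau_muscle + tau_cable - G(theta),

where ``G(theta) = (m g lc + M g ll) sin(theta)`` is the flexion moment
gravity demands and ``tau_muscle = sum_i d_i(theta) F_i``.  With the
shoulder locked there is a single revolute joint, so Coriolis and
centripetal terms vanish identically.

The muscle command generator computes the required muscle moment from
the PD-augmented reference acceleration

    thetaddot_cmd = thetaddot_des + kp (theta_des - theta) + kv (thetadot_des - thetadot)
    tau_required  = I * thetaddot_cmd + G(theta) - tau_assist,

i.e. the assist moment offloads gravity so the muscles mainly carry the
inertial component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import exosuit as exo
from . import muscle as mm
from .model import ArmModel, Gains

__all__ = [
    "JointState",
    "ReactionForce",
    "SimulationError",
    "mass_about_elbow",
    "gravity_moment",
    "inverse_dynamics_moment",
    "muscle_joint_moment",
    "forward_step",
    "joint_reaction",
]

#: Soft-stop range (rad); simulation aborts with diagnostics outside it.
SOFT_STOP = (-0.2, 2.0)


class SimulationError(RuntimeError):
    """Forward integration failed (NaN, divergence, or soft-stop breach)."""


@dataclass
class JointState:
    """Elbow angle and angular velocity."""

    theta: float
    thetadot: float = 0.0


@dataclass
class ReactionForce:
    """World-frame force the upper arm exerts on the forearm at the elbow."""

    fx: float
    fy: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.fx, self.fy)


def mass_about_elbow(model: ArmModel) -> float:
    """Total rotational inertia about the elbow (kg*m^2), load included."""
    inertia = model.segment.inertia_about_elbow
    if model.settings.inertia_about == "com":
        inertia += model.segment.forearm_mass * model.segment.com_distance**2
    return inertia + model.load.external_mass * model.load.load_distance**2


def gravity_moment(model: ArmModel, theta: float) -> float:
    """Flexion moment (N*m) gravity demands at elbow angle ``theta``."""
    seg, load = model.segment, model.load
    return (
        seg.forearm_mass * model.gravity * seg.com_distance
        + load.external_mass * model.gravity * load.load_distance
    ) * math.sin(theta)


def inverse_dynamics_moment(
    model: ArmModel,
    traj_sample: tuple[float, float, float],
    feedback: JointState,
    gains: Gains | None = None,
    assist_moment: float = 0.0,
) -> float:
    """Net muscle moment (N*m) the tracking controller demands.

    ``traj_sample`` is the reference ``(theta_des, thetadot_des,
    thetaddot_des)``; the feedback state supplies the tracking errors
    and the linearisation point for gravity.  With
    ``settings.literal_dynamics_sign`` the gravity and assist terms are
    subtracted wholesale (the as-printed convention), retained only for
    comparison runs.
    """
    gains = gains or model.gains
    theta_des, thetadot_des, thetaddot_des = traj_sample
    thetaddot_cmd = (
        thetaddot_des
        + gains.kp * (theta_des - feedback.theta)
        + gains.kv * (thetadot_des - feedback.thetadot)
    )
    inertia = mass_about_elbow(model)
    grav = gravity_moment(model, feedback.theta)
    if model.settings.literal_dynamics_sign:
        return inertia * thetaddot_cmd - grav - assist_moment
    return inertia * thetaddot_cmd + grav - assist_moment


def muscle_joint_moment(model: ArmModel, theta: float, thetadot: float, activations) -> float:
    """Total muscle moment (N*m) about the elbow for given activations."""
    total = 0.0
    for musc, a in zip(model.muscles, activations):
        state = mm.evaluate_geometry(musc, theta, thetadot)
        state.activation = float(a)
        total += state.moment_arm * mm.muscle_force(musc, state)
    return total


def _rhs(model: ArmModel, inertia: float, controls: exo.ControlFrame):
    geom = model.exosuit

    def f(t, y):
        theta, thetadot = y[0], y[1]
        acts = y[2:]
        tau_mus = muscle_joint_moment(model, theta, thetadot, acts)
        tau_cab = 0.0
        if controls.flexor_tension > 0 or controls.extensor_tension > 0:
            tau_cab = exo.cable_moment(
                geom, theta, controls.flexor_tension, controls.extensor_tension
            )
        thetaddot = (tau_mus + tau_cab - gravity_moment(model, theta)) / inertia
        dadt = [
            mm.activation_derivative(
                min(max(a, 0.0), 1.0), float(u), musc
            )
            for a, u, musc in zip(acts, controls.excitations, model.muscles)
        ]
        return [thetadot, thetaddot, *dadt]

    return f


def forward_step(
    model: ArmModel,
    state: JointState,
    activations,
    controls: exo.ControlFrame,
    dt: float,
) -> tuple[JointState, np.ndarray]:
    """Integrate joint and activation dynamics over one control interval.

    Excitations and cable tensions are held constant (zero-order hold).
    Returns the joint state and activation vector at ``t + dt``.
    """
    inertia = mass_about_elbow(model)
    y0 = [state.theta, state.thetadot, *np.clip(np.asarray(activations, float), 0.0, 1.0)]
    sol = solve_ivp(
        _rhs(model, inertia, controls),
        (0.0, dt),
        y0,
        method="RK45",
        rtol=1e-6,
        atol=1e-8,
        max_step=model.settings.integrator_max_step,
    )
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        raise SimulationError(
            f"integration failed over dt={dt:.4g} s from state "
            f"theta={state.theta:.4f}, thetadot={state.thetadot:.4f}: {sol.message}"
        )
    yf = sol.y[:, -1]
    if not (SOFT_STOP[0] <= yf[0] <= SOFT_STOP[1]):
        raise SimulationError(
            f"elbow angle {yf[0]:.4f} rad left the soft-stop range {SOFT_STOP}; "
            f"state dump: thetadot={yf[1]:.4f}, activations={yf[2:]}"
        )
    return JointState(theta=float(yf[0]), thetadot=float(yf[1])), np.clip(yf[2:], 0.0, 1.0)


def joint_reaction(
    model: ArmModel,
    state: JointState,
    muscle_forces,
    cable_force_on_forearm=(0.0, 0.0),
    thetaddot: float | None = None,
) -> ReactionForce:
    """Elbow reaction force from a Newton-Euler balance on the forearm.

    ``muscle_forces`` are tendon-line force magnitudes (N, one per
    muscle, fixture order); their directions are reconstructed from the
    effective straight-line attachments.  ``cable_force_on_forearm`` is
    the world-frame strap force.  If ``thetaddot`` is omitted it is
    recovered from the rotational equation of motion, keeping the
    balance self-consistent.
    """
    theta, thetadot = state.theta, state.thetadot
    e_axis = np.array([math.sin(theta), -math.cos(theta)])
    e_perp = np.array([math.cos(theta), math.sin(theta)])
    cable = np.asarray(cable_force_on_forearm, float)

    # muscle force vectors on the forearm: insertion -> origin
    f_mus_total = np.zeros(2)
    tau_mus = 0.0
    for musc, fmag in zip(model.muscles, muscle_forces):
        ins = musc.insertion[1] * e_axis + musc.insertion[0] * e_perp
        ori = np.array(musc.origin, float)
        seg = ori - ins
        u = seg / max(np.hypot(*seg), 1e-9)
        f_mus_total += fmag * u
        state_k = mm.evaluate_geometry(musc, theta, thetadot)
        tau_mus += state_k.moment_arm * fmag

    inertia = mass_about_elbow(model)
    if thetaddot is None:
        tau_cable = float(
            cable[1] * 0.0
        )  # recomputed below from the anchor position if a force is present
        if np.any(cable != 0.0):
            p = (
                model.exosuit.forearm_anchor[1] * e_axis
                + model.exosuit.forearm_anchor[0] * e_perp
            )
            tau_cable = float(p[0] * cable[1] - p[1] * cable[0])
        thetaddot = (tau_mus + tau_cable - gravity_moment(model, theta)) / inertia

    seg, load = model.segment, model.load
    m_total = seg.forearm_mass + load.external_mass
    first_moment = seg.forearm_mass * seg.com_distance + load.external_mass * load.load_distance
    accel_com_total = first_moment * (thetaddot * e_perp - thetadot**2 * e_axis)
    weight = np.array([0.0, -m_total * model.gravity])

    r = accel_com_total - weight - f_mus_total - cable
    return ReactionForce(fx=float(r[0]), fy=float(r[1]))
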