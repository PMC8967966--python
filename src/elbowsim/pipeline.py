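"""Closed-loop simulation pipeline and result summarisation.

One control step on the sampling grid (121 Hz by default):

1. read the fed-back joint state ``(theta, thetadot)`` from the forward
   model;
2. if assistance is on, compute the gravity-compensation actuator
   moment from the fed-back angle and map it to cable tensions through
   the instantaneous cable moment arms;
3. run inverse dynamics with PD-augmented reference acceleration to get
   the required net muscle moment (the assist moment enters as an
   external credit);
4. resolve muscle redundancy by static optimization to target
   activations;
5. invert the activation dynamics (backward-difference activation rate)
   to muscle excitations;
6. advance the forward model one grid interval with excitations and
   cable tensions held.

Everything downstream — joint reaction forces, strap interaction
forces, metabolic power — is evaluated on the recorded grid series.
The pipeline is fully deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import exosuit as exo
from . import metabolics as met
from . import muscle as mm
from . import redundancy as so
from .model import ArmModel, Gains, SimSettings, FLEXOR_NAMES
from .trajectory import ReferenceTrajectory

__all__ = ["RunSpec", "SimulationResult", "SummaryMetrics", "run", "sweep", "summarize"]


@dataclass
class RunSpec:
    """A single closed-loop simulation condition."""

    model: ArmModel
    trajectory: ReferenceTrajectory
    assist: bool
    label: str = ""
    gains: Gains | None = None
    settings: SimSettings | None = None

    def resolved(self) -> tuple[Gains, SimSettings]:
        return self.gains or self.model.gains, self.settings or self.model.settings


@dataclass
class SimulationResult:
    """Full time-series record of one run plus its specification."""

    spec: RunSpec
    times: np.ndarray
    theta: np.ndarray
    thetadot: np.ndarray
    tau_required: np.ndarray       # N*m, inverse-dynamics muscle moment
    assist_moment: np.ndarray      # N*m
    flexor_tension: np.ndarray     # N
    extensor_tension: np.ndarray   # N
    activations: np.ndarray        # (n, 6), forward-model state
    excitations: np.ndarray        # (n, 6)
    target_activations: np.ndarray  # (n, 6), static-optimization output
    muscle_forces: np.ndarray      # (n, 6), tendon-line force
    fiber_forces: np.ndarray       # (n, 6)
    norm_fiber_lengths: np.ndarray
    norm_fiber_velocities: np.ndarray
    reserve_moment: np.ndarray     # N*m
    reaction_fx: np.ndarray
    reaction_fy: np.ndarray
    normal_force: np.ndarray       # N, forearm strap
    shear_force: np.ndarray        # N, forearm strap
    metabolic: met.MetabolicBreakdown = None

    @property
    def reaction_magnitude(self) -> np.ndarray:
        return np.hypot(self.reaction_fx, self.reaction_fy)

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.spec.model.muscles]

    def tracking_error(self) -> float:
        """Max absolute deviation from the reference angle (rad)."""
        return float(np.max(np.abs(self.theta - self.spec.trajectory.theta)))

    def to_frame(self) -> pd.DataFrame:
        """Flat per-sample table; column dictionary in the package docs."""
        data = {
            "time": self.times,
            "theta": self.theta,
            "thetadot": self.thetadot,
            "theta_ref": self.spec.trajectory.theta,
            "tau_required": self.tau_required,
            "assist_moment": self.assist_moment,
            "flexor_tension": self.flexor_tension,
            "extensor_tension": self.extensor_tension,
            "reserve_moment": self.reserve_moment,
            "reaction_fx": self.reaction_fx,
            "reaction_fy": self.reaction_fy,
            "reaction_magnitude": self.reaction_magnitude,
            "strap_normal": self.normal_force,
            "strap_shear": self.shear_force,
        }
        for j, name in enumerate(self.muscle_names):
            data[f"act_{name}"] = self.activations[:, j]
            data[f"exc_{name}"] = self.excitations[:, j]
            data[f"force_{name}"] = self.muscle_forces[:, j]
        if self.metabolic is not None:
            data["metabolic_total"] = self.metabolic.total_rate
            data["metabolic_work"] = self.metabolic.work_rate
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_sto(self, path) -> None:
        """Write an OpenSim STO-format motion file for cross-checking."""
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(
                f"{self.spec.label or 'run'}\nversion=1\n"
                f"nRows={len(df)}\nnColumns={df.shape[1]}\n"
                "inDegrees=no\nendheader\n"
            )
            fh.write("\t".join(df.columns) + "\n")
            np.savetxt(fh, df.to_numpy(), delimiter="\t", fmt="%.10g")


@dataclass
class SummaryMetrics:
    """Assisted-versus-unassisted comparison for one matched condition."""

    activation_reduction: float        # %, mean biceps-group RMS activation
    moment_reduction: float            # %, RMS required muscle moment
    reaction_reduction: float          # %, RMS elbow reaction magnitude
    metabolic_reduction: float         # %, RMS total metabolic power
    peak_normal_force: float           # N, assisted forearm strap
    peak_shear_force: float            # N, assisted forearm strap
    triceps_rms_off: float
    triceps_rms_on: float
    rms: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "activation_reduction_pct": self.activation_reduction,
            "moment_reduction_pct": self.moment_reduction,
            "reaction_reduction_pct": self.reaction_reduction,
            "metabolic_reduction_pct": self.metabolic_reduction,
            "peak_normal_force_N": self.peak_normal_force,
            "peak_shear_force_N": self.peak_shear_force,
            "triceps_rms_off": self.triceps_rms_off,
            "triceps_rms_on": self.triceps_rms_on,
        }


def rms(x: np.ndarray) -> float:
    """Root mean square over the task window."""
    return float(np.sqrt(np.mean(np.square(np.asarray(x, float)))))


def percent_reduction(off: float, on: float) -> float:
    """``100 * (off - on) / off``; positive when assistance helps."""
    if off == 0:
        return 0.0
    return 100.0 * (off - on) / off


def run(spec: RunSpec) -> SimulationResult:
    """Execute one closed-loop simulation and assemble its record."""
    model = spec.model
    traj = spec.trajectory
    gains, settings = spec.resolved()
    n = len(traj)
    dt = float(traj.times[1] - traj.times[0])

    muscles = model.muscles
    inertia = dyn.mass_about_elbow(model)

    state = dyn.JointState(theta=float(traj.theta[0]), thetadot=0.0)

    # storage
    theta = np.empty(n)
    thetadot = np.empty(n)
    tau_req = np.empty(n)
    tau_a = np.empty(n)
    t1_arr = np.empty(n)
    t2_arr = np.empty(n)
    acts = np.empty((n, 6))
    excs = np.empty((n, 6))
    targets = np.empty((n, 6))
    forces = np.empty((n, 6))
    ffib = np.empty((n, 6))
    lnorm = np.empty((n, 6))
    vnorm = np.empty((n, 6))
    reserve = np.empty(n)
    rfx = np.empty(n)
    rfy = np.empty(n)
    fnorm = np.empty(n)
    fshear = np.empty(n)

    a_star_prev: np.ndarray | None = None
    activations: np.ndarray | None = None

    for k in range(n):
        th, thd = state.theta, state.thetadot

        # (2) assist law from the fed-back angle, mapped to tensions
        assist = exo.gc_assist_moment(model, th, enabled=spec.assist)
        geo = exo.cable_geometry(model.exosuit, th)
        t1, t2 = exo.cable_tensions(assist, geo.r_flexor, geo.r_extensor)

        # (3) inverse dynamics with PD feedback
        sample = (traj.theta[k], traj.thetadot[k], traj.thetaddot[k])
        tau = dyn.inverse_dynamics_moment(model, sample, state, gains, assist)

        # (4) static optimization at the fed-back kinematics
        problem = so.build_problem(model, th, thd, tau)
        a_star, res = so.solve(problem, warm_start=a_star_prev)

        # (5) activation-rate inversion to excitations
        rate = np.zeros(6) if a_star_prev is None else (a_star - a_star_prev) / dt
        u = np.array(
            [
                mm.excitation_from_activation(a_star[j], rate[j], muscles[j])
                for j in range(6)
            ]
        )
        a_star_prev = a_star

        if activations is None:
            # start from the statically consistent activation set
            activations = a_star.copy()

        # record the current grid point
        theta[k], thetadot[k] = th, thd
        tau_req[k], tau_a[k] = tau, assist
        t1_arr[k], t2_arr[k] = t1, t2
        targets[k] = a_star
        excs[k] = u
        acts[k] = activations
        reserve[k] = res

        mus_force = np.empty(6)
        for j, musc in enumerate(muscles):
            st = mm.evaluate_geometry(musc, th, thd)
            st.activation = float(activations[j])
            mus_force[j] = mm.muscle_force(musc, st)
            ffib[k, j] = mm.fiber_force(musc, st)
            lnorm[k, j] = st.norm_fiber_length
            vnorm[k, j] = st.norm_fiber_velocity
        forces[k] = mus_force

        cable_f = exo.cable_force_on_forearm(model.exosuit, th, t1, t2)
        reaction = dyn.joint_reaction(model, state, mus_force, cable_f)
        rfx[k], rfy[k] = reaction.fx, reaction.fy
        inter = exo.interaction_forces(model.exosuit, th, t1, t2)
        fnorm[k], fshear[k] = inter.normal, inter.shear

        # (6) advance the forward model (not past the last grid point)
        if k < n - 1:
            frame = exo.ControlFrame(
                excitations=u,
                flexor_tension=t1,
                extensor_tension=t2,
                assist_moment=assist,
                timestamp=float(traj.times[k]),
            )
            frame.validate()
            state, activations = dyn.forward_step(model, state, activations, frame, dt)

    breakdown = met.metabolic_rate(
        model, traj.times, excs, acts, lnorm, vnorm, ffib
    )

    return SimulationResult(
        spec=spec,
        times=traj.times.copy(),
        theta=theta,
        thetadot=thetadot,
        tau_required=tau_req,
        assist_moment=tau_a,
        flexor_tension=t1_arr,
        extensor_tension=t2_arr,
        activations=acts,
        excitations=excs,
        target_activations=targets,
        muscle_forces=forces,
        fiber_forces=ffib,
        norm_fiber_lengths=lnorm,
        norm_fiber_velocities=vnorm,
        reserve_moment=reserve,
        reaction_fx=rfx,
        reaction_fy=rfy,
        normal_force=fnorm,
        shear_force=fshear,
        metabolic=breakdown,
    )


def sweep(specs: list[RunSpec]) -> list[SimulationResult]:
    """Run a list of conditions serially; order does not affect results."""
    if not specs:
        raise ValueError("sweep requires at least one RunSpec")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels in sweep: {labels}")
    results = []
    errors = {}
    for s in specs:
        try:
            results.append(run(copy.deepcopy(s)))
        except Exception as exc:  # collect, report at the end
            errors[s.label] = exc
            results.append(None)
    if errors:
        summary = "; ".join(f"{lab}: {err}" for lab, err in errors.items())
        raise RuntimeError(f"sweep cells failed: {summary}")
    return results


def _group_indices(result: SimulationResult, group: str) -> list[int]:
    names = result.muscle_names
    if group == "flexors":
        wanted = FLEXOR_NAMES
    elif group == "biceps_heads":
        wanted = ("biceps_long", "biceps_short")
    else:
        raise ValueError(f"unknown muscle group {group!r}")
    return [names.index(w) for w in wanted]


def group_rms_activation(result: SimulationResult, group: str = "flexors") -> float:
    """Mean of per-muscle RMS activation over the named group."""
    idx = _group_indices(result, group)
    return float(np.mean([rms(result.activations[:, j]) for j in idx]))


def triceps_rms_activation(result: SimulationResult) -> float:
    names = result.muscle_names
    idx = [j for j, nm in enumerate(names) if nm.startswith("triceps")]
    return float(np.mean([rms(result.activations[:, j]) for j in idx]))


def summarize(
    off: SimulationResult, on: SimulationResult, group: str = "flexors"
) -> SummaryMetrics:
    """Assist-benefit metrics for one matched off/on condition pair."""
    if off.times.shape != on.times.shape or not np.allclose(off.times, on.times):
        raise ValueError("off/on runs must share the same time grid")
    if off.spec.assist or not on.spec.assist:
        raise ValueError("expected (assist OFF, assist ON) result pair")

    act_off = group_rms_activation(off, group)
    act_on = group_rms_activation(on, group)
    mom_off, mom_on = rms(off.tau_required), rms(on.tau_required)
    rea_off, rea_on = rms(off.reaction_magnitude), rms(on.reaction_magnitude)
    met_off = off.metabolic.rms_total
    met_on = on.metabolic.rms_total

    return SummaryMetrics(
        activation_reduction=percent_reduction(act_off, act_on),
        moment_reduction=percent_reduction(mom_off, mom_on),
        reaction_reduction=percent_reduction(rea_off, rea_on),
        metabolic_reduction=percent_reduction(met_off, met_on),
        peak_normal_force=float(np.max(on.normal_force)),
        peak_shear_force=float(np.max(on.shear_force)),
        triceps_rms_off=triceps_rms_activation(off),
        triceps_rms_on=triceps_rms_activation(on),
        rms={
            "activation_off": act_off,
            "activation_on": act_on,
            "moment_off": mom_off,
            "moment_on": mom_on,
            "reaction_off": rea_off,
            "reaction_on": rea_on,
            "metabolic_off": met_off,
            "metabolic_on": met_on,
        },
    )
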