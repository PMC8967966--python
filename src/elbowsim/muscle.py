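"""Hill-type muscle mechanics: geometry, force curves, activation dynamics.

The force of each musculotendon unit is

    F = Fmax * [ fl(l~) * fv(v~) * a + fp(l~) ] * cos(phi)

with ``l~`` the fiber length normalised by the optimal fiber length,
``v~`` the fiber velocity normalised by the maximum shortening velocity
(shortening negative), ``a`` the activation and ``phi`` the pennation
angle.  The curve shapes follow the Thelen-style muscle model:

* active force-length: Gaussian ``exp(-(l~-1)^2 / gamma)``, gamma=0.45;
* force-velocity: Hill hyperbola on the concentric side (zero force at
  ``v~ = -1``), saturating eccentric branch approaching ``FmLen = 1.4``,
  C1-continuous at the isometric point;
* passive force-length: exponential with shape factor ``kf = 4`` and
  strain at one maximum isometric force ``eps0 = 0.6``, zero at or
  below slack (``l~ <= 1``).

The tendon is rigid: the fiber absorbs all MTU length change, with a
constant-thickness pennation model (``l * sin(phi)`` constant).  This
keeps the per-instant redundancy problem algebraic.

Activation dynamics are the standard first-order lag with state-dependent
time constant,

    da/dt = (u - a) / kappa(a, u),
    kappa = kact * (0.5 + 1.5 a)      if u > a,
    kappa = kdeact / (0.5 + 1.5 a)    if u <= a,

which is analytically invertible for the excitation ``u`` given ``a``
and the desired rate — the inversion the muscle command generator uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import GEOMETRY_FIT_RANGE, MuscleParams

__all__ = [
    "MuscleState",
    "evaluate_geometry",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
    "muscle_force",
    "activation_derivative",
    "excitation_from_activation",
]

log = logging.getLogger(__name__)

# Thelen-style curve constants (dimensionless)
FL_GAMMA = 0.45    # width of the active force-length Gaussian
FV_FMLEN = 1.4     # eccentric force asymptote
FV_AF = 0.25       # Hill force-velocity shape factor
FP_KF = 4.0        # passive exponential shape factor
FP_EPS0 = 0.6      # passive strain at one maximum isometric force


@dataclass
class MuscleState:
    """Instantaneous kinematic and activation state of one muscle."""

    fiber_length: float
    norm_fiber_length: float
    fiber_velocity: float       # m/s, shortening negative
    norm_fiber_velocity: float  # fiber velocity / (vmax * lopt)
    pennation: float            # rad
    moment_arm: float           # m, signed (+ flexion)
    activation: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.activation <= 1.0):
            raise ValueError(f"activation out of [0, 1]: {self.activation}")
        if self.fiber_length <= 0:
            raise ValueError(f"fiber_length must be > 0: {self.fiber_length}")
        if not (0.0 <= self.pennation < math.pi / 2):
            raise ValueError(f"pennation out of [0, pi/2): {self.pennation}")


def evaluate_geometry(
    muscle: MuscleParams, theta: float, thetadot: float = 0.0
) -> MuscleState:
    """Kinematic muscle state at elbow angle ``theta`` and rate ``thetadot``.

    Angles outside the fixture fit range are clamped (with a logged
    warning) rather than extrapolated.
    """
    lo, hi = GEOMETRY_FIT_RANGE
    if theta < lo or theta > hi:
        log.warning(
            "elbow angle %.3f rad outside geometry fit range [%.2f, %.2f]; clamping",
            theta, lo, hi,
        )
        theta = min(max(theta, lo), hi)

    arm = float(muscle.moment_arm(theta))
    lmtu = float(muscle.mtu_length(theta))
    lopt = muscle.optimal_fiber_length
    h = lopt * math.sin(muscle.pennation_at_optimal)  # constant muscle thickness
    proj = max(lmtu - muscle.tendon_slack_length, 1e-4)  # fiber length along tendon
    lfiber = math.hypot(proj, h)
    phi = math.atan2(h, proj)
    # rigid tendon: d(lmtu)/dt = -arm * thetadot, fiber rate = that * cos(phi)
    vfiber = -arm * thetadot * math.cos(phi)
    vmax = muscle.max_contraction_velocity * lopt  # m/s
    return MuscleState(
        fiber_length=lfiber,
        norm_fiber_length=lfiber / lopt,
        fiber_velocity=vfiber,
        norm_fiber_velocity=vfiber / vmax,
        pennation=phi,
        moment_arm=arm,
    )


def active_force_length(norm_fiber_length):
    """Active force-length multiplier, Gaussian about the optimal length."""
    lnorm = np.asarray(norm_fiber_length, dtype=float)
    out = np.exp(-((lnorm - 1.0) ** 2) / FL_GAMMA)
    return out if out.ndim else float(out)


def force_velocity(norm_fiber_velocity, activation: float = 1.0):
    """Force-velocity multiplier; shortening negative, isometric at 1.

    The concentric branch is the Hill hyperbola
    ``(1 + v~) / (1 - v~/Af)`` (zero at ``v~ = -1``); the eccentric
    branch ``(FmLen v~ + c) / (v~ + c)`` with ``c = (FmLen-1)/ (1 + 1/Af)``
    matches value and slope at ``v~ = 0`` and approaches ``FmLen``.
    The ``activation`` argument is accepted for interface symmetry; the
    default curve does not rescale with activation.
    """
    v = np.asarray(norm_fiber_velocity, dtype=float)
    conc = np.clip((1.0 + v) / (1.0 - np.minimum(v, 0.0) / FV_AF), 0.0, None)
    c = (FV_FMLEN - 1.0) / (1.0 + 1.0 / FV_AF)
    ecc = (FV_FMLEN * v + c) / (v + c)
    out = np.where(v < 0.0, conc, ecc)
    return out if out.ndim else float(out)


def passive_force_length(norm_fiber_length):
    """Passive elastic multiplier; zero at or below slack (``l~ <= 1``)."""
    lnorm = np.asarray(norm_fiber_length, dtype=float)
    raw = (np.exp(FP_KF * (lnorm - 1.0) / FP_EPS0) - 1.0) / (math.exp(FP_KF) - 1.0)
    out = np.maximum(raw, 0.0)
    return out if out.ndim else float(out)


def muscle_force(params: MuscleParams, state: MuscleState) -> float:
    """Tendon-line force (N) of one muscle in the given state; >= 0."""
    a = min(max(state.activation, 0.0), 1.0)
    fl = active_force_length(state.norm_fiber_length)
    fv = force_velocity(state.norm_fiber_velocity, a)
    fp = passive_force_length(state.norm_fiber_length)
    return max(
        params.max_isometric_force * (fl * fv * a + fp) * math.cos(state.pennation),
        0.0,
    )


def fiber_force(params: MuscleParams, state: MuscleState) -> float:
    """Force along the fiber (N), i.e. without the pennation projection."""
    a = min(max(state.activation, 0.0), 1.0)
    fl = active_force_length(state.norm_fiber_length)
    fv = force_velocity(state.norm_fiber_velocity, a)
    fp = passive_force_length(state.norm_fiber_length)
    return max(params.max_isometric_force * (fl * fv * a + fp), 0.0)


def _kappa(a: float, u: float, params: MuscleParams) -> float:
    if u > a:
        return params.act_time_constant * (0.5 + 1.5 * a)
    return params.deact_time_constant / (0.5 + 1.5 * a)


def activation_derivative(a: float, u: float, params: MuscleParams) -> float:
    """First-order activation dynamics rate da/dt (1/s)."""
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"activation out of [0, 1]: {a}")
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"excitation out of [0, 1]: {u}")
    return (u - a) / _kappa(a, u, params)


def excitation_from_activation(a: float, dadt: float, params: MuscleParams) -> float:
    """Invert the activation dynamics: the excitation producing ``dadt`` at ``a``.

    A positive rate selects the fast (activation) branch, a non-positive
    rate the slow (deactivation) branch; the branches agree at
    ``dadt = 0`` where ``u = a``.  The result is clamped to [0, 1] (a
    clamp is logged at debug level) since no admissible excitation can
    exceed the bounds.
    """
    a = min(max(a, 0.0), 1.0)
    if dadt > 0.0:
        u = a + params.act_time_constant * (0.5 + 1.5 * a) * dadt
    else:
        u = a + params.deact_time_constant / (0.5 + 1.5 * a) * dadt
    if u < 0.0 or u > 1.0:
        log.debug("excitation %.4f clamped to [0, 1] (a=%.4f, dadt=%.2f)", u, a, dadt)
        u = min(max(u, 0.0), 1.0)
    return u
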