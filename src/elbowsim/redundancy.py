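"""Per-instant muscle redundancy resolution by least squared activation.

Each control step solves

    minimize    sum_i a_i^2
    subject to  tau_required = sum_i d_i * (cap_i * a_i) + sum_i pm_i,
                0 <= a_i <= 1,

where ``cap_i = Fmax_i fl(l~_i) fv(v~_i) cos(phi_i)`` is the active
force capacity of muscle *i* at the current kinematic state and
``pm_i = d_i Fmax_i fp(l~_i) cos(phi_i)`` its (activation-independent)
passive moment contribution.

The problem is a bound-constrained quadratic program with one equality
constraint, whose KKT conditions give ``a_i = clip(lambda w_i / 2, 0, 1)``
with ``w_i = d_i cap_i`` and a scalar multiplier ``lambda``.  The solver
finds ``lambda`` by bisection on the (monotone, piecewise-linear)
constraint residual — exact to machine precision, deterministic, and far
cheaper than a generic NLP iteration.  When the demanded moment exceeds
total muscle capacity an optional reserve actuator (quadratic penalty
weight 1000) absorbs the residual and the event is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import muscle as mm
from .model import ArmModel

__all__ = ["RedundancyProblem", "build_problem", "solve", "InfeasibleProblem"]

log = logging.getLogger(__name__)

RESERVE_PENALTY = 1000.0


class InfeasibleProblem(RuntimeError):
    """Moment demand cannot be met and the reserve actuator is disabled."""


@dataclass
class RedundancyProblem:
    """One instant's linearised muscle-redundancy problem."""

    required_moment: float            # N*m
    moment_arms: np.ndarray           # m, signed, 6-vector
    active_capacities: np.ndarray     # N, >= 0, 6-vector
    passive_moments: np.ndarray       # N*m, 6-vector
    allow_reserve: bool = True
    tolerance: float = 1e-6

    @property
    def weights(self) -> np.ndarray:
        """Moment produced per unit activation, ``w_i = d_i * cap_i``."""
        return self.moment_arms * self.active_capacities

    @property
    def active_demand(self) -> float:
        """Moment the active fibers must supply after passive credits."""
        return self.required_moment - float(np.sum(self.passive_moments))


def build_problem(
    model: ArmModel,
    theta: float,
    thetadot: float,
    required_moment: float,
    allow_reserve: bool = True,
) -> RedundancyProblem:
    """Evaluate capacities and passive moments at the current kinematics."""
    arms = np.empty(6)
    caps = np.empty(6)
    passive = np.empty(6)
    for i, musc in enumerate(model.muscles):
        st = mm.evaluate_geometry(musc, theta, thetadot)
        fl = mm.active_force_length(st.norm_fiber_length)
        fv = mm.force_velocity(st.norm_fiber_velocity)
        fp = mm.passive_force_length(st.norm_fiber_length)
        cosphi = np.cos(st.pennation)
        arms[i] = st.moment_arm
        caps[i] = max(musc.max_isometric_force * fl * fv * cosphi, 0.0)
        passive[i] = st.moment_arm * musc.max_isometric_force * fp * cosphi
    return RedundancyProblem(
        required_moment=float(required_moment),
        moment_arms=arms,
        active_capacities=caps,
        passive_moments=passive,
        allow_reserve=allow_reserve,
        tolerance=model.settings.optimizer_tolerance,
    )


def _delivered(lam: float, w: np.ndarray, reserve: bool) -> float:
    a = np.clip(lam * w / 2.0, 0.0, 1.0)
    out = float(w @ a)
    if reserve:
        out += lam / (2.0 * RESERVE_PENALTY)
    return out


def solve(
    problem: RedundancyProblem, warm_start: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Solve for the activation 6-vector; returns ``(activations, reserve)``.

    ``reserve`` is the moment (N*m) supplied by the reserve actuator
    (zero whenever the muscles alone can meet the demand).  The
    ``warm_start`` argument is accepted for interface compatibility;
    the bisection solve is exact and needs no starting point.
    """
    w = problem.weights
    b = problem.active_demand
    tol = problem.tolerance

    if abs(b) <= tol:
        return np.zeros(6), 0.0

    max_pos = _delivered(1e30, w, False)   # every positive-weight muscle saturated
    max_neg = _delivered(-1e30, w, False)
    feasible = max_neg - tol <= b <= max_pos + tol
    if not feasible and not problem.allow_reserve:
        gap = b - (max_pos if b > 0 else max_neg)
        raise InfeasibleProblem(
            f"moment demand {problem.required_moment:.3f} N*m exceeds muscle "
            f"capacity; gap {gap:.3f} N*m (enable the reserve actuator to proceed)"
        )

    # the reserve actuator only engages when the muscles alone cannot close
    # the equality, so feasible problems are solved exactly without it
    reserve = problem.allow_reserve and not feasible
    # bracket the multiplier; _delivered is nondecreasing in lambda
    scale = float(np.max(np.abs(w))) or 1.0
    lo, hi = 0.0, 2.0 * abs(b) / max(scale**2 / 6.0, 1e-12)
    if reserve:
        hi = max(hi, 2.0 * RESERVE_PENALTY * abs(b))
    hi += 1.0
    sign = 1.0 if b > 0 else -1.0
    f = lambda lam: _delivered(sign * lam, w, reserve) * sign
    while f(hi) < abs(b) and hi < 1e16:
        hi *= 4.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < abs(b):
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * max(1.0, hi):
            break
    lam = sign * 0.5 * (lo + hi)
    a = np.clip(lam * w / 2.0, 0.0, 1.0)
    res = lam / (2.0 * RESERVE_PENALTY) if reserve else 0.0
    achieved = float(w @ a) + res
    if abs(achieved - b) > max(tol, 1e-9 * abs(b)):
        raise InfeasibleProblem(
            f"solver failed to close the moment equality: demand {b:.6f}, "
            f"achieved {achieved:.6f} (lambda={lam:.3e})"
        )
    if reserve:
        log.warning(
            "reserve actuator engaged: %.4f N*m beyond muscle capacity", res
        )
    return a, float(res)
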