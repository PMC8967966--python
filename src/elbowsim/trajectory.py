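"""Minimum-jerk reference trajectories for the elbow-flexion task.

The reference motion is the classical quintic minimum-jerk reach

    theta(t) = theta0 + dtheta * (10 s^3 - 15 s^4 + 6 s^5),  s = t/T,

which has zero velocity and acceleration at both endpoints and peak
angular velocity ``1.875 * dtheta / T``.  The task of interest flexes
the elbow from 0 to 1.57 rad in either 1 s (fast) or 2 s (slow),
sampled on a uniform grid at the control rate (121 Hz by default,
endpoints included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ReferenceTrajectory", "make_min_jerk", "perturb_trajectory"]


class ParameterError(ValueError):
    """An invalid trajectory parameter."""


@dataclass
class ReferenceTrajectory:
    """Sampled desired elbow angle and its first two derivatives."""

    times: np.ndarray
    theta: np.ndarray
    thetadot: np.ndarray
    thetaddot: np.ndarray
    duration: float
    theta_start: float
    theta_end: float

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])

    def to_csv(self, path) -> None:
        """Write a two-column (time, angle) CSV."""
        pd.DataFrame({"time": self.times, "theta": self.theta}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, smoothing: float = 0.0) -> "ReferenceTrajectory":
        """Read a (time, angle) CSV; derivatives via a smoothing spline."""
        from scipy.interpolate import make_splrep

        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        th = df.iloc[:, 1].to_numpy(float)
        spl = make_splrep(t, th, k=5, s=smoothing)
        return cls(
            times=t,
            theta=spl(t),
            thetadot=spl.derivative(1)(t),
            thetaddot=spl.derivative(2)(t),
            duration=float(t[-1] - t[0]),
            theta_start=float(th[0]),
            theta_end=float(th[-1]),
        )


def _grid(duration: float, sample_rate: float) -> np.ndarray:
    n = int(round(duration * sample_rate))
    return np.linspace(0.0, duration, n + 1)


def make_min_jerk(
    theta_start: float,
    theta_end: float,
    duration: float,
    sample_rate: float = 121.0,
) -> ReferenceTrajectory:
    """Build the quintic minimum-jerk trajectory on a uniform grid.

    Parameters
    ----------
    theta_start, theta_end
        Endpoint elbow angles (rad).
    duration
        Movement time T (s); must be positive.
    sample_rate
        Grid rate (Hz); both endpoints are included.
    """
    if duration <= 0:
        raise ParameterError(f"duration must be > 0, got {duration}")
    if sample_rate <= 0:
        raise ParameterError(f"sample_rate must be > 0, got {sample_rate}")
    t = _grid(duration, sample_rate)
    s = t / duration
    d = theta_end - theta_start
    theta = theta_start + d * (10 * s**3 - 15 * s**4 + 6 * s**5)
    thetadot = d / duration * (30 * s**2 - 60 * s**3 + 30 * s**4)
    thetaddot = d / duration**2 * (60 * s - 180 * s**2 + 120 * s**3)
    return ReferenceTrajectory(
        times=t,
        theta=theta,
        thetadot=thetadot,
        thetaddot=thetaddot,
        duration=float(duration),
        theta_start=float(theta_start),
        theta_end=float(theta_end),
    )


def perturb_trajectory(
    traj: ReferenceTrajectory,
    kind: str,
    magnitude: float,
    center: float | None = None,
    width: float | None = None,
) -> ReferenceTrajectory:
    """Add a robustness perturbation with analytically consistent derivatives.

    ``rapid_change`` adds a compactly supported C2 bump
    ``magnitude * (4 z (1 - z))^3`` with ``z = (t - c)/w + 1/2`` on the
    window ``|t - c| < w/2`` (value, slope, and curvature all vanish at
    the support edges); the endpoints of the trajectory are untouched as
    long as the bump support stays inside the time span.
    ``intermittent`` adds a smoothstep ramp (quintic, zero end slopes)
    that switches the reference by ``magnitude`` over the window and
    holds it — emulating a step-like intent change with bounded
    derivatives.
    """
    c = traj.duration / 2 if center is None else center
    w = traj.duration / 5 if width is None else width
    t = traj.times
    x = (t - c) / w  # window-normalised time

    if kind == "rapid_change":
        inside = np.abs(x) < 0.5
        z = np.clip(x + 0.5, 0.0, 1.0)
        h = 4.0 * z * (1.0 - z)          # 0..1, peak at the window center
        dh = 4.0 - 8.0 * z               # dh/dz
        bump = h**3
        dbump = np.where(inside, 3.0 * h**2 * dh / w, 0.0)
        ddbump = np.where(inside, (6.0 * h * dh**2 - 24.0 * h**2) / w**2, 0.0)
    elif kind == "intermittent":
        s = np.clip(x + 0.5, 0.0, 1.0)
        ramp_on = (x > -0.5) & (x < 0.5)
        bump = 10 * s**3 - 15 * s**4 + 6 * s**5
        dbump = np.where(ramp_on, (30 * s**2 - 60 * s**3 + 30 * s**4) / w, 0.0)
        ddbump = np.where(ramp_on, (60 * s - 180 * s**2 + 120 * s**3) / w**2, 0.0)
    else:
        raise ParameterError(f"unknown perturbation kind {kind!r}")

    return ReferenceTrajectory(
        times=t,
        theta=traj.theta + magnitude * bump,
        thetadot=traj.thetadot + magnitude * dbump,
        thetaddot=traj.thetaddot + magnitude * ddbump,
        duration=traj.duration,
        theta_start=traj.theta_start,
        theta_end=float(traj.theta_end + (magnitude * bump[-1])),
    )
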