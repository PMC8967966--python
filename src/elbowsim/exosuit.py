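"""Gravity-compensation exosuit: assist law, cable mapping, strap forces.

The assist controller is purely angle-based gravity compensation: the
desired actuator moment equals the gravity-demanded flexion moment

    tau_a = (m g lc + M g ll) * sin(theta)

evaluated at the measured output elbow angle.  An actuator module maps
the desired moment to cable tensions through the instantaneous cable
moment arms: a positive (flexion) moment is carried entirely by the
flexor cable (``T1 = tau_a / r1``, ``T2 = 0``) and a negative moment by
the extensor cable (``T1 = 0``, ``T2 = |tau_a| / r2``), so at most one
cable is taut at a time.

Each cable is a straight segment from an upper-arm strap anchor (fixed
in the vertical upper-arm frame) to a forearm strap anchor (rotating
with the forearm).  World frame: x anterior, y up, elbow at the origin;
the forearm long axis points along ``(sin theta, -cos theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ArmModel, ExosuitGeometry

__all__ = [
    "ControlFrame",
    "InteractionForce",
    "CableGeometry",
    "gc_assist_moment",
    "cable_geometry",
    "cable_tensions",
    "cable_moment",
    "cable_force_on_forearm",
    "interaction_forces",
]


class GeometryError(ValueError):
    """Degenerate or invalid cable geometry."""


@dataclass
class ControlFrame:
    """One control step's muscle excitations and cable tensions."""

    excitations: np.ndarray      # 6-vector in [0, 1]
    flexor_tension: float        # N
    extensor_tension: float      # N
    assist_moment: float         # N*m, requested actuator moment
    timestamp: float = 0.0       # s

    def validate(self) -> None:
        u = np.asarray(self.excitations, float)
        if u.shape != (6,) or np.any(u < 0) or np.any(u > 1):
            raise ValueError(f"excitations must be a 6-vector in [0, 1], got {u}")
        if self.flexor_tension < 0 or self.extensor_tension < 0:
            raise ValueError("cable tensions must be >= 0")
        if self.flexor_tension > 0 and self.extensor_tension > 0:
            raise ValueError("at most one cable may be taut at a time")


@dataclass
class InteractionForce:
    """Strap contact force magnitudes in the forearm frame."""

    normal: float  # N, perpendicular to the forearm long axis
    shear: float   # N, along the forearm long axis
    at: str = "forearm_strap"


@dataclass
class CableGeometry:
    """Instantaneous cable moment arms and pull directions (world frame)."""

    r_flexor: float              # m, moment arm of the flexor cable
    r_extensor: float            # m, moment arm of the extensor cable
    flexor_unit: np.ndarray      # unit vector of flexor pull at its forearm anchor
    extensor_unit: np.ndarray
    flexor_anchor_world: np.ndarray
    extensor_anchor_world: np.ndarray


def gc_assist_moment(model: ArmModel, theta: float, enabled: bool = True) -> float:
    """Gravity-compensation actuator moment (N*m) at elbow angle ``theta``."""
    if not enabled:
        return 0.0
    seg, load = model.segment, model.load
    return (
        seg.forearm_mass * model.gravity * seg.com_distance
        + load.external_mass * model.gravity * load.load_distance
    ) * math.sin(theta)


def _forearm_axes(theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Forearm long-axis and anterior-perpendicular unit vectors (world)."""
    e_axis = np.array([math.sin(theta), -math.cos(theta)])
    e_perp = np.array([math.cos(theta), math.sin(theta)])
    return e_axis, e_perp


def _one_cable(
    arm_anchor: tuple[float, float],
    forearm_anchor: tuple[float, float],
    theta: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed moment arm (+ = flexion), pull unit vector, anchor position."""
    e_axis, e_perp = _forearm_axes(theta)
    p = forearm_anchor[1] * e_axis + forearm_anchor[0] * e_perp  # world
    a = np.array(arm_anchor, float)  # upper-arm frame == world frame
    seg = a - p
    length = float(np.hypot(*seg))
    if length < 1e-9:
        raise GeometryError(f"zero-length cable at theta={theta:.3f}")
    u = seg / length
    r_signed = float(p[0] * u[1] - p[1] * u[0])  # z of p x u
    return r_signed, u, p


def cable_geometry(geom: ExosuitGeometry, theta: float) -> CableGeometry:
    """Moment arms and pull directions of both cables at angle ``theta``."""
    fa, ff = geom.flexor_anchors
    ea, ef = geom.extensor_anchors
    r1, u1, p1 = _one_cable(fa, ff, theta)
    r2, u2, p2 = _one_cable(ea, ef, theta)
    # flexor produces +theta moment, extensor -theta; report both positive
    return CableGeometry(
        r_flexor=r1,
        r_extensor=-r2,
        flexor_unit=u1,
        extensor_unit=u2,
        flexor_anchor_world=p1,
        extensor_anchor_world=p2,
    )


def cable_tensions(assist_moment: float, r1: float, r2: float) -> tuple[float, float]:
    """Map a desired actuator moment to (flexor, extensor) cable tensions."""
    if r1 <= 0 or r2 <= 0:
        raise GeometryError(f"cable moment arms must be positive, got r1={r1}, r2={r2}")
    if assist_moment > 0:
        return assist_moment / r1, 0.0
    if assist_moment < 0:
        return 0.0, -assist_moment / r2
    return 0.0, 0.0


def cable_moment(geom: ExosuitGeometry, theta: float, t1: float, t2: float) -> float:
    """Joint moment (N*m) applied by the cables at angle ``theta``."""
    geo = cable_geometry(geom, theta)
    return geo.r_flexor * t1 - geo.r_extensor * t2


def cable_force_on_forearm(
    geom: ExosuitGeometry, theta: float, t1: float, t2: float
) -> np.ndarray:
    """Total world-frame cable force applied at the forearm strap (N)."""
    geo = cable_geometry(geom, theta)
    return t1 * geo.flexor_unit + t2 * geo.extensor_unit


def interaction_forces(
    geom: ExosuitGeometry, theta: float, t1: float, t2: float
) -> InteractionForce:
    """Normal/shear strap force magnitudes on the forearm at angle ``theta``."""
    if t1 < 0 or t2 < 0:
        raise ValueError("cable tensions must be >= 0")
    f = cable_force_on_forearm(geom, theta, t1, t2)
    e_axis, e_perp = _forearm_axes(theta)
    return InteractionForce(
        normal=abs(float(f @ e_perp)),
        shear=abs(float(f @ e_axis)),
        at="forearm_strap",
    )
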