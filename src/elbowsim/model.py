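"""Domain types, configuration loading, and the packaged muscle fixture.

The simulated system is a planar, single-degree-of-freedom elbow: the
upper arm is vertical and fixed (shoulder locked), the forearm rotates
about the elbow, and the elbow angle ``theta`` is measured from the
downward vertical (``theta = 0`` with the arm hanging fully extended,
``pi/2`` flexed to horizontal).  Six Hill-type muscles — three flexors
(biceps long and short head, brachialis) and three extensors (triceps
long, medial, lateral heads) — actuate the joint, and a cable-driven
exosuit with one flexor and one extensor cable can assist it.

All quantities are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "SegmentParams",
    "LoadCase",
    "MuscleParams",
    "ExosuitGeometry",
    "Gains",
    "SimSettings",
    "ArmModel",
    "MUSCLE_NAMES",
    "FLEXOR_NAMES",
    "EXTENSOR_NAMES",
    "load_model",
    "write_config",
    "default_model",
    "default_muscle_fixture",
]

#: Canonical muscle names, in fixture order.
MUSCLE_NAMES = (
    "biceps_long",
    "biceps_short",
    "brachialis",
    "triceps_long",
    "triceps_medial",
    "triceps_lateral",
)
FLEXOR_NAMES = MUSCLE_NAMES[:3]
EXTENSOR_NAMES = MUSCLE_NAMES[3:]

#: Angle range (rad) over which the fixture polynomials were fitted.
GEOMETRY_FIT_RANGE = (-0.1, 1.8)


class ConfigurationError(ValueError):
    """A configuration file is missing fields or cannot be parsed."""


class ValidationError(ValueError):
    """A parsed configuration violates a model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class SegmentParams:
    """Inertial parameters of the forearm segment.

    ``inertia_about_elbow`` is the sagittal-plane moment of inertia of
    the forearm taken about the elbow joint (not the segment COM); see
    :class:`SimSettings.inertia_about` for the alternative reading.
    """

    forearm_mass: float
    com_distance: float
    inertia_about_elbow: float
    upper_arm_orientation: float = 0.0

    def validate(self) -> None:
        _require(self.forearm_mass > 0, f"forearm_mass must be > 0, got {self.forearm_mass}")
        _require(self.com_distance > 0, f"com_distance must be > 0, got {self.com_distance}")
        _require(
            self.inertia_about_elbow > 0,
            f"inertia_about_elbow must be > 0, got {self.inertia_about_elbow}",
        )


@dataclass
class LoadCase:
    """A hand-held point load at ``load_distance`` along the forearm."""

    external_mass: float
    load_distance: float

    def validate(self) -> None:
        _require(self.external_mass >= 0, f"external_mass must be >= 0, got {self.external_mass}")
        _require(self.load_distance > 0, f"load_distance must be > 0, got {self.load_distance}")


@dataclass
class MuscleParams:
    """Hill-type parameters and angle-polynomial geometry of one muscle.

    ``moment_arm_coeffs`` and ``mtu_length_coeffs`` are polynomial
    coefficients in the elbow angle (ascending powers, radians in,
    metres out).  The moment arm is signed: positive produces a flexion
    moment.  Geometric consistency requires
    ``d(mtu_length)/d(theta) = -moment_arm`` for the signed arm, i.e.
    flexor MTUs shorten as the elbow flexes.

    ``origin``/``insertion`` are effective straight-line attachment
    points (upper-arm frame / forearm frame) used only to orient muscle
    force vectors in the joint-reaction balance.
    """

    name: str
    max_isometric_force: float
    optimal_fiber_length: float
    tendon_slack_length: float
    max_contraction_velocity: float
    pennation_at_optimal: float
    act_time_constant: float
    deact_time_constant: float
    moment_arm_coeffs: tuple[float, ...]
    mtu_length_coeffs: tuple[float, ...]
    sign: int
    origin: tuple[float, float] = (0.0, 0.2)
    insertion: tuple[float, float] = (0.0, 0.03)

    def __post_init__(self) -> None:
        self.moment_arm_coeffs = tuple(float(c) for c in self.moment_arm_coeffs)
        self.mtu_length_coeffs = tuple(float(c) for c in self.mtu_length_coeffs)
        self.origin = tuple(float(c) for c in self.origin)
        self.insertion = tuple(float(c) for c in self.insertion)

    def moment_arm(self, theta: float | np.ndarray) -> float | np.ndarray:
        """Signed muscle moment arm (m) at elbow angle ``theta``."""
        return np.polynomial.polynomial.polyval(theta, self.moment_arm_coeffs)

    def mtu_length(self, theta: float | np.ndarray) -> float | np.ndarray:
        """Musculotendon-unit path length (m) at elbow angle ``theta``."""
        return np.polynomial.polynomial.polyval(theta, self.mtu_length_coeffs)

    def validate(self) -> None:
        _require(self.name in MUSCLE_NAMES, f"unknown muscle name {self.name!r}")
        _require(self.sign in (-1, 1), f"{self.name}: sign must be +1 or -1, got {self.sign}")
        _require(
            self.max_isometric_force > 0,
            f"{self.name}: max_isometric_force must be > 0, got {self.max_isometric_force}",
        )
        _require(
            self.optimal_fiber_length > 0,
            f"{self.name}: optimal_fiber_length must be > 0, got {self.optimal_fiber_length}",
        )
        _require(
            self.tendon_slack_length >= 0,
            f"{self.name}: tendon_slack_length must be >= 0, got {self.tendon_slack_length}",
        )
        _require(
            self.max_contraction_velocity > 0,
            f"{self.name}: max_contraction_velocity must be > 0, "
            f"got {self.max_contraction_velocity}",
        )
        _require(
            0 <= self.pennation_at_optimal < math.pi / 2,
            f"{self.name}: pennation_at_optimal must lie in [0, pi/2), "
            f"got {self.pennation_at_optimal}",
        )
        _require(
            0 < self.act_time_constant < self.deact_time_constant,
            f"{self.name}: need 0 < act_time_constant < deact_time_constant, "
            f"got {self.act_time_constant}, {self.deact_time_constant}",
        )
        # sign of the moment arm must match the flexor/extensor label
        thetas = np.linspace(0.0, math.pi / 2, 50)
        arms = self.moment_arm(thetas)
        _require(
            bool(np.all(np.sign(arms) == self.sign)),
            f"{self.name}: moment arm changes sign or contradicts sign={self.sign} "
            f"on [0, pi/2] (range {arms.min():.4g}..{arms.max():.4g})",
        )
        # geometric consistency: dL/dtheta = -moment_arm (central differences)
        h = 1e-5
        dl = (self.mtu_length(thetas + h) - self.mtu_length(thetas - h)) / (2 * h)
        err = np.max(np.abs(dl + arms))
        _require(
            err < 1e-4,
            f"{self.name}: mtu_length'(theta) != -moment_arm(theta) (max err {err:.2e} m)",
        )


@dataclass
class ExosuitGeometry:
    """Cable anchor points of the exosuit straps.

    One anchor pair is shared by both cables: the flexor cable runs on
    the anterior side as given, the extensor cable mirrors the anterior
    offsets to the posterior side.  Separate pairs may be supplied via
    ``extensor_arm_anchor``/``extensor_forearm_anchor``.
    """

    arm_anchor: tuple[float, float]
    forearm_anchor: tuple[float, float]
    extensor_arm_anchor: tuple[float, float] | None = None
    extensor_forearm_anchor: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.arm_anchor = tuple(float(c) for c in self.arm_anchor)
        self.forearm_anchor = tuple(float(c) for c in self.forearm_anchor)
        if self.extensor_arm_anchor is not None:
            self.extensor_arm_anchor = tuple(float(c) for c in self.extensor_arm_anchor)
        if self.extensor_forearm_anchor is not None:
            self.extensor_forearm_anchor = tuple(float(c) for c in self.extensor_forearm_anchor)

    @property
    def flexor_anchors(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return self.arm_anchor, self.forearm_anchor

    @property
    def extensor_anchors(self) -> tuple[tuple[float, float], tuple[float, float]]:
        arm = self.extensor_arm_anchor or (-self.arm_anchor[0], self.arm_anchor[1])
        fore = self.extensor_forearm_anchor or (-self.forearm_anchor[0], self.forearm_anchor[1])
        return arm, fore

    def validate(self) -> None:
        for label, (x, y) in (("arm_anchor", self.arm_anchor), ("forearm_anchor", self.forearm_anchor)):
            _require(math.hypot(x, y) > 1e-6, f"{label} coincides with the elbow origin")
        # moment arms of both cables must stay positive over the task range;
        # checked here with a local import to avoid a circular dependency.
        from . import exosuit

        thetas = np.linspace(0.0, math.pi / 2, 40)
        for th in thetas:
            geo = exosuit.cable_geometry(self, float(th))
            _require(
                geo.r_flexor > 0,
                f"flexor cable moment arm not positive at theta={th:.3f} ({geo.r_flexor:.4g})",
            )
            _require(
                geo.r_extensor > 0,
                f"extensor cable moment arm not positive at theta={th:.3f} ({geo.r_extensor:.4g})",
            )


@dataclass
class Gains:
    """PD feedback gains of the trajectory-tracking controller."""

    kp: float = 900.0  # 1/s^2
    kv: float = 60.0   # 1/s

    def validate(self) -> None:
        _require(self.kp > 0, f"kp must be > 0, got {self.kp}")
        _require(self.kv > 0, f"kv must be > 0, got {self.kv}")


@dataclass
class SimSettings:
    """Numerical settings of the closed-loop simulation."""

    sample_rate: float = 121.0
    integrator_max_step: float = 0.008
    integrator_min_step: float = 0.0
    optimizer_tolerance: float = 1e-6
    rng_seed: int = 0
    inertia_about: str = "elbow"  # 'elbow' (tabulated value as-is) or 'com' (adds m*lc^2)
    literal_dynamics_sign: bool = False

    def validate(self) -> None:
        _require(self.sample_rate > 0, f"sample_rate must be > 0, got {self.sample_rate}")
        _require(
            0 < self.integrator_max_step <= 0.02,
            f"integrator_max_step must lie in (0, 0.02] s, got {self.integrator_max_step}",
        )
        _require(
            0 <= self.integrator_min_step <= self.integrator_max_step,
            "integrator_min_step must lie in [0, integrator_max_step], "
            f"got {self.integrator_min_step}",
        )
        _require(
            self.optimizer_tolerance > 0,
            f"optimizer_tolerance must be > 0, got {self.optimizer_tolerance}",
        )
        _require(
            self.inertia_about in ("elbow", "com"),
            f"inertia_about must be 'elbow' or 'com', got {self.inertia_about!r}",
        )


@dataclass
class ArmModel:
    """The complete simulated world: arm, load, muscles, exosuit, gravity."""

    segment: SegmentParams
    load: LoadCase
    muscles: list[MuscleParams]
    exosuit: ExosuitGeometry
    gravity: float = 9.81
    gains: Gains = field(default_factory=Gains)
    settings: SimSettings = field(default_factory=SimSettings)

    def validate(self) -> None:
        self.segment.validate()
        self.load.validate()
        _require(
            len(self.muscles) == 6,
            f"expected 6 muscles, got {len(self.muscles)}",
        )
        for m in self.muscles:
            m.validate()
        names = [m.name for m in self.muscles]
        _require(len(set(names)) == 6, f"duplicate muscle names in {names}")
        n_flex = sum(1 for m in self.muscles if m.sign == 1)
        _require(
            n_flex == 3,
            f"expected 3 flexors and 3 extensors, got {n_flex} flexors",
        )
        self.exosuit.validate()
        _require(self.gravity >= 0, f"gravity must be >= 0, got {self.gravity}")
        self.gains.validate()
        self.settings.validate()

    @property
    def flexors(self) -> list[MuscleParams]:
        return [m for m in self.muscles if m.sign == 1]

    @property
    def extensors(self) -> list[MuscleParams]:
        return [m for m in self.muscles if m.sign == -1]

    def muscle(self, name: str) -> MuscleParams:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    def with_load(self, external_mass: float, load_distance: float | None = None) -> "ArmModel":
        """Return a copy with a different hand-held load."""
        import copy

        out = copy.deepcopy(self)
        out.load.external_mass = float(external_mass)
        if load_distance is not None:
            out.load.load_distance = float(load_distance)
        out.load.validate()
        return out


# ---------------------------------------------------------------------------
# configuration I/O

_TOP_KEYS = {"segment", "load", "exosuit", "gravity", "gains", "settings", "muscle_file", "muscles"}

_SCHEMA = {
    "segment": {"forearm_mass", "com_distance", "inertia_about_elbow", "upper_arm_orientation"},
    "load": {"external_mass", "load_distance"},
    "exosuit": {"arm_anchor", "forearm_anchor", "extensor_arm_anchor", "extensor_forearm_anchor"},
    "gains": {"kp", "kv"},
    "settings": {
        "sample_rate",
        "integrator_max_step",
        "integrator_min_step",
        "optimizer_tolerance",
        "rng_seed",
        "inertia_about",
        "literal_dynamics_sign",
    },
}

_MUSCLE_KEYS = {
    "name",
    "sign",
    "max_isometric_force",
    "optimal_fiber_length",
    "tendon_slack_length",
    "max_contraction_velocity",
    "pennation_at_optimal",
    "act_time_constant",
    "deact_time_constant",
    "moment_arm_coeffs",
    "mtu_length_coeffs",
    "origin",
    "insertion",
}


def _check_keys(section: str, data: dict, allowed: set, required: set | None = None) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    if required:
        missing = required - set(data)
        if missing:
            raise ConfigurationError(f"missing required field(s) in '{section}': {sorted(missing)}")


def _parse_muscles(entries: Sequence[dict]) -> list[MuscleParams]:
    muscles = []
    for entry in entries:
        if not isinstance(entry, dict):
            raise ConfigurationError(f"muscle entry is not a mapping: {entry!r}")
        _check_keys(
            f"muscle {entry.get('name', '?')}",
            entry,
            _MUSCLE_KEYS,
            _MUSCLE_KEYS - {"origin", "insertion"},
        )
        muscles.append(MuscleParams(**entry))
    return muscles


def _load_muscle_file(name_or_path: str, base: Path | None) -> list[MuscleParams]:
    path = Path(name_or_path)
    if not path.is_absolute():
        for root in ([base] if base else []) + [None]:
            if root is not None and (root / path).exists():
                path = root / path
                break
        else:
            # fall back to the packaged data directory
            ref = resources.files("elbowsim.data") / name_or_path
            with resources.as_file(ref) as p:
                if not p.exists():
                    raise ConfigurationError(f"muscle file not found: {name_or_path}")
                data = yaml.safe_load(p.read_text())
            return _parse_muscles(data["muscles"])
    if not path.exists():
        raise ConfigurationError(f"muscle file not found: {name_or_path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "muscles" not in data:
        raise ConfigurationError(f"muscle file {path} must contain a 'muscles' list")
    return _parse_muscles(data["muscles"])


def _model_from_dict(raw: dict, base: Path | None = None) -> ArmModel:
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    _check_keys("<root>", raw, _TOP_KEYS, {"segment", "load", "exosuit"})
    for sect in ("segment", "load", "exosuit", "gains", "settings"):
        if sect in raw:
            required = _SCHEMA[sect] if sect in ("segment", "load") else None
            if sect == "segment":
                required = _SCHEMA[sect] - {"upper_arm_orientation"}
            if sect == "exosuit":
                required = {"arm_anchor", "forearm_anchor"}
            _check_keys(sect, raw[sect], _SCHEMA[sect], required)

    if "muscles" in raw:
        muscles = _parse_muscles(raw["muscles"])
    else:
        muscles = _load_muscle_file(raw.get("muscle_file", "arm26_muscles.yaml"), base)

    model = ArmModel(
        segment=SegmentParams(**raw["segment"]),
        load=LoadCase(**raw["load"]),
        muscles=muscles,
        exosuit=ExosuitGeometry(**raw["exosuit"]),
        gravity=float(raw.get("gravity", 9.81)),
        gains=Gains(**raw.get("gains", {})),
        settings=SimSettings(**raw.get("settings", {})),
    )
    model.validate()
    return model


def load_model(config_path: str | Path) -> ArmModel:
    """Load and validate an :class:`ArmModel` from a YAML configuration.

    Raises :class:`ConfigurationError` for missing/unknown fields and
    :class:`ValidationError` when an invariant is violated.
    """
    path = Path(config_path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return _model_from_dict(raw, base=path.parent)


def write_config(model: ArmModel, path: str | Path) -> Path:
    """Serialise a model (muscles inlined) so it round-trips via YAML."""
    raw = {
        "segment": asdict(model.segment),
        "load": asdict(model.load),
        "exosuit": {
            k: list(v)
            for k, v in asdict(model.exosuit).items()
            if v is not None
        },
        "gravity": model.gravity,
        "gains": asdict(model.gains),
        "settings": asdict(model.settings),
        "muscles": [
            {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(m).items()
                }
            }
            for m in model.muscles
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(raw, sort_keys=False))
    return path


def default_muscle_fixture() -> list[MuscleParams]:
    """The packaged six-muscle elbow parameter set (arm26-patterned)."""
    return _load_muscle_file("arm26_muscles.yaml", base=None)


def default_model() -> ArmModel:
    """The packaged default model: 1.53 kg forearm, no hand load."""
    ref = resources.files("elbowsim.data") / "default_model.yaml"
    with resources.as_file(ref) as p:
        return load_model(p)
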