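"""Shared fixtures: the default model and the matched off/on run pairs.

Closed-loop runs are the expensive part (~0.5-1.5 s each), so the
conditions used by several test modules are simulated once per session.
"""

from __future__ import annotations

import pytest

import elbowsim as es
from elbowsim import pipeline as pl


@pytest.fixture(scope="session")
def model() -> es.ArmModel:
    return es.default_model()


def _pair(model: es.ArmModel, duration: float, load: float):
    m = model.with_load(load)
    traj = es.make_min_jerk(0.0, 1.57, duration, m.settings.sample_rate)
    off = pl.run(pl.RunSpec(model=m, trajectory=traj, assist=False, label="off"))
    on = pl.run(pl.RunSpec(model=m, trajectory=traj, assist=True, label="on"))
    return off, on


@pytest.fixture(scope="session")
def runs(model) -> dict[str, tuple]:
    """Matched (assist OFF, assist ON) result pairs keyed by condition."""
    return {
        "fast_0kg": _pair(model, 1.0, 0.0),
        "fast_5kg": _pair(model, 1.0, 5.0),
        "slow_2kg": _pair(model, 2.0, 2.0),
        "slow_5kg": _pair(model, 2.0, 5.0),
    }
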