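"""Muscle metabolic energetics: basal, heat, and mechanical work rates.

Whole-task metabolic power is bookkept as

    Edot = Bdot + (Adot + Mdot + Sdot + Wdot)

summed over the six modeled muscles, following the Umberger-family
muscle energetics model:

* basal rate ``Bdot = 1.2 W/kg`` of muscle mass;
* activation + maintenance heat ``(128 FT + 25) W/kg``, scaled by
  ``A^0.6`` where ``A`` is the excitation/activation drive
  (``A = u`` when ``u > a``, else ``(u + a)/2``), split 40 % activation
  / 60 % maintenance with the maintenance share scaled by the isometric
  force-length factor above optimal length;
* shortening heat proportional to normalized fiber velocity with
  slow/fast-twitch coefficients ``alpha_ST = 100 / vmax_ST`` and
  ``alpha_FT = 153 / vmax_FT`` (``vmax_ST = vmax / 2.5``), scaled by
  ``A^2``; lengthening heat ``0.3 alpha_ST`` scaled by ``A``;
* mechanical work rate ``Wdot = -F_fiber * v_fiber`` (positive while
  shortening), with absorbed (negative) work clamped to zero at the
  muscle level by default.

Muscle mass is reconstructed from strength as
``mass = rho * Fmax * lopt / sigma`` with muscle density
``rho = 1059.7 kg/m^3`` and specific tension ``sigma = 0.25 MPa``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import muscle as mm
from .model import ArmModel, MuscleParams

__all__ = ["MetabolicBreakdown", "muscle_mass", "metabolic_rate"]

MUSCLE_DENSITY = 1059.7     # kg/m^3
SPECIFIC_TENSION = 0.25e6   # Pa
BASAL_RATE = 1.2            # W per kg of muscle mass
FAST_TWITCH_FRACTION = 0.5  # default mixed fiber composition
LENGTHENING_COEFF = 0.3     # lengthening heat, fraction of alpha_ST


class InputError(ValueError):
    """Misaligned metabolic input series."""


@dataclass
class MetabolicBreakdown:
    """Per-sample metabolic power decomposition (W), totals over muscles."""

    times: np.ndarray
    basal_rate: np.ndarray
    activation_rate: np.ndarray
    maintenance_rate: np.ndarray
    shortening_rate: np.ndarray
    work_rate: np.ndarray
    per_muscle_total: np.ndarray  # (n_samples, n_muscles)

    @property
    def total_rate(self) -> np.ndarray:
        return (
            self.basal_rate
            + self.activation_rate
            + self.maintenance_rate
            + self.shortening_rate
            + self.work_rate
        )

    @property
    def rms_total(self) -> float:
        return float(np.sqrt(np.mean(self.total_rate**2)))

    def work_integral(self) -> float:
        """Task mechanical work (J) by trapezoidal quadrature."""
        return float(np.trapezoid(self.work_rate, self.times))


def muscle_mass(params: MuscleParams) -> float:
    """Muscle mass (kg) reconstructed from strength and optimal length."""
    return (
        MUSCLE_DENSITY
        * params.max_isometric_force
        * params.optimal_fiber_length
        / SPECIFIC_TENSION
    )


def _drive(u: np.ndarray, a: np.ndarray) -> np.ndarray:
    return np.where(u > a, u, 0.5 * (u + a))


def metabolic_rate(
    model: ArmModel,
    times: np.ndarray,
    excitations: np.ndarray,
    activations: np.ndarray,
    norm_fiber_lengths: np.ndarray,
    norm_fiber_velocities: np.ndarray,
    fiber_forces: np.ndarray,
    fast_twitch_fraction: float = FAST_TWITCH_FRACTION,
    allow_negative_work: bool = False,
) -> MetabolicBreakdown:
    """Per-sample metabolic power for aligned (n_samples, 6) input series.

    ``fiber_forces`` are forces along the fiber (N);
    ``norm_fiber_velocities`` are normalised by ``vmax * lopt``
    (shortening negative).
    """
    times = np.asarray(times, float)
    series = {
        "excitations": np.asarray(excitations, float),
        "activations": np.asarray(activations, float),
        "norm_fiber_lengths": np.asarray(norm_fiber_lengths, float),
        "norm_fiber_velocities": np.asarray(norm_fiber_velocities, float),
        "fiber_forces": np.asarray(fiber_forces, float),
    }
    n = len(times)
    for name, arr in series.items():
        if arr.shape != (n, 6):
            raise InputError(
                f"{name} must have shape ({n}, 6) aligned with times, got {arr.shape}"
            )

    ft = fast_twitch_fraction
    u, a = series["excitations"], series["activations"]
    lnorm = series["norm_fiber_lengths"]
    vnorm = series["norm_fiber_velocities"]
    ffib = series["fiber_forces"]

    masses = np.array([muscle_mass(m) for m in model.muscles])
    vmaxes = np.array([m.max_contraction_velocity for m in model.muscles])
    lopts = np.array([m.optimal_fiber_length for m in model.muscles])

    drive = _drive(u, a)
    d_am = drive**0.6
    fiso = mm.active_force_length(lnorm)
    above = lnorm > 1.0

    h_am = (128.0 * ft + 25.0) * d_am                  # W/kg
    act = 0.4 * h_am
    maint = 0.6 * h_am * np.where(above, fiso, 1.0)

    # shortening / lengthening heat; fiber velocity in lopt/s
    v_lopt = vnorm * vmaxes
    alpha_st = 100.0 / (vmaxes / 2.5)                  # W/kg per (lopt/s)
    alpha_ft = 153.0 / vmaxes
    alpha_mix = alpha_st * (1.0 - ft) + alpha_ft * ft
    h_short = np.where(
        v_lopt < 0.0,
        -v_lopt * alpha_mix * drive**2 * np.where(above, fiso, 1.0),
        v_lopt * LENGTHENING_COEFF * alpha_st * drive,
    )

    # mechanical work rate: positive while shortening
    v_fiber = vnorm * vmaxes * lopts                   # m/s
    wdot = -ffib * v_fiber
    if not allow_negative_work:
        wdot = np.maximum(wdot, 0.0)

    basal_per = BASAL_RATE * masses                    # W, constant
    act_w = act * masses
    maint_w = maint * masses
    short_w = h_short * masses
    per_muscle = basal_per[None, :] + act_w + maint_w + short_w + wdot

    return MetabolicBreakdown(
        times=times,
        basal_rate=np.full(n, basal_per.sum()),
        activation_rate=act_w.sum(axis=1),
        maintenance_rate=maint_w.sum(axis=1),
        shortening_rate=short_w.sum(axis=1),
        work_rate=wdot.sum(axis=1),
        per_muscle_total=per_muscle,
    )
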