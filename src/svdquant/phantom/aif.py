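"""Synthetic arterial input function for the DCE phantom.

The whole-blood gadolinium curve after a bolus is modelled as a
bi-exponential wash-in/wash-out

    C_wb(t) = A * (exp(-m1 t) - exp(-m2 t)),   m2 > m1 > 0,

which is zero at t=0, rises to a bolus peak and decays.  The plasma curve
is the whole-blood curve divided by (1 - Hct).  The amplitude A is scaled
so the *plasma* peak is proportional to the injected dose.  The form was
chosen for analytic integrability: the running integral needed by Patlak
analysis has a closed form, used by oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BiexpAIF", "simulate_aif"]

# plasma peak per unit dose: 0.025 mmol/kg -> ~0.5 mM peak plasma Gd
PEAK_PLASMA_MM_PER_DOSE = 20.0
DEFAULT_M1_PER_MIN = 0.08
DEFAULT_M2_PER_MIN = 1.5


@dataclass(frozen=True)
class BiexpAIF:
    """Closed-form bi-exponential bolus, times in minutes."""

    amplitude_mM: float
    m1_per_min: float
    m2_per_min: float
    hct: float

    def whole_blood(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return self.amplitude_mM * (np.exp(-self.m1_per_min * t) - np.exp(-self.m2_per_min * t))

    def plasma(self, t_min: np.ndarray) -> np.ndarray:
        return self.whole_blood(t_min) / (1.0 - self.hct)

    def plasma_integral(self, t_min: np.ndarray) -> np.ndarray:
        """Exact running integral of the plasma curve (mM*min)."""
        t = np.asarray(t_min, dtype=float)
        m1, m2 = self.m1_per_min, self.m2_per_min
        raw = (1 - np.exp(-m1 * t)) / m1 - (1 - np.exp(-m2 * t)) / m2
        return self.amplitude_mM * raw / (1.0 - self.hct)


def simulate_aif(
    times_min: np.ndarray,
    dose_mmol_per_kg: float = 0.025,
    hct: float = 0.45,
    m1_per_min: float = DEFAULT_M1_PER_MIN,
    m2_per_min: float = DEFAULT_M2_PER_MIN,
) -> tuple[np.ndarray, np.ndarray, BiexpAIF]:
    """Sample whole-blood and plasma concentration curves (mM).

    Returns ``(whole_blood, plasma, model)`` where ``model`` is the
    closed-form :class:`BiexpAIF` the samples came from.
    """
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not 0.0 < hct < 1.0:
        raise ValueError("hct must lie in (0, 1)")
    if not 0 < m1_per_min < m2_per_min:
        raise ValueError("require 0 < m1 < m2")

    # amplitude scaled so the plasma peak equals PEAK * dose
    t_peak = np.log(m2_per_min / m1_per_min) / (m2_per_min - m1_per_min)
    unit = np.exp(-m1_per_min * t_peak) - np.exp(-m2_per_min * t_peak)
    peak_plasma = PEAK_PLASMA_MM_PER_DOSE * dose_mmol_per_kg
    amplitude = peak_plasma * (1.0 - hct) / unit

    model = BiexpAIF(amplitude, m1_per_min, m2_per_min, hct)
    return model.whole_blood(t), model.plasma(t), model
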