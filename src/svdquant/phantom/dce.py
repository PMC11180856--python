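"""Forward simulation of a dynamic contrast-enhanced T1-mapping study.

For each post-contrast cycle the simulator computes tissue gadolinium
concentration from the Patlak forward model

    C_t(t) = Ki * integral_0^t C_p dtau + v_p * C_p(t),

shortens T1 according to 1/T1(t) = 1/T1(0) + r1 * C_t(t), and evaluates
the SPGR signal equation at each flip angle.  The plasma integral is
computed by trapezoid on the cycle sampling grid -- the same quadrature the
Patlak fit uses -- so the noise-free simulation is an exact fixed point of
the quantification chain.  Superior-sagittal-sinus voxels carry the
whole-blood concentration instead of the tissue model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dce_patlak import DEFAULT_R1_RELAXIVITY
from ..t1_mapping import spgr_signal
from .aif import BiexpAIF, simulate_aif
from .masks import LabelVolume, Labels
from .spec import PhantomSpec

__all__ = ["DCEStudy", "simulate_dce_study", "DEFAULT_FLIP_ANGLES_DEG",
           "DEFAULT_TR_MS", "DEFAULT_CYCLE_S", "N_POST_CYCLES"]

DEFAULT_FLIP_ANGLES_DEG = np.array([2.0, 5.0, 10.0, 15.0, 20.0, 25.0])
DEFAULT_TR_MS = 5.0
DEFAULT_CYCLE_S = 60.0
N_POST_CYCLES = 8


@dataclass(frozen=True)
class DCEStudy:
    """One simulated DCE acquisition: 1 pre- + 8 post-contrast cycles."""

    signals: np.ndarray            # (n_cycles=9, n_angles) + grid
    flip_angles_deg: np.ndarray
    tr_ms: float
    cycle_times_min: np.ndarray    # post-contrast cycle times (8,)
    aif_model: BiexpAIF
    truth_ki: np.ndarray
    truth_vp: np.ndarray
    truth_t1_ms: np.ndarray


def simulate_dce_study(
    masks: LabelVolume,
    truth_ki: np.ndarray,
    truth_vp: np.ndarray,
    truth_t1_ms: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    flip_angles_deg: np.ndarray = DEFAULT_FLIP_ANGLES_DEG,
    tr_ms: float = DEFAULT_TR_MS,
    cycle_s: float = DEFAULT_CYCLE_S,
) -> DCEStudy:
    """Simulate the nine-cycle multi-flip-angle SPGR acquisition."""
    if np.any(truth_t1_ms[masks.labels > 0] <= 0):
        raise ValueError("truth T1 must be positive inside the head")
    grid = masks.shape
    times_min = (np.arange(1, N_POST_CYCLES + 1) * cycle_s) / 60.0
    all_times = np.concatenate([[0.0], times_min])

    wb, cp, model = simulate_aif(all_times, spec.dose_mmol_per_kg, spec.hct)
    # plasma integral by trapezoid on the sampling grid (matches the fit)
    cp_int = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * np.diff(all_times))])

    sss = masks.mask(Labels.SSS)
    conc = (truth_ki[None] * cp_int[1:, None, None, None]
            + truth_vp[None] * cp[1:, None, None, None])      # (8,)+grid
    conc[:, sss] = wb[1:, None]                                # blood ROI

    t1_safe = np.where(truth_t1_ms > 0, truth_t1_ms, 1.0)
    r1 = DEFAULT_R1_RELAXIVITY
    inv_t1 = 1000.0 / t1_safe                                  # 1/s
    t1_cycles = 1000.0 / (inv_t1[None] + r1 * conc)            # ms

    n_angles = flip_angles_deg.size
    signals = np.zeros((N_POST_CYCLES + 1, n_angles) + grid)
    head = masks.labels > 0
    for j, alpha in enumerate(flip_angles_deg):
        base = spgr_signal(1.0, t1_safe, alpha, tr_ms)
        signals[0, j][head] = base[head]
        for c in range(N_POST_CYCLES):
            s = spgr_signal(1.0, t1_cycles[c], alpha, tr_ms)
            signals[c + 1, j][head] = s[head]

    if spec.noise_sd_dce > 0:
        baseline_level = float(np.mean(signals[0][:, head]))
        signals = signals + rng.normal(
            0.0, spec.noise_sd_dce * baseline_level, size=signals.shape)

    return DCEStudy(signals=signals, flip_angles_deg=np.asarray(flip_angles_deg, float),
                    tr_ms=float(tr_ms), cycle_times_min=times_min, aif_model=model,
                    truth_ki=truth_ki, truth_vp=truth_vp, truth_t1_ms=truth_t1_ms)
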