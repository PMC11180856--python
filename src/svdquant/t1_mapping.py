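"""Variable-flip-angle T1 mapping from spoiled gradient-echo signals.

The steady-state SPGR signal at flip angle alpha and repetition time TR is

    S = M0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),  E1 = exp(-TR/T1).

Acquiring the same volume at several flip angles lets T1 and M0 be
estimated voxelwise.  The default estimator is the DESPOT1 linearisation

    S/sin(alpha) = E1 * (S/tan(alpha)) + M0 * (1 - E1),

an ordinary least-squares line whose slope is E1; ``T1 = -TR / ln(slope)``.
Voxels whose slope falls outside (0, 1) have no physical T1 and are flagged
invalid (with a reason code) rather than silently zeroed.  An optional
nonlinear refinement polishes the linearised estimates by Levenberg-
Marquardt on the full signal equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["spgr_signal", "VFAT1", "T1Results", "fit_vfa_t1"]

REASON_OK = 0
REASON_ZERO_SIGNAL = 1
REASON_SLOPE_RANGE = 2


def spgr_signal(m0, t1_ms, alpha_deg, tr_ms):
    """Forward SPGR signal equation; broadcasts over array inputs."""
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    e1 = np.exp(-tr_ms / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


@dataclass(frozen=True)
class T1Results:
    """Fitted T1/M0 maps with per-voxel validity flags.

    ``t1_ms`` and ``m0`` are NaN where ``valid`` is False; ``reason`` holds
    a small integer code (0 ok, 1 all-zero signal, 2 slope outside (0,1)).
    """

    t1_ms: np.ndarray
    m0: np.ndarray
    r2_fit: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    flip_angles_deg: np.ndarray
    tr_ms: float

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def summary(self) -> str:
        v = self.t1_ms[self.valid]
        lines = [
            "VFA T1 fit",
            f"  voxels fitted : {self.valid.size}",
            f"  valid         : {self.n_valid}",
            f"  T1 median (ms): {np.median(v):.1f}" if v.size else "  T1 median (ms): n/a",
            f"  flip angles   : {np.array2string(self.flip_angles_deg)}",
            f"  TR (ms)       : {self.tr_ms}",
        ]
        return "\n".join(lines)


class VFAT1:
    """Voxelwise variable-flip-angle T1 model.

    Parameters
    ----------
    signals : (..., n_angles) array
        SPGR magnitude signal per voxel per flip angle.
    flip_angles_deg : (n_angles,) array
        At least two distinct angles in (0, 90].
    tr_ms : float
        Repetition time, > 0.
    """

    def __init__(self, signals, flip_angles_deg, tr_ms: float):
        signals = np.asarray(signals, dtype=float)
        angles = np.asarray(flip_angles_deg, dtype=float)
        if angles.ndim != 1 or signals.shape[-1] != angles.size:
            raise ValueError("last axis of signals must match flip_angles_deg")
        if np.unique(angles).size < 2:
            raise ValueError("need at least two distinct flip angles")
        if np.any(angles <= 0) or np.any(angles > 90):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if tr_ms <= 0:
            raise ValueError("TR must be positive")
        self.signals = signals
        self.flip_angles_deg = angles
        self.tr_ms = float(tr_ms)

    def fit(self, refine: bool = False) -> T1Results:
        """DESPOT1 linearised fit; ``refine=True`` adds nonlinear polish."""
        sig = self.signals.reshape(-1, self.flip_angles_deg.size)
        a = np.deg2rad(self.flip_angles_deg)
        y = sig / np.sin(a)
        x = sig / np.tan(a)

        n = self.flip_angles_deg.size
        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        sxx = ((x - xm) ** 2).sum(axis=1)
        sxy = ((x - xm) * (y - ym)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = sxy / sxx
            intercept = ym[:, 0] - slope * xm[:, 0]

        zero_sig = np.all(sig == 0, axis=1)
        bad_slope = ~zero_sig & ~((slope > 0) & (slope < 1))
        valid = ~(zero_sig | bad_slope)

        reason = np.full(sig.shape[0], REASON_OK, dtype=np.int8)
        reason[zero_sig] = REASON_ZERO_SIGNAL
        reason[bad_slope] = REASON_SLOPE_RANGE

        t1 = np.full(sig.shape[0], np.nan)
        m0 = np.full(sig.shape[0], np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            t1[valid] = -self.tr_ms / np.log(slope[valid])
            m0[valid] = intercept[valid] / (1.0 - slope[valid])

        # goodness of fit of the linearised regression
        ss_res = ((y - (slope[:, None] * x + intercept[:, None])) ** 2).sum(axis=1)
        ss_tot = ((y - ym) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
        r2[~valid] = np.nan

        if refine:
            idx = np.flatnonzero(valid)
            for i in idx:
                res = least_squares(
                    lambda p, s=sig[i]: spgr_signal(p[0], p[1], self.flip_angles_deg, self.tr_ms) - s,
                    x0=[m0[i], t1[i]],
                    bounds=([0, 1e-3], [np.inf, np.inf]),
                )
                m0[i], t1[i] = res.x

        shape = self.signals.shape[:-1]
        return T1Results(
            t1_ms=t1.reshape(shape),
            m0=m0.reshape(shape),
            r2_fit=r2.reshape(shape),
            valid=valid.reshape(shape),
            reason=reason.reshape(shape),
            flip_angles_deg=self.flip_angles_deg,
            tr_ms=self.tr_ms,
        )


def fit_vfa_t1(signals, flip_angles_deg, tr_ms, refine: bool = False) -> T1Results:
    """Functional wrapper around :class:`VFAT1`."""
    return VFAT1(signals, flip_angles_deg, tr_ms).fit(refine=refine)
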