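"""Patlak blood-brain-barrier permeability mapping from serial T1 maps.

Serial quantitative T1 maps acquired during a gadolinium injection are
converted to tissue concentration via the linear relaxivity relation

    C_t(t) = (1/T1(t) - 1/T1(0)) / r1        (T1 in seconds),

an arterial input function is read from a superior-sagittal-sinus ROI and
corrected to plasma by the factor 1/(1 - Hct), and the voxelwise influx
rate Ki is the slope of the Patlak plot

    C_t(t)/C_p(t)  vs.  (integral_0^t C_p dtau) / C_p(t),

fitted by ordinary least squares; the intercept is the plasma /
distribution-volume term v_p.  Under the unit tissue-density convention
(1 g/mL) a slope in 1/min is reported as mL/g/min.  Negative Ki values are
retained: in near-intact white matter the true influx is close to zero and
noise drives estimates on both sides of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AIF",
    "concentration_from_t1",
    "extract_aif",
    "Patlak",
    "PatlakResults",
    "patlak_fit",
    "ki_map",
    "KiMap",
]

DEFAULT_R1_RELAXIVITY = 3.5  # 1/s/mM, gadoterate at 3T


@dataclass(frozen=True)
class AIF:
    """Plasma input function with provenance."""

    times_min: np.ndarray
    plasma_conc_mM: np.ndarray
    source: str = "synthetic"
    hct_used: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.plasma_conc_mM, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("AIF times must be strictly increasing")
        if np.any(c < -1e-12):
            raise ValueError("plasma concentration must be non-negative")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "plasma_conc_mM", c)


def concentration_from_t1(t1_t_ms, t1_0_ms, r1_per_s_per_mM: float = DEFAULT_R1_RELAXIVITY):
    """Gadolinium concentration (mM) from post- and pre-contrast T1 (ms)."""
    t1_t = np.asarray(t1_t_ms, dtype=float)
    t1_0 = np.asarray(t1_0_ms, dtype=float)
    if np.any(t1_t <= 0) or np.any(t1_0 <= 0):
        raise ValueError("T1 values must be positive")
    if r1_per_s_per_mM <= 0:
        raise ValueError("relaxivity must be positive")
    return (1000.0 / t1_t - 1000.0 / t1_0) / r1_per_s_per_mM


def extract_aif(times_min, sss_conc_mM, hct: float, source: str = "sss-derived") -> AIF:
    """Plasma AIF from a superior-sagittal-sinus concentration curve.

    ``sss_conc_mM`` may be (n_times,) for a pre-averaged curve or
    (n_voxels, n_times); ROI voxels are averaged BEFORE the (1-Hct)
    correction.
    """
    if not 0.0 < hct < 1.0:
        raise ValueError("hct must lie in (0, 1)")
    conc = np.atleast_2d(np.asarray(sss_conc_mM, dtype=float))
    if conc.shape[0] == 0:
        raise ValueError("empty SSS ROI")
    mean_curve = conc.mean(axis=0)
    plasma = np.clip(mean_curve, 0.0, None) / (1.0 - hct)
    return AIF(times_min=np.asarray(times_min, float), plasma_conc_mM=plasma,
               source=source, hct_used=hct)


@dataclass(frozen=True)
class PatlakResults:
    """Patlak fit: influx rate, intercept and fit quality (arrays for maps)."""

    ki_ml_per_g_min: np.ndarray | float
    vp: np.ndarray | float
    r2: np.ndarray | float
    n_points_used: int
    window_start_min: float

    def summary(self) -> str:
        ki = np.atleast_1d(self.ki_ml_per_g_min)
        vp = np.atleast_1d(self.vp)
        return "\n".join([
            "Patlak graphical analysis",
            f"  points used     : {self.n_points_used}",
            f"  window start    : {self.window_start_min} min",
            f"  Ki  (mL/g/min)  : mean {np.nanmean(ki):.3e}",
            f"  v_p             : mean {np.nanmean(vp):.3e}",
        ])


class Patlak:
    """Patlak graphical model for one or many tissue curves.

    Parameters
    ----------
    times_min : (n_t,) sample times
    ct_mM : (n_t,) or (n_voxels, n_t) tissue concentration
    aif : :class:`AIF` sampled on the same time grid
    """

    def __init__(self, times_min, ct_mM, aif: AIF):
        t = np.asarray(times_min, dtype=float)
        ct = np.asarray(ct_mM, dtype=float)
        if not np.array_equal(t, aif.times_min):
            raise ValueError("tissue and AIF time grids differ")
        if ct.shape[-1] != t.size:
            raise ValueError("last axis of ct must match times")
        self.times_min = t
        self.ct = np.atleast_2d(ct)
        self._scalar = ct.ndim == 1
        self.aif = aif

    def fit(self, window_start_min: float = 0.0) -> PatlakResults:
        cp = self.aif.plasma_conc_mM
        # running plasma integral by trapezoid, same rule as the simulator
        integ = np.concatenate([[0.0], np.cumsum(
            0.5 * (cp[1:] + cp[:-1]) * np.diff(self.times_min))])
        use = (self.times_min >= window_start_min) & (cp > 0)
        if use.sum() < 2:
            raise ValueError("fewer than 2 usable Patlak points "
                             "(need C_p > 0 at >= 2 times in the window)")
        x = integ[use] / cp[use]
        y = self.ct[:, use] / cp[use]

        xm = x.mean()
        sxx = ((x - xm) ** 2).sum()
        ym = y.mean(axis=1)
        sxy = ((x - xm) * (y - ym[:, None])).sum(axis=1)
        slope = sxy / sxx
        intercept = ym - slope * xm
        resid = y - (slope[:, None] * x + intercept[:, None])
        ss_tot = ((y - ym[:, None]) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - (resid**2).sum(axis=1) / ss_tot, 1.0)

        if self._scalar:
            slope, intercept, r2 = float(slope[0]), float(intercept[0]), float(r2[0])
        return PatlakResults(ki_ml_per_g_min=slope, vp=intercept, r2=r2,
                             n_points_used=int(use.sum()),
                             window_start_min=float(window_start_min))


def patlak_fit(times_min, ct_mM, aif: AIF, window_start_min: float = 0.0) -> PatlakResults:
    """Functional wrapper around :class:`Patlak`."""
    return Patlak(times_min, ct_mM, aif).fit(window_start_min)


@dataclass(frozen=True)
class KiMap:
    """Voxelwise Patlak results rasterised back onto the volume grid."""

    ki: np.ndarray
    vp: np.ndarray
    r2: np.ndarray
    valid: np.ndarray

    def values_in(self, mask: np.ndarray) -> np.ndarray:
        return self.ki[mask & self.valid]


def ki_map(
    t1_cycles_ms: np.ndarray,
    t1_baseline_ms: np.ndarray,
    cycle_times_min: np.ndarray,
    aif: AIF,
    mask: np.ndarray,
    baseline_valid: np.ndarray | None = None,
    cycles_valid: np.ndarray | None = None,
    r1_per_s_per_mM: float = DEFAULT_R1_RELAXIVITY,
    window_start_min: float = 0.0,
) -> KiMap:
    """Voxelwise Ki/vp map from serial T1 maps within a mask.

    ``t1_cycles_ms`` has shape ``(n_cycles,) + grid`` for the post-contrast
    cycles; the AIF must be sampled at ``[0] + cycle_times``.  Voxels whose
    T1 fit was invalid at baseline or in any cycle propagate as missing.
    """
    t1_cycles_ms = np.asarray(t1_cycles_ms, dtype=float)
    n_cycles = t1_cycles_ms.shape[0]
    if n_cycles < 3:
        raise ValueError("need at least 3 post-contrast cycles")
    if mask.shape != t1_baseline_ms.shape:
        raise ValueError("mask/volume shape mismatch")

    valid = mask.copy()
    if baseline_valid is not None:
        valid &= baseline_valid
    if cycles_valid is not None:
        valid &= np.all(cycles_valid, axis=0)
    valid &= t1_baseline_ms > 0
    valid &= np.all(t1_cycles_ms > 0, axis=0)

    idx = np.flatnonzero(valid.ravel())
    grid = t1_baseline_ms.shape
    ki = np.full(grid, np.nan)
    vp = np.full(grid, np.nan)
    r2 = np.full(grid, np.nan)
    if idx.size:
        t1c = t1_cycles_ms.reshape(n_cycles, -1)[:, idx].T          # (n_vox, n_cycles)
        t10 = t1_baseline_ms.ravel()[idx]
        conc = concentration_from_t1(t1c, t10[:, None], r1_per_s_per_mM)
        # prepend the zero-concentration baseline sample at t=0
        times = np.concatenate([[0.0], np.asarray(cycle_times_min, float)])
        ct = np.concatenate([np.zeros((idx.size, 1)), conc], axis=1)
        res = Patlak(times, ct, aif).fit(window_start_min)
        ki.ravel()[idx] = res.ki_ml_per_g_min
        vp.ravel()[idx] = res.vp
        r2.ravel()[idx] = res.r2
    return KiMap(ki=ki, vp=vp, r2=r2, valid=valid)
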