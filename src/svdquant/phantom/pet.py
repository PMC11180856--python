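"""Forward simulation of a dynamic TSPO PET study.

Voxel time-activity curves follow the simplified reference tissue model
with a vascular term,

    C_vox(t) = (1 - v_b) * SRTM(R1, k2, BP_ND; C_R)(t) + v_b * C_wb(t),

where the reference curve C_R is the white-matter class curve and C_wb the
blood class curve of a healthy-control kinetic class library.  The library
also carries pooled control-cohort voxel samples of Ki and BP_ND that
calibrate the 95th-percentile hotspot thresholds downstream.

Frame-level Gaussian noise is added with a standard deviation proportional
to the peak activity and inversely proportional to the square root of the
frame duration, mimicking count statistics across an unequal frame
schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..pet_kinetics import (_expconv_piecewise_linear, _fine_times_min,
                            _frame_average, _interp_frames_to_fine,
                            convolve_with_exp)
from ..schedules import FrameSchedule
from .masks import LabelVolume, Labels
from .spec import PhantomSpec

__all__ = ["ClassLibrary", "make_class_library", "DynamicPET",
           "simulate_pet_study", "srtm_forward_many"]

CLASS_NAMES = ("gray", "white", "blood", "high-binding")
# (K1-like scale, efflux 1/min) per tissue class
CLASS_KINETICS = {"gray": (0.45, 0.12), "white": (0.30, 0.15),
                  "high-binding": (0.35, 0.03)}
PEAK_KBQ_PER_ML_PER_MBQ = 0.2
BLOOD_M1_PER_MIN = 0.12
BLOOD_M2_PER_MIN = 3.0


@dataclass(frozen=True)
class ClassLibrary:
    """Healthy-control kinetic class curves plus control voxel samples."""

    class_names: tuple[str, ...]
    class_tacs: np.ndarray            # (n_class, n_frames)
    schedule: FrameSchedule
    control_ki_values: np.ndarray
    control_bp_values: np.ndarray

    def __post_init__(self):
        tacs = np.asarray(self.class_tacs, float)
        if np.any(tacs < -1e-9):
            raise ValueError("class TACs must be non-negative")
        if np.linalg.matrix_rank(tacs) < tacs.shape[0]:
            raise ValueError("class TACs must be linearly independent")
        if self.control_ki_values.size == 0 or self.control_bp_values.size == 0:
            raise ValueError("control samples must be non-empty")

    @property
    def blood(self) -> np.ndarray:
        return self.class_tacs[list(self.class_names).index("blood")]

    @property
    def white(self) -> np.ndarray:
        return self.class_tacs[list(self.class_names).index("white")]


def make_class_library(spec: PhantomSpec, schedule: FrameSchedule,
                       rng: np.random.Generator,
                       n_control: int = 20000) -> ClassLibrary:
    """Build the control class library implied by a phantom spec.

    The blood curve is a bi-exponential bolus scaled to the injected
    activity; tissue class curves are exponential-washout responses to it.
    Control Ki / BP_ND voxel samples are drawn from the same Gaussian null
    the phantom assigns to patient NAWM, making them exchangeable with
    patient null voxels (the property the percentile threshold relies on).
    """
    t = schedule.mid_min
    peak = PEAK_KBQ_PER_ML_PER_MBQ * spec.injected_activity_MBq
    m1, m2 = BLOOD_M1_PER_MIN, BLOOD_M2_PER_MIN
    t_pk = np.log(m2 / m1) / (m2 - m1)
    unit = np.exp(-m1 * t_pk) - np.exp(-m2 * t_pk)
    blood = peak / unit * (np.exp(-m1 * t) - np.exp(-m2 * t))

    curves = {"blood": blood}
    for name, (k1, k2) in CLASS_KINETICS.items():
        curves[name] = k1 * convolve_with_exp(blood, k2, schedule)
    tacs = np.stack([curves[n] for n in CLASS_NAMES])

    ki = rng.normal(spec.truth_Ki_nawm, spec.truth_Ki_sd_nawm, size=n_control)
    bp = rng.normal(spec.truth_BP_nawm, spec.truth_BP_sd_nawm, size=n_control)
    return ClassLibrary(class_names=CLASS_NAMES, class_tacs=tacs,
                        schedule=schedule, control_ki_values=ki,
                        control_bp_values=bp)


@dataclass(frozen=True)
class DynamicPET:
    """4-D dynamic PET volume plus its frame schedule."""

    tacs: np.ndarray                  # (n_frames,) + grid, kBq/mL
    schedule: FrameSchedule
    decay_corrected: bool = True

    def __post_init__(self):
        if self.tacs.shape[0] != self.schedule.n_frames:
            raise ValueError("frame count does not match schedule")


def srtm_forward_many(r1, k2, bp_nd, ref: np.ndarray, schedule: FrameSchedule,
                      dt_s: float = 1.0, chunk: int = 512) -> np.ndarray:
    """Vectorised SRTM forward model for per-voxel parameter vectors.

    Exploits the uniform fine grid: the exponential-convolution recursion
    coefficients are constant per voxel, so the time loop is vectorised
    across voxels.  Returns (n_vox, n_frames).
    """
    r1 = np.atleast_1d(np.asarray(r1, float))
    k2 = np.broadcast_to(np.asarray(k2, float), r1.shape).copy()
    bp = np.broadcast_to(np.asarray(bp_nd, float), r1.shape).copy()
    if np.any(bp <= -1):
        raise ValueError("bp_nd must exceed -1")
    k2a = k2 / (1.0 + bp)

    t_fine = _fine_times_min(schedule, dt_s)
    f = _interp_frames_to_fine(np.asarray(ref, float), schedule, t_fine)
    dt = t_fine[1] - t_fine[0]
    df = np.diff(f)
    out = np.empty((r1.size, schedule.n_frames))
    for lo in range(0, r1.size, chunk):
        sl = slice(lo, min(lo + chunk, r1.size))
        lam = k2a[sl]
        a = np.exp(-lam * dt)
        w0 = (1.0 - a) / lam
        w1 = (1.0 - w0 / dt) / lam
        conv = np.zeros((lam.size, t_fine.size))
        for i in range(t_fine.size - 1):
            conv[:, i + 1] = conv[:, i] * a + f[i] * w0 + df[i] * w1
        conv_frames = np.stack(
            [_frame_average(c, t_fine, schedule) for c in conv])
        out[sl] = (r1[sl, None] * np.asarray(ref, float)[None, :]
                   + ((k2[sl] - r1[sl] * lam)[:, None]) * conv_frames)
    return out


def simulate_pet_study(masks: LabelVolume, truth_r1: np.ndarray,
                       truth_k2: np.ndarray, truth_bp: np.ndarray,
                       truth_vb: np.ndarray, library: ClassLibrary,
                       schedule: FrameSchedule, spec: PhantomSpec,
                       rng: np.random.Generator) -> DynamicPET:
    """Simulate the dynamic PET volume for a phantom subject."""
    if np.any(truth_bp[masks.labels > 0] <= -1):
        raise ValueError("bp_nd must exceed -1 (implies negative efflux)")
    grid = masks.shape
    n_f = schedule.n_frames
    tacs = np.zeros((n_f,) + grid)

    head = masks.labels > 0
    gm = masks.labels == Labels.GM
    wmlike = head & ~gm
    idx = np.flatnonzero(wmlike.ravel())
    tissue = srtm_forward_many(truth_r1.ravel()[idx], truth_k2.ravel()[idx],
                               truth_bp.ravel()[idx], library.white, schedule)
    vb = np.clip(truth_vb.ravel()[idx], 0.0, 1.0)
    vox = (1.0 - vb)[:, None] * tissue + vb[:, None] * library.blood[None, :]
    tacs.reshape(n_f, -1)[:, idx] = vox.T

    # gray matter follows the gray kinetic class (distinct delivery/efflux),
    # with per-voxel scale spread and the same vascular admixture
    idx_gm = np.flatnonzero(gm.ravel())
    if idx_gm.size:
        gray = library.class_tacs[list(library.class_names).index("gray")]
        scale = rng.lognormal(0.0, 0.1, size=idx_gm.size)
        vb_g = np.clip(truth_vb.ravel()[idx_gm], 0.0, 1.0)
        vox_g = ((1.0 - vb_g) * scale)[:, None] * gray[None, :] \
            + vb_g[:, None] * library.blood[None, :]
        tacs.reshape(n_f, -1)[:, idx_gm] = vox_g.T

    if spec.noise_sd_pet > 0:
        peak = float(np.max(vox)) if idx.size else 1.0
        dur = schedule.duration_s
        sd = spec.noise_sd_pet * peak * np.sqrt(dur.mean() / dur)
        noise = rng.normal(0.0, 1.0, size=tacs.shape) * sd[:, None, None, None]
        noise[:, ~head] = 0.0
        tacs = tacs + noise

    return DynamicPET(tacs=tacs, schedule=schedule, decay_corrected=True)
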