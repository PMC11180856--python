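"""TSPO PET kinetics: basis-function SRTM with vascular correction.

The simplified reference tissue model (SRTM) describes a target-tissue
time-activity curve C_T(t) in terms of a reference-region curve C_R(t)
through three parameters -- delivery ratio R1, efflux rate k2 (1/min) and
non-displaceable binding potential BP_ND:

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * [C_R (x) exp(-k2a t)],
    k2a = k2 / (1 + BP_ND),

where (x) denotes convolution.  The basis-function implementation scans a
log-spaced grid of k2a values (theta3); for each, the convolution basis
B(t) = C_R (x) exp(-theta3 t) makes the model linear in (theta1, theta2) =
(R1, k2 - R1*k2a), solved by least squares, and the grid point with the
smallest residual sum of squares wins (ties to the smallest theta3).

Vascular correction adds a whole-blood term: the fitted curve is
(1 - v_b) * SRTM + v_b * C_wb with the blood fraction v_b box-constrained
to [0, 1].  Because no arterial samples exist, C_wb comes from the blood
class of the healthy-control kinetic class library.

The pseudo-reference region itself is extracted by supervised cluster
analysis: each voxel's unit-area-normalised curve is decomposed by
non-negative least squares onto normalised healthy-tissue class curves
(gray, white, blood, high-binding); voxels dominated by the white class
form the reference set.

BP_ND may legitimately be negative in white matter (reference-region bias);
estimates are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .schedules import FrameSchedule

__all__ = [
    "default_theta3_grid",
    "convolve_with_exp",
    "srtm_forward",
    "ReferenceCurve",
    "svca_reference",
    "SRTM",
    "SRTMResults",
    "srtm_basis_fit",
    "bp_map",
    "BPMap",
]

THETA3_MIN_PER_MIN = 0.006
THETA3_MAX_PER_MIN = 0.6
THETA3_N = 100


def default_theta3_grid(n: int = THETA3_N,
                        lo: float = THETA3_MIN_PER_MIN,
                        hi: float = THETA3_MAX_PER_MIN) -> np.ndarray:
    """Log-spaced theta3 (= k2a) search grid in 1/min, ascending."""
    return np.geomspace(lo, hi, n)


# ---------------------------------------------------------------------------
# exponential convolution on a fine grid

def _fine_times_min(schedule: FrameSchedule, dt_s: float) -> np.ndarray:
    total = schedule.end_s[-1]
    n = int(np.ceil(total / dt_s)) + 1
    return np.linspace(0.0, total, n) / 60.0


def _interp_frames_to_fine(curve: np.ndarray, schedule: FrameSchedule,
                           t_fine_min: np.ndarray) -> np.ndarray:
    # anchor at t=0 by linear extrapolation of the first two midpoints,
    # clipped at zero (a bolus starts near zero; a flat curve stays flat)
    mids = schedule.mid_min
    if curve.size >= 2 and mids[1] > mids[0]:
        slope = (curve[1] - curve[0]) / (mids[1] - mids[0])
        v0 = max(0.0, curve[0] - slope * mids[0])
    else:
        v0 = 0.0
    mids = np.concatenate([[0.0], mids])
    vals = np.concatenate([[v0], curve])
    return np.interp(t_fine_min, mids, vals)


def _expconv_piecewise_linear(f: np.ndarray, t_min: np.ndarray,
                              lam_per_min: float) -> np.ndarray:
    """Exact convolution of a piecewise-linear f with exp(-lam t).

    Uses the closed-form update over each linear segment, so accuracy is
    limited only by how well the fine grid's linear interpolant represents
    the true curve.
    """
    dt = np.diff(t_min)
    out = np.zeros_like(f)
    a = np.exp(-lam_per_min * dt)
    lam = lam_per_min
    w0 = (1.0 - a) / lam                      # integral of exp over segment
    w1 = (1.0 - w0 / dt) / lam                # weight of the linear ramp
    for i in range(f.size - 1):
        out[i + 1] = out[i] * a[i] + f[i] * w0[i] + (f[i + 1] - f[i]) * w1[i]
    return out


def _frame_average(fine: np.ndarray, t_fine_min: np.ndarray,
                   schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval (trapezoid)."""
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (fine[1:] + fine[:-1]) * np.diff(t_fine_min))])
    start = schedule.start_s / 60.0
    end = schedule.end_s / 60.0
    c_start = np.interp(start, t_fine_min, cum)
    c_end = np.interp(end, t_fine_min, cum)
    return (c_end - c_start) / (end - start)


def convolve_with_exp(curve: np.ndarray, lambda_per_min: float,
                      schedule: FrameSchedule, dt_s: float = 1.0) -> np.ndarray:
    """Convolve a frame-sampled curve with exp(-lambda t), in minutes.

    The frame curve is linearly interpolated from frame midpoints onto a
    fine internal grid, convolved there, and integrated back over frame
    durations.  Linear in the input curve.
    """
    if lambda_per_min <= 0:
        raise ValueError("lambda must be positive")
    curve = np.asarray(curve, dtype=float)
    t_fine = _fine_times_min(schedule, dt_s)
    f = _interp_frames_to_fine(curve, schedule, t_fine)
    conv = _expconv_piecewise_linear(f, t_fine, lambda_per_min)
    return _frame_average(conv, t_fine, schedule)


def srtm_forward(r1: float, k2: float, bp_nd: float,
                 ref_curve: np.ndarray, schedule: FrameSchedule,
                 dt_s: float = 1.0) -> np.ndarray:
    """SRTM-predicted tissue curve from reference curve and parameters."""
    if 1.0 + bp_nd <= 0:
        raise ValueError("bp_nd must exceed -1 (efflux would be negative)")
    ref_curve = np.asarray(ref_curve, dtype=float)
    k2a = k2 / (1.0 + bp_nd)
    conv = convolve_with_exp(ref_curve, k2a, schedule, dt_s)
    return r1 * ref_curve + (k2 - r1 * k2a) * conv


# ---------------------------------------------------------------------------
# supervised cluster analysis reference extraction

@dataclass(frozen=True)
class ReferenceCurve:
    """Pseudo-reference time-activity curve from supervised clustering."""

    tac: np.ndarray
    n_voxels_contributing: int
    mean_white_weight: float

    def __post_init__(self):
        if np.any(np.asarray(self.tac) < -1e-9):
            raise ValueError("reference curve must be non-negative")


def _unit_area(curves: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    area = np.trapezoid(curves, t_min, axis=-1)
    area = np.where(area > 0, area, np.nan)
    return curves / area[..., None]


def svca_reference(tacs: np.ndarray, library, brain_mask: np.ndarray,
                   white_weight_min: float = 0.9,
                   min_voxels: int = 10,
                   mode: str = "mean") -> ReferenceCurve:
    """Extract the white-matter pseudo-reference curve.

    Parameters
    ----------
    tacs : (n_frames,) + grid array of voxel time-activity curves
    library : ClassLibrary with ``class_names``, ``class_tacs`` (n_class,
        n_frames) and ``schedule`` matching the data
    brain_mask : boolean grid of voxels to classify
    white_weight_min : inclusion threshold on the normalised white-class
        weight (default 0.9)
    mode : ``"mean"`` -- the reference is the white-weight-weighted mean of
        the member voxels' raw curves (so a vascular admixture in the
        members carries into the reference, where the voxelwise v_b term
        later absorbs it); ``"projected"`` -- each member is regressed on
        the white and blood class curves and the reference is the white
        class curve scaled by the vascular-corrected tissue amplitude
        c/(1-d), removing the intravascular contribution from the
        reference itself.
    """
    schedule: FrameSchedule = library.schedule
    if tacs.shape[0] != schedule.n_frames:
        raise ValueError("TAC frame count does not match library schedule")
    if not np.any(brain_mask):
        raise ValueError("brain mask is empty")

    t_min = schedule.mid_min
    classes = _unit_area(np.asarray(library.class_tacs, float), t_min)
    white_idx = list(library.class_names).index("white")

    vox = tacs.reshape(schedule.n_frames, -1)[:, brain_mask.ravel()].T  # (n_vox, n_f)
    areas = np.trapezoid(vox, t_min, axis=1)
    ok = areas > 0
    norm = vox[ok] / areas[ok, None]

    A = classes.T  # (n_frames, n_class)
    weights = np.empty((norm.shape[0], classes.shape[0]))
    for i, v in enumerate(norm):
        try:
            weights[i], _ = nnls(A, v, maxiter=50 * A.shape[1])
        except RuntimeError:  # rare NNLS non-convergence: bounded lstsq
            from scipy.optimize import lsq_linear
            weights[i] = lsq_linear(A, v, bounds=(0, np.inf)).x
    wsum = weights.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        white_w = np.where(wsum > 0, weights[:, white_idx] / wsum, 0.0)

    members = white_w >= white_weight_min
    if members.sum() < min_voxels:
        raise ValueError(
            f"supervised clustering found {int(members.sum())} reference "
            f"voxels (< {min_voxels}); relax white_weight_min (currently "
            f"{white_weight_min})")
    w = white_w[members]
    raw = vox[ok][members]
    if mode == "mean":
        ref = (raw * w[:, None]).sum(axis=0) / w.sum()
    elif mode == "projected":
        blood_idx = list(library.class_names).index("blood")
        white = np.asarray(library.class_tacs, float)[white_idx]
        blood = np.asarray(library.class_tacs, float)[blood_idx]
        X = np.column_stack([white, blood])
        c, d = np.linalg.lstsq(X, raw.T, rcond=None)[0]
        d = np.clip(d, 0.0, 0.9)
        scale = float(np.average(c / (1.0 - d), weights=w))
        ref = scale * white
    else:
        raise ValueError("mode must be 'mean' or 'projected'")
    return ReferenceCurve(tac=np.clip(ref, 0.0, None),
                          n_voxels_contributing=int(members.sum()),
                          mean_white_weight=float(w.mean()))


# ---------------------------------------------------------------------------
# basis-function SRTM fit

@dataclass(frozen=True)
class SRTMResults:
    """Single-voxel SRTM estimates and diagnostics."""

    r1: float
    k2: float
    bp_nd: float
    v_b: float
    theta: tuple[float, float, float]
    rss: float
    valid: bool = True
    k2_identifiable: bool = True

    def summary(self) -> str:
        return "\n".join([
            "Basis-function SRTM fit",
            f"  R1 (delivery ratio) : {self.r1:.4f}",
            f"  k2 (1/min)          : {self.k2:.4f}"
            + ("" if self.k2_identifiable else "  [non-identifiable]"),
            f"  BP_ND               : {self.bp_nd:.4f}",
            f"  v_b                 : {self.v_b:.4f}",
            f"  RSS                 : {self.rss:.4e}",
        ])


def _theta_to_params(theta1, theta2, theta3):
    bp = theta2 / theta3 + theta1 - 1.0
    k2 = theta2 + theta1 * theta3
    return bp, k2


class SRTM:
    """Basis-function SRTM model for a single time-activity curve.

    Parameters
    ----------
    tac : (n_frames,) target curve
    ref : :class:`ReferenceCurve` or array
    schedule : :class:`FrameSchedule`
    blood_curve : whole-blood curve for the vascular term (optional)
    """

    def __init__(self, tac, ref, schedule: FrameSchedule, blood_curve=None):
        self.tac = np.asarray(tac, dtype=float)
        self.ref = np.asarray(ref.tac if isinstance(ref, ReferenceCurve) else ref, float)
        if self.tac.size != schedule.n_frames or self.ref.size != schedule.n_frames:
            raise ValueError("curve length does not match schedule")
        self.schedule = schedule
        self.blood = None if blood_curve is None else np.asarray(blood_curve, float)

    def fit(self, theta3_grid: np.ndarray | None = None,
            vascular: bool | None = None, dt_s: float = 1.0) -> SRTMResults:
        if theta3_grid is None:
            theta3_grid = default_theta3_grid()
        theta3_grid = np.asarray(theta3_grid, dtype=float)
        if theta3_grid.size == 0 or np.any(theta3_grid <= 0):
            raise ValueError("theta3 grid must be non-empty and positive")
        theta3_grid = np.sort(theta3_grid)
        if vascular is None:
            vascular = self.blood is not None
        if vascular and self.blood is None:
            raise ValueError("vascular fit requested but no blood curve given")

        bases = np.stack([convolve_with_exp(self.ref, th, self.schedule, dt_s)
                          for th in theta3_grid])
        res = _fit_theta_scan(self.tac[None, :], self.ref, bases, theta3_grid,
                              self.blood if vascular else None)
        (r1, k2, bp, vb, th1, th2, th3, rss, valid, ident) = (x[0] for x in res)
        return SRTMResults(r1=float(r1), k2=float(k2), bp_nd=float(bp),
                           v_b=float(vb), theta=(float(th1), float(th2), float(th3)),
                           rss=float(rss), valid=bool(valid),
                           k2_identifiable=bool(ident))


def _lstsq_many(X: np.ndarray, Y: np.ndarray):
    """Least squares of Y (n_f, n_vox) on X (n_f, p) via normal equations."""
    XtX = X.T @ X
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        return None, None
    coef = np.linalg.solve(XtX, X.T @ Y)             # (p, n_vox)
    resid = Y - X @ coef
    return coef, (resid**2).sum(axis=0)


def _fit_theta_scan(tacs: np.ndarray, ref: np.ndarray, bases: np.ndarray,
                    theta3_grid: np.ndarray, blood: np.ndarray | None):
    """Scan theta3 for many voxels at once.

    tacs : (n_vox, n_frames);  bases : (n_theta, n_frames)
    Returns per-voxel arrays (r1, k2, bp, vb, th1, th2, th3, rss, valid,
    k2_identifiable).
    """
    Y = tacs.T                                        # (n_frames, n_vox)
    n_vox = Y.shape[1]
    best_rss = np.full(n_vox, np.inf)
    best = {k: np.full(n_vox, np.nan) for k in ("th1", "th2", "th3", "vb")}
    any_valid = np.zeros(n_vox, dtype=bool)

    for th, B in zip(theta3_grid, bases):
        if blood is None:
            X = np.column_stack([ref, B])
            coef, rss = _lstsq_many(X, Y)
            if coef is None:
                continue
            th1, th2 = coef[0], coef[1]
            vb = np.zeros(n_vox)
        else:
            X = np.column_stack([ref, B, blood])
            coef, rss = _lstsq_many(X, Y)
            if coef is None:
                continue
            a, b, w = coef[0].copy(), coef[1].copy(), coef[2].copy()
            # box-constrain the blood fraction, re-solving on the boundary
            for bound in (0.0, 1.0):
                off = (w < 0.0) if bound == 0.0 else (w > 1.0)
                if np.any(off):
                    X2 = np.column_stack([ref, B])
                    coef2, rss2 = _lstsq_many(X2, Y[:, off] - bound * blood[:, None])
                    if coef2 is None:
                        continue
                    a[off], b[off], w[off] = coef2[0], coef2[1], bound
                    rss[off] = rss2
            # the tissue part is scaled by (1 - v_b)
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(w < 1.0, 1.0 - w, np.nan)
                th1, th2 = a / scale, b / scale
            vb = w
        better = rss < best_rss * (1.0 - 1e-12)      # strict: ties keep smaller theta3
        best_rss = np.where(better, rss, best_rss)
        for k, v in (("th1", th1), ("th2", th2), ("th3", np.full(n_vox, th)), ("vb", vb)):
            best[k] = np.where(better, v, best[k])
        any_valid |= better

    bp, k2 = _theta_to_params(best["th1"], best["th2"], best["th3"])
    valid = any_valid & np.isfinite(bp)
    scale = np.nanmax(np.abs(tacs), axis=1)
    ident = np.abs(best["th2"]) > 1e-6 * np.where(scale > 0, scale, 1.0)
    return (best["th1"], k2, bp, best["vb"], best["th1"], best["th2"],
            best["th3"], best_rss, valid, ident)


def srtm_basis_fit(tac, ref, schedule: FrameSchedule, blood_curve=None,
                   theta3_grid=None, vascular: bool | None = None) -> SRTMResults:
    """Functional wrapper around :class:`SRTM`."""
    return SRTM(tac, ref, schedule, blood_curve).fit(theta3_grid, vascular)


@dataclass(frozen=True)
class BPMap:
    """Voxelwise SRTM results rasterised onto the volume grid."""

    bp_nd: np.ndarray
    r1: np.ndarray
    k2: np.ndarray
    v_b: np.ndarray
    rss: np.ndarray
    valid: np.ndarray

    def values_in(self, mask: np.ndarray) -> np.ndarray:
        return self.bp_nd[mask & self.valid]


def bp_map(tacs: np.ndarray, ref, schedule: FrameSchedule, mask: np.ndarray,
           blood_curve=None, theta3_grid=None, vascular: bool | None = None,
           dt_s: float = 1.0) -> BPMap:
    """Voxelwise basis-function SRTM over a mask.

    ``tacs`` has shape ``(n_frames,) + grid``; all voxels share the same
    basis set, so the theta3 scan is vectorised across the mask.
    """
    if tacs.shape[0] != schedule.n_frames:
        raise ValueError("frame count does not match schedule")
    if mask.shape != tacs.shape[1:]:
        raise ValueError("mask shape does not match volume")
    ref_arr = np.asarray(ref.tac if isinstance(ref, ReferenceCurve) else ref, float)
    if theta3_grid is None:
        theta3_grid = default_theta3_grid()
    theta3_grid = np.sort(np.asarray(theta3_grid, float))
    if vascular is None:
        vascular = blood_curve is not None
    blood = np.asarray(blood_curve, float) if (vascular and blood_curve is not None) else None

    bases = np.stack([convolve_with_exp(ref_arr, th, schedule, dt_s)
                      for th in theta3_grid])
    idx = np.flatnonzero(mask.ravel())
    vox = tacs.reshape(schedule.n_frames, -1)[:, idx].T
    th1, k2, bp, vb, _, _, _, rss, valid, _ = _fit_theta_scan(
        vox, ref_arr, bases, theta3_grid, blood)

    grid = mask.shape
    out = {name: np.full(grid, np.nan) for name in ("bp", "r1", "k2", "vb", "rss")}
    for name, vals in (("bp", bp), ("r1", th1), ("k2", k2), ("vb", vb), ("rss", rss)):
        out[name].ravel()[idx] = vals
    vmask = np.zeros(grid, dtype=bool)
    vmask.ravel()[idx] = valid
    return BPMap(bp_nd=out["bp"], r1=out["r1"], k2=out["k2"], v_b=out["vb"],
                 rss=out["rss"], valid=vmask)
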