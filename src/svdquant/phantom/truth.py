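"""Ground-truth parameter maps for a phantom subject.

NAWM voxels draw their true Ki and BP_ND from the same Gaussian null as
the control library (exchangeability is what makes the 95th-percentile
hotspot threshold calibrated); a configurable fraction of NAWM voxels is
re-assigned elevated "hotspot" truth.  Hotspot voxels are grown as
spatially contiguous blobs rather than i.i.d. voxels, mimicking the focal
clusters seen in patient maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import LabelVolume, Labels
from .spec import PhantomSpec

__all__ = ["TruthMaps", "assign_hotspot_mask", "make_truth_maps"]


@dataclass(frozen=True)
class TruthMaps:
    """Voxelwise ground truth for one simulated subject."""

    ki: np.ndarray
    vp: np.ndarray
    t1_ms: np.ndarray
    r1: np.ndarray
    k2: np.ndarray
    bp: np.ndarray
    vb: np.ndarray
    hotspot_mask: np.ndarray


def assign_hotspot_mask(nawm_mask: np.ndarray, fraction: float,
                        rng: np.random.Generator,
                        blob_radius_vox: float = 2.5) -> np.ndarray:
    """Contiguous hotspot blobs covering ~``fraction`` of the NAWM mask."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    target = int(round(fraction * nawm_mask.sum()))
    hot = np.zeros_like(nawm_mask)
    if target == 0:
        return hot
    candidates = np.argwhere(nawm_mask)
    grids = np.ogrid[tuple(slice(0, s) for s in nawm_mask.shape)]
    for _ in range(200):
        c = candidates[rng.integers(candidates.shape[0])]
        r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        hot |= (r2 <= blob_radius_vox**2) & nawm_mask
        if hot.sum() >= target:
            break
    return hot


def make_truth_maps(masks: LabelVolume, spec: PhantomSpec,
                    rng: np.random.Generator,
                    ki_mu: float | None = None, bp_mu: float | None = None,
                    hotspot_fraction: float | None = None) -> TruthMaps:
    """Assign per-voxel ground truth given the label volume.

    ``ki_mu`` / ``bp_mu`` / ``hotspot_fraction`` override the spec's NAWM
    means for subject-level heterogeneity.
    """
    grid = masks.shape
    labels = masks.labels
    ki_mu = spec.truth_Ki_nawm if ki_mu is None else ki_mu
    bp_mu = spec.truth_BP_nawm if bp_mu is None else bp_mu
    frac = spec.hotspot_fraction if hotspot_fraction is None else hotspot_fraction

    t1 = np.full(grid, spec.t1_gm_ms)
    for code, val in ((Labels.WM, spec.t1_wm_ms), (Labels.WMH, spec.t1_wmh_ms),
                      (Labels.CSF, spec.t1_csf_ms), (Labels.SSS, spec.t1_blood_ms)):
        t1[labels == code] = val
    t1[labels == Labels.BACKGROUND] = spec.t1_gm_ms  # unused outside head

    nawm = labels == Labels.WM
    hot = assign_hotspot_mask(nawm, frac, rng)

    ki = np.zeros(grid)
    bp = np.zeros(grid)
    head = labels > 0
    ki[head] = rng.normal(ki_mu, spec.truth_Ki_sd_nawm, size=int(head.sum()))
    bp[head] = rng.normal(bp_mu, spec.truth_BP_sd_nawm, size=int(head.sum()))
    # lesional and hotspot tissue: elevated permeability and binding
    wmh = labels == Labels.WMH
    ki[wmh] = rng.normal(spec.truth_Ki_hotspot, spec.truth_Ki_sd_hotspot, wmh.sum())
    ki[hot] = rng.normal(spec.truth_Ki_hotspot, spec.truth_Ki_sd_hotspot, hot.sum())
    bp[hot] = rng.normal(spec.truth_BP_hotspot, spec.truth_BP_sd_hotspot, hot.sum())
    bp = np.maximum(bp, -0.9)

    vp = np.full(grid, spec.truth_vp)
    r1m = np.full(grid, spec.truth_R1)
    r1m[labels == Labels.GM] = 1.3          # gray matter delivers faster
    k2m = np.full(grid, spec.truth_k2)
    vb = np.full(grid, spec.truth_vb)
    vb[labels == Labels.SSS] = 1.0

    return TruthMaps(ki=ki, vp=vp, t1_ms=t1, r1=r1m, k2=k2m, bp=bp, vb=vb,
                     hotspot_mask=hot)
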