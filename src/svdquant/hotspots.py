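"""Hotspot endpoint metrics in eroded normal-appearing white matter.

The trial's endpoints are rank-based: a voxel of the NAWM is a "hotspot"
when its parameter value (Patlak Ki or SRTM BP_ND) strictly exceeds the
95th percentile of the corresponding pooled control-cohort voxel
distribution.  NAWM is white matter minus the WMH lesion mask, eroded by a
physical 3 mm ball to eliminate CSF/gray-matter contamination.  Reported
per subject and map type: the threshold, the hotspot volume as a
percentage of eroded NAWM (co-primary endpoint), and the mean parameter
value inside hotspots and across NAWM (secondary endpoints).

Percentiles use the Hazen / R type-7 convention, h = 1 + (n-1) q/100 on
the sorted sample, pinned for reproducibility (changing the convention
changes thresholds).  Invalid-fit voxels are excluded from both numerator
and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["erode_mask", "build_nawm", "percentile_threshold",
           "hotspot_metrics", "HotspotResult", "ball_structure"]

DEFAULT_EROSION_MM = 3.0
DEFAULT_PERCENTILE = 95.0
MIN_CONTROL_N = 20


def ball_structure(radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Structuring element of voxel offsets within a physical radius."""
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    if np.any(voxel_size_mm <= 0):
        raise ValueError("voxel size must be positive")
    half = np.floor(radius_mm / voxel_size_mm).astype(int)
    axes = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel_size_mm)]
    grids = np.meshgrid(*axes, indexing="ij")
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2 + 1e-9


def erode_mask(mask: np.ndarray, radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Morphological erosion by a physical-radius ball.

    Out-of-volume neighbours count as background, so voxels near the
    volume edge erode away.
    """
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if radius_mm == 0:
        return mask.copy()
    struct = ball_structure(radius_mm, voxel_size_mm)
    return ndimage.binary_erosion(mask, structure=struct, border_value=0)


def build_nawm(wm_mask: np.ndarray, wmh_mask: np.ndarray,
               voxel_size_mm, erosion_mm: float = DEFAULT_EROSION_MM) -> np.ndarray:
    """Eroded NAWM = (WM and not WMH), eroded by ``erosion_mm``."""
    if wm_mask.shape != wmh_mask.shape:
        raise ValueError("WM and WMH masks differ in shape")
    nawm = wm_mask & ~wmh_mask
    nawm = erode_mask(nawm, erosion_mm, voxel_size_mm)
    if not np.any(nawm):
        raise ValueError("eroded NAWM is empty; endpoint undefined")
    return nawm


def percentile_threshold(control_values: np.ndarray,
                         q: float = DEFAULT_PERCENTILE) -> float:
    """Type-7 (linear interpolation) percentile of pooled control voxels."""
    vals = np.asarray(control_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if not 0.0 < q < 100.0:
        raise ValueError("q must lie in (0, 100)")
    if vals.size < MIN_CONTROL_N:
        raise ValueError(
            f"need >= {MIN_CONTROL_N} control values for a stable q={q} "
            f"threshold (got {vals.size})")
    return float(np.percentile(vals, q, method="linear"))


@dataclass(frozen=True)
class HotspotResult:
    """Endpoint bundle for one parameter map and NAWM mask."""

    threshold: float
    hotspot_mask: np.ndarray
    pct_volume: float
    mean_in_hotspots: float      # NaN when no voxel exceeds the threshold
    mean_in_nawm: float
    n_nawm_voxels: int
    n_excluded_invalid: int

    def summary(self) -> str:
        mh = ("n/a" if np.isnan(self.mean_in_hotspots)
              else f"{self.mean_in_hotspots:.4g}")
        return "\n".join([
            "Hotspot endpoint",
            f"  threshold        : {self.threshold:.4g}",
            f"  NAWM voxels      : {self.n_nawm_voxels}"
            f" (excluded invalid: {self.n_excluded_invalid})",
            f"  hotspot volume   : {self.pct_volume:.2f} % of NAWM",
            f"  mean in hotspots : {mh}",
            f"  mean in NAWM     : {self.mean_in_nawm:.4g}",
        ])


def hotspot_metrics(param_map: np.ndarray, nawm_mask: np.ndarray,
                    threshold: float) -> HotspotResult:
    """Hotspot percentage and means over a (possibly partially invalid) map.

    Voxels with non-finite parameter values are excluded from both the
    numerator and the denominator; ties at the threshold are non-hotspot
    (strict '>').
    """
    if param_map.shape != nawm_mask.shape:
        raise ValueError("map/mask shape mismatch")
    if not np.any(nawm_mask):
        raise ValueError("empty NAWM mask")
    finite = np.isfinite(param_map)
    usable = nawm_mask & finite
    n_excl = int(nawm_mask.sum() - usable.sum())
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no valid voxels inside NAWM")

    hot = usable & (param_map > threshold)
    n_hot = int(hot.sum())
    vals = param_map[usable]
    return HotspotResult(
        threshold=float(threshold),
        hotspot_mask=hot,
        pct_volume=100.0 * n_hot / n,
        mean_in_hotspots=float(param_map[hot].mean()) if n_hot else float("nan"),
        mean_in_nawm=float(vals.mean()),
        n_nawm_voxels=n,
        n_excluded_invalid=n_excl,
    )
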