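"""Phantom tissue geometry.

Builds a labelled head phantom on a regular grid: a spherical brain with a
gray-matter shell, white-matter core, a small central CSF cavity, spherical
white-matter-hyperintensity (WMH) lesions placed inside the white matter,
and a superior-sagittal-sinus (SSS) blood ROI as a tube along the posterior
edge of the volume.  This stands in for the segmentation and lesion
contouring a real study performs upstream of quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spec import PhantomSpec

__all__ = ["Labels", "LabelVolume", "generate_phantom_masks"]


class Labels:
    """Integer tissue codes used throughout the phantom."""

    BACKGROUND = 0
    GM = 1
    WM = 2          # NAWM-eligible white matter
    WMH = 3
    CSF = 4
    SSS = 5


@dataclass(frozen=True)
class LabelVolume:
    """3-D integer label volume plus voxel-to-world affine."""

    labels: np.ndarray
    affine: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels, codes)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


def _sphere_mask(shape, center, radius_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius_vox**2


def generate_phantom_masks(spec: PhantomSpec) -> LabelVolume:
    """Generate the deterministic label volume for a phantom spec.

    WMH blobs are spheres with radii sampled uniformly from
    ``spec.wmh_radius_mm`` and centres rejected-sampled so the whole sphere
    fits inside the white-matter core; placement failing after a bounded
    number of retries raises with the violated constraint named.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    vox = spec.voxel_size_mm
    center = tuple((s - 1) / 2.0 for s in shape)
    min_half_extent_mm = min(s * v for s, v in zip(shape, vox)) / 2.0

    # concentric brain: GM shell over WM core, in physical units
    r_brain = 0.88 * min_half_extent_mm
    r_wm = 0.64 * min_half_extent_mm
    r_csf = 0.10 * min_half_extent_mm

    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2_mm = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center, vox))
    labels = np.zeros(shape, dtype=np.int16)
    labels[r2_mm <= r_brain**2] = Labels.GM
    labels[r2_mm <= r_wm**2] = Labels.WM
    labels[r2_mm <= r_csf**2] = Labels.CSF

    # WMH lesions: spheres fully inside the WM ball
    wm_center = np.array(center)
    for _ in range(spec.n_wmh_blobs):
        placed = False
        for _attempt in range(200):
            radius_mm = rng.uniform(*spec.wmh_radius_mm)
            # admissible centre distance so the blob stays inside WM
            max_off = (r_wm - radius_mm) - 1e-9
            if max_off <= 0:
                continue
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = max_off * rng.uniform() ** (1 / 3)
            c = wm_center + dist * direction / np.array(vox)
            blob = _sphere_mask(shape, c, radius_mm / vox[0])
            if np.all(labels[blob] != Labels.CSF):
                labels[blob & (labels == Labels.WM)] = Labels.WMH
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "WMH blob placement failed: no admissible centre keeps a "
                f"sphere of radius in {spec.wmh_radius_mm} mm inside the "
                f"white-matter ball of radius {r_wm:.1f} mm"
            )

    # SSS ROI: tube along z at the posterior (max-y) edge, inside the FOV
    yc = shape[1] - 3
    xc = center[0]
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    tube2d = ((x - xc) * vox[0]) ** 2 + ((y - yc) * vox[1]) ** 2 <= (1.6 * vox[1]) ** 2
    z0, z1 = shape[2] // 4, 3 * shape[2] // 4
    sss = np.zeros(shape, dtype=bool)
    sss[:, :, z0:z1] = tube2d[:, :, None]
    labels[sss] = Labels.SSS
    if not np.any(labels == Labels.SSS):
        raise RuntimeError("SSS ROI is empty; grid too small")

    affine = np.diag(list(vox) + [1.0])
    return LabelVolume(labels=labels, affine=affine, voxel_size_mm=vox)
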