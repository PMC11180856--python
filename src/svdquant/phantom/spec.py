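"""Phantom configuration.

:class:`PhantomSpec` collects every knob of the digital head phantom: grid
geometry, lesion load, ground-truth kinetic parameters for normal-appearing
white matter (NAWM) and for focal "hotspot" tissue, noise levels, and the
contrast/tracer administration parameters.  Defaults reproduce the order of
magnitude of published small-vessel-disease cohorts: NAWM influx rate
Ki ~ 0.0002 mL/g/min with SD 0.0003 (near-zero, negatives possible), NAWM
TSPO binding potential ~ -0.03, hotspot Ki ~ 0.007 and hotspot BP ~ 0.19.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["PhantomSpec"]


@dataclass(frozen=True)
class PhantomSpec:
    # geometry
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_wmh_blobs: int = 3
    wmh_radius_mm: tuple[float, float] = (2.0, 4.0)
    seed: int = 0

    # noise (fractions)
    noise_sd_dce: float = 0.01    # of baseline SPGR signal
    noise_sd_pet: float = 0.05    # of peak TAC

    # ground-truth kinetics
    truth_Ki_nawm: float = 0.0002       # mL/g/min
    truth_Ki_sd_nawm: float = 0.0003
    truth_Ki_hotspot: float = 0.007
    truth_Ki_sd_hotspot: float = 0.001
    truth_vp: float = 0.01              # plasma/distribution-volume term
    truth_BP_nawm: float = -0.03        # unitless
    truth_BP_sd_nawm: float = 0.025
    truth_BP_hotspot: float = 0.19
    truth_BP_sd_hotspot: float = 0.018
    truth_R1: float = 1.0               # delivery ratio vs reference WM
    truth_k2: float = 0.10              # 1/min efflux
    truth_vb: float = 0.05              # PET vascular fraction
    hotspot_fraction: float = 0.10      # fraction of NAWM voxels made hotspot

    # physiology / administration
    hct: float = 0.45
    dose_mmol_per_kg: float = 0.025
    injected_activity_MBq: float = 500.0

    # tissue T1 at 3T (ms)
    t1_wm_ms: float = 800.0
    t1_gm_ms: float = 1200.0
    t1_csf_ms: float = 3000.0
    t1_wmh_ms: float = 1000.0
    t1_blood_ms: float = 1600.0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if not 0.0 < self.hct < 1.0:
            raise ValueError("hct must lie in (0, 1)")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ValueError("hotspot_fraction must lie in [0, 1]")
        if self.n_wmh_blobs < 0:
            raise ValueError("n_wmh_blobs must be >= 0")
        lo, hi = self.wmh_radius_mm
        if lo <= 0 or hi < lo:
            raise ValueError("wmh_radius_mm must be an increasing positive range")
        if self.truth_BP_nawm <= -1 or self.truth_BP_hotspot <= -1:
            raise ValueError("binding potential must exceed -1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["wmh_radius_mm"] = list(self.wmh_radius_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "voxel_size_mm", "wmh_radius_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
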