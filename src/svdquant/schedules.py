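"""Dynamic-acquisition frame schedules.

A :class:`FrameSchedule` describes how a dynamic PET acquisition is binned
into frames: contiguous, non-overlapping intervals covering the scan.  The
default schedule is 55 frames of geometrically increasing duration covering
75 minutes, mirroring a list-mode acquisition histogrammed into discrete
time bins with short early frames around the bolus and long late frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule"]

DEFAULT_N_FRAMES = 55
DEFAULT_TOTAL_S = 75.0 * 60.0


def _geometric_durations(n_frames: int, total_s: float, first_s: float = 10.0) -> np.ndarray:
    """Durations d_i = first_s * r**i with sum total_s; solves for r."""
    if n_frames == 1:
        return np.array([total_s])

    def total(r: float) -> float:
        if abs(r - 1.0) < 1e-12:
            return first_s * n_frames
        return first_s * (r**n_frames - 1.0) / (r - 1.0)

    lo, hi = 1.0 + 1e-9, 2.0
    while total(hi) < total_s:
        hi *= 1.5
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if total(mid) < total_s:
            lo = mid
        else:
            hi = mid
    r = 0.5 * (lo + hi)
    d = first_s * r ** np.arange(n_frames)
    d *= total_s / d.sum()  # absorb residual rounding
    return d


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition.

    Parameters
    ----------
    start_s : array of frame start times (seconds)
    duration_s : array of frame durations (seconds)
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        if start.shape != dur.shape or start.ndim != 1:
            raise ValueError("start_s and duration_s must be 1-D with equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        ends = start + dur
        if not np.allclose(start[1:], ends[:-1], rtol=0, atol=1e-6):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    @classmethod
    def geometric(
        cls,
        n_frames: int = DEFAULT_N_FRAMES,
        total_s: float = DEFAULT_TOTAL_S,
        first_s: float = 10.0,
    ) -> "FrameSchedule":
        """Geometrically increasing frame durations summing to ``total_s``."""
        dur = _geometric_durations(n_frames, total_s, first_s)
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)

    def to_dict(self) -> dict:
        return {
            "start_s": self.start_s.tolist(),
            "duration_s": self.duration_s.tolist(),
            "n_frames": self.n_frames,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(np.asarray(d["start_s"]), np.asarray(d["duration_s"]))
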