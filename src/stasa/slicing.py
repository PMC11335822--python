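"""Cross-section slicing of a scanpath sample along the time axis.

Scanpaths live in a 3D coordinate system (x, y, t).  Cutting that volume at
regular times t_k = k * delta yields, per slice, the 2D positions of every
fixation active at t_k — the point clouds that density clustering operates
on.  A fixation with interval [b, e) is active at t iff b <= t < e; the
half-open convention prevents a fixation ending at t and one starting at t
from both claiming the slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import ScanpathSample

__all__ = ["SlicePoint", "TimeSlice", "SliceSeries", "slice_sample"]


@dataclass(frozen=True)
class SlicePoint:
    x: float
    y: float
    scanpath_index: int
    fixation_index: int


@dataclass(frozen=True)
class TimeSlice:
    """All fixation positions active at one sampled time."""

    t: float
    points: tuple[SlicePoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) position array; shape (0, 2) for an empty slice."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class SliceSeries:
    delta: float
    slices: tuple[TimeSlice, ...]

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.slices], dtype=float)


def slice_sample(sample: ScanpathSample, delta: float) -> SliceSeries:
    """Cut the sample at t = 0, delta, 2*delta, ... up to the last fixation end.

    Each slice lists at most one point per scanpath (fixations of one
    scanpath never overlap in time).  Slices during which every scanpath is
    mid-saccade are kept but empty, so the slice index remains a linear
    function of time.
    """
    if delta <= 0:
        raise ParameterError("slice spacing delta must be positive")
    t_max = max(sp.fixations[-1].e for sp in sample)
    n_slices = int(np.floor(t_max / delta)) + 1
    slices = []
    for k in range(n_slices):
        t = k * delta
        pts = []
        for si, sp in enumerate(sample):
            for fi, f in enumerate(sp):
                if f.b <= t < f.e:
                    pts.append(SlicePoint(f.x, f.y, si, fi))
                    break  # at most one active fixation per scanpath
        slices.append(TimeSlice(t, tuple(pts)))
    return SliceSeries(delta, tuple(slices))
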