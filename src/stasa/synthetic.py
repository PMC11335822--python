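"""Seeded generator of scanpath samples with planted short-time AOIs.

Emulates a free-viewing experiment: ~15 observers look at one static
stimulus (800 x 600 px by default) for 3 s, and the sample-level strategy
is planted explicitly as a sequence of spatio-temporal boxes — each
observer places one fixation uniformly inside each box, with Gaussian
jitter on the interval endpoints controlling how desynchronized observers
are.  A configurable fraction of observers instead scatter their fixations
uniformly over the whole stimulus (outliers), which is what the density
clustering stage is supposed to reject.

Because the planted boxes are known, recovery can be scored exactly:
a correct aggregation returns one AOI per box, near the box centre, over
roughly the planted interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ScanpathValidationError
from .model import (
    Fixation,
    Scanpath,
    ScanpathSample,
    StimulusFrame,
    reconstruct_times,
)

__all__ = ["PlantedAOI", "SimulationSpec", "generate_sample", "degrade_to_durations",
           "default_spec"]


@dataclass(frozen=True)
class PlantedAOI:
    """Ground-truth spatio-temporal box: fixations land uniformly inside."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    b: float
    e: float

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ParameterError("planted AOI box must have positive area")
        if self.e <= self.b:
            raise ParameterError("planted AOI interval must have positive length")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)

    def contains(self, x: float, y: float, pad: float = 0.0) -> bool:
        return (
            self.x_min - pad <= x <= self.x_max + pad
            and self.y_min - pad <= y <= self.y_max + pad
        )


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic sample.

    Defaults mirror a typical free-viewing benchmark setup: 15 observers,
    3-s trials, 800 x 600 px stimuli.  ``jitter_sd`` (ms) desynchronizes
    interval endpoints; ``outlier_rate`` is the fraction of observers whose
    gaze ignores the planted structure entirely.
    """

    stimulus: StimulusFrame = field(
        default_factory=lambda: StimulusFrame(800, 600, 3000)
    )
    aois: tuple[PlantedAOI, ...] = ()
    m: int = 15
    jitter_sd: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ParameterError("need at least two scanpaths")
        if not 0 <= self.outlier_rate < 1:
            raise ParameterError("outlier_rate must be in [0, 1)")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be non-negative")
        prev_end = -np.inf
        for aoi in self.aois:
            if aoi.b < prev_end:
                raise ParameterError("planted AOI intervals must not overlap")
            prev_end = aoi.e


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """Three-AOI free-viewing scenario on the default stimulus.

    The boxes step across the stimulus left-to-right with ~500-ms dwell
    times separated by short saccade gaps — the scale of dwell and box
    sizes seen in natural-scene viewing.
    """
    aois = (
        PlantedAOI(100, 100, 250, 220, 0, 800),
        PlantedAOI(400, 250, 560, 380, 950, 1850),
        PlantedAOI(550, 420, 720, 540, 2000, 2900),
    )
    return SimulationSpec(aois=aois, seed=seed, **overrides)


_MAX_RETRIES = 100


def _jittered_intervals(
    spec: SimulationSpec, rng: np.random.Generator
) -> list[tuple[float, float]] | None:
    """Perturb each planted interval; None when ordering cannot be kept."""
    total = spec.stimulus.viewing_duration
    intervals = []
    prev_end = 0.0
    for aoi in spec.aois:
        b = aoi.b + rng.normal(0, spec.jitter_sd) if spec.jitter_sd else aoi.b
        e = aoi.e + rng.normal(0, spec.jitter_sd) if spec.jitter_sd else aoi.e
        b = float(np.clip(b, prev_end, total))
        e = float(np.clip(e, b, total))
        if e - b < 1.0:  # jitter crushed the fixation
            return None
        intervals.append((b, e))
        prev_end = e
    return intervals


def generate_sample(spec: SimulationSpec) -> tuple[ScanpathSample, tuple[PlantedAOI, ...]]:
    """Draw one sample and return it with the planted ground truth.

    Non-outlier observers place one fixation per planted AOI, uniform in
    its box, over the (jittered) planted interval.  Outlier observers get
    the same number of fixations at uniform positions over the whole
    stimulus, with the viewing time partitioned evenly into fixations and
    gaps.  Deterministic for a fixed seed.
    """
    if not spec.aois:
        raise ParameterError("spec must plant at least one AOI")
    rng = np.random.default_rng(spec.seed)
    n_outliers = int(round(spec.outlier_rate * spec.m))
    is_outlier = np.zeros(spec.m, dtype=bool)
    if n_outliers:
        is_outlier[rng.choice(spec.m, size=n_outliers, replace=False)] = True

    stim = spec.stimulus
    scanpaths = []
    for m in range(spec.m):
        if is_outlier[m]:
            n = len(spec.aois)
            durations = np.full(n, 0.8 * stim.viewing_duration / n)
            times = reconstruct_times(durations, stim.viewing_duration)
            fixes = tuple(
                Fixation(
                    float(rng.uniform(0, stim.width)),
                    float(rng.uniform(0, stim.height)),
                    b,
                    e,
                )
                for (b, e) in times
            )
            scanpaths.append(Scanpath(f"outlier{m:02d}", fixes))
            continue
        intervals = None
        for _ in range(_MAX_RETRIES):
            intervals = _jittered_intervals(spec, rng)
            if intervals is not None:
                break
        if intervals is None:
            raise ScanpathValidationError(
                f"observer {m}: temporal jitter kept violating interval ordering"
            )
        fixes = tuple(
            Fixation(
                float(rng.uniform(aoi.x_min, aoi.x_max)),
                float(rng.uniform(aoi.y_min, aoi.y_max)),
                b,
                e,
            )
            for aoi, (b, e) in zip(spec.aois, intervals)
        )
        scanpaths.append(Scanpath(f"obs{m:02d}", fixes))
    return ScanpathSample(tuple(scanpaths), stim), spec.aois


def degrade_to_durations(sample: ScanpathSample) -> pd.DataFrame:
    """Strip timestamps, keeping only per-fixation durations.

    Emulates exports that record (x, y, duration) without start/end times;
    :func:`stasa.model.reconstruct_times` rebuilds usable timestamps from
    such records.  Row order preserves fixation order per observer.
    """
    rows = [
        {"observer": sp.observer_id, "x": f.x, "y": f.y, "dur": f.duration}
        for sp in sample
        for f in sp
    ]
    return pd.DataFrame(rows, columns=["observer", "x", "y", "dur"])
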