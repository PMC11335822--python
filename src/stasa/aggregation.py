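"""Short-time AOI detection and representative-scanpath assembly.

The pipeline: slice the sample along the time axis, find the major dense
cluster on each slice, bound it with a concave hull, score the area overlap
(intersection over union) of hulls on adjacent slices, and declare a
short-time AOI wherever a run of consecutive slices keeps that overlap
above a threshold theta.  Each AOI is the union of its slices' hulls with
the run's first and last slice time as its interval; the representative
scanpath places one synthetic fixation at each AOI's centroid over that
interval.

Theta trades temporal tolerance against spatial discrimination: small
values absorb observer desynchronization into longer AOIs, large values
split spatially close but temporally distinct AOIs.  :func:`tune_theta`
scans a grid (0.1 ... 0.9 by default) and keeps the candidate whose mean
dissimilarity to the sample is lowest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import find_major_cluster
from .errors import (
    DegenerateClusterError,
    DegenerateRegionError,
    EmptyRepresentativeError,
    ParameterError,
)
from .geometry import Region, centroid, concave_hull, degenerate_region, overlap_similarity, union_regions
from .model import Fixation, Scanpath, ScanpathSample
from .similarity import representativeness
from .slicing import SliceSeries, slice_sample

__all__ = [
    "ShortTimeAOI",
    "RepresentativeScanpath",
    "slice_regions",
    "similarity_series",
    "detect_intervals",
    "build_aoi",
    "stasa",
    "tune_theta",
    "DEFAULT_THETA_GRID",
    "MIN_SLICES",
    "MIN_AOI_DURATION_MS",
]

logger = logging.getLogger(__name__)

DEFAULT_THETA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))
#: an AOI must span at least this many consecutive slices ...
MIN_SLICES = 3
#: ... and at least this much time, ms.  At the default 30-ms slice spacing
#: the duration rule is the binding one (3 slices span only 60 ms).
MIN_AOI_DURATION_MS = 100.0


@dataclass(frozen=True)
class ShortTimeAOI:
    """A bounding region valid over a bounded time interval (P, b, e)."""

    region: Region
    b: float
    e: float

    @property
    def duration(self) -> float:
        return self.e - self.b

    @property
    def center(self) -> tuple[float, float]:
        return centroid(self.region)


@dataclass(frozen=True)
class RepresentativeScanpath:
    """A synthesized scanpath plus the AOIs its fixations came from."""

    scanpath: Scanpath
    aois: tuple[ShortTimeAOI, ...]
    theta_used: float
    mean_dissimilarity: float  # mean Scasim to the sample, ms


def slice_regions(
    sample: ScanpathSample, delta: float, *, degenerate_pad: float = 1.0,
    eps_stride: int = 1,
) -> tuple[SliceSeries, list[Region | None]]:
    """Slice the sample and bound each slice's major cluster.

    Returns the slice series and one region (or ``None``) per slice.  A
    cluster of fewer than three distinct or collinear points cannot carry a
    polygon, so it is substituted by a thin buffered disc/segment
    (``degenerate_pad`` px) rather than dropped — a strongly agreeing but
    tight consensus still marks an AOI.
    """
    series = slice_sample(sample, delta)
    m = len(sample)
    regions: list[Region | None] = []
    for slc in series:
        cluster = find_major_cluster(
            slc, sample.stimulus, m, eps_stride=eps_stride
        )
        if cluster is None:
            regions.append(None)
            continue
        try:
            regions.append(concave_hull(cluster.xy).as_region())
        except DegenerateClusterError:
            regions.append(degenerate_region(cluster.xy, pad=degenerate_pad))
    return series, regions


def similarity_series(regions: Sequence[Region | None]) -> list[tuple[int, float]]:
    """Adjacent-slice overlap similarities ``(i, S(i, i+1))``.

    A missing region on either slice scores 0: absent consensus cannot
    belong to an AOI, so it always breaks a run.
    """
    out: list[tuple[int, float]] = []
    for i in range(len(regions) - 1):
        p, q = regions[i], regions[i + 1]
        if p is None or q is None:
            out.append((i, 0.0))
        else:
            try:
                out.append((i, overlap_similarity(p, q)))
            except DegenerateRegionError:
                out.append((i, 0.0))
    return out


def detect_intervals(
    series: Sequence[tuple[int, float]] | Sequence[float],
    theta: float,
    delta: float,
    *,
    min_slices: int = MIN_SLICES,
    min_duration: float = MIN_AOI_DURATION_MS,
) -> list[tuple[int, int]]:
    """Maximal runs of slices whose every adjacent overlap exceeds theta.

    ``series`` holds the similarity of slice pairs (i, i+1); a run of
    consecutive entries all strictly above theta covers slices
    ``first .. last + 1``.  Runs with fewer than ``min_slices`` slices or a
    time span below ``min_duration`` are discarded.  Returned as inclusive
    slice-index ranges, time-ordered and pairwise disjoint.
    """
    if not 0 < theta < 1:
        raise ParameterError("theta must lie strictly between 0 and 1")
    values = [s[1] if isinstance(s, tuple) else float(s) for s in series]
    out: list[tuple[int, int]] = []
    run_start: int | None = None
    for i, v in enumerate(values + [-np.inf]):  # sentinel closes a trailing run
        if v > theta:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            first, last = run_start, i  # slices run_start .. i
            n_slices = last - first + 1
            if n_slices >= min_slices and (last - first) * delta >= min_duration:
                out.append((first, last))
            run_start = None
    return out


def build_aoi(
    regions: Sequence[Region], slice_times: Sequence[float]
) -> ShortTimeAOI:
    """Union the regions of one interval into a short-time AOI.

    The interval runs from the first to the last slice time; slices are
    point samples, so no trailing delta is added.
    """
    if len(regions) < MIN_SLICES:
        raise ParameterError(f"an AOI needs at least {MIN_SLICES} slices")
    if len(regions) != len(slice_times):
        raise ParameterError("regions and slice_times must align")
    return ShortTimeAOI(
        region=union_regions(list(regions)),
        b=float(slice_times[0]),
        e=float(slice_times[-1]),
    )


def _assemble(
    series: SliceSeries,
    regions: Sequence[Region | None],
    sims: Sequence[tuple[int, float]],
    theta: float,
) -> tuple[Scanpath, tuple[ShortTimeAOI, ...]]:
    intervals = detect_intervals(sims, theta, series.delta)
    times = series.times
    aois: list[ShortTimeAOI] = []
    for first, last in intervals:
        segment = [regions[i] for i in range(first, last + 1)]
        assert all(r is not None for r in segment)
        aois.append(build_aoi(segment, times[first : last + 1]))
    if not aois:
        raise EmptyRepresentativeError(
            f"no short-time AOI survived at theta={theta}; try a smaller theta"
        )
    fixations = tuple(
        Fixation(*aoi.center, aoi.b, aoi.e) for aoi in aois
    )
    return Scanpath("representative", fixations), tuple(aois)


def stasa(
    sample: ScanpathSample,
    delta: float = 30.0,
    theta: float = 0.5,
    *,
    eps_stride: int = 1,
) -> RepresentativeScanpath:
    """Run the full short-time-AOI aggregation at a fixed threshold.

    Raises :class:`EmptyRepresentativeError` when no interval survives the
    run rules at this theta (the caller may lower it or use
    :func:`tune_theta`).
    """
    if not 0 < theta < 1:
        raise ParameterError("theta must lie strictly between 0 and 1")
    series, regions = slice_regions(sample, delta, eps_stride=eps_stride)
    sims = similarity_series(regions)
    scanpath, aois = _assemble(series, regions, sims, theta)
    mean_d = representativeness(scanpath, sample, "scasim")
    return RepresentativeScanpath(scanpath, aois, theta, mean_d)


def tune_theta(
    sample: ScanpathSample,
    delta: float = 30.0,
    grid: Sequence[float] = DEFAULT_THETA_GRID,
    dissimilarity: str = "scasim",
    *,
    measure_config=None,
    eps_stride: int = 1,
    return_scores: bool = False,
):
    """Pick theta by minimizing mean dissimilarity to the sample.

    The slicing/clustering/hull stage does not depend on theta, so it runs
    once; each grid value only reruns interval detection and scoring.
    Thetas that produce no AOI are skipped; ties resolve to the smaller
    theta.  With ``return_scores`` the per-theta objective values are also
    returned (NaN for skipped thetas).
    """
    if len(grid) == 0:
        raise ParameterError("theta grid is empty")
    from .similarity import higher_is_better, representativeness as _rep

    series, regions = slice_regions(sample, delta, eps_stride=eps_stride)
    sims = similarity_series(regions)
    flip = -1.0 if higher_is_better(dissimilarity) else 1.0

    best: RepresentativeScanpath | None = None
    best_obj = np.inf
    scores: dict[float, float] = {}
    for theta in grid:
        try:
            scanpath, aois = _assemble(series, regions, sims, theta)
        except EmptyRepresentativeError:
            scores[float(theta)] = float("nan")
            continue
        obj = _rep(scanpath, sample, dissimilarity, measure_config)
        scores[float(theta)] = float(obj)
        if flip * obj < best_obj:  # strict: ties keep the smaller theta
            best_obj = flip * obj
            mean_scasim = (
                obj if dissimilarity == "scasim" and measure_config is None
                else _rep(scanpath, sample, "scasim")
            )
            best = RepresentativeScanpath(scanpath, aois, float(theta), float(mean_scasim))
    if best is None:
        raise EmptyRepresentativeError("every theta in the grid produced no AOI")
    logger.debug("tuned theta=%s over grid %s", best.theta_used, list(grid))
    if return_scores:
        return best, scores
    return best


def write_representative(
    rep: RepresentativeScanpath, scanpath_path: str | Path, aoi_path: str | Path
) -> None:
    """Write the representative scanpath CSV and the AOI polygon sidecar."""
    rows = [
        {"observer": rep.scanpath.observer_id, "x": f.x, "y": f.y, "b": f.b, "e": f.e}
        for f in rep.scanpath
    ]
    pd.DataFrame(rows, columns=["observer", "x", "y", "b", "e"]).to_csv(
        scanpath_path, index=False
    )
    aoi_rows = []
    for j, aoi in enumerate(rep.aois):
        for ci, comp in enumerate(aoi.region.components):
            for x, y in list(comp.exterior.coords)[:-1]:
                aoi_rows.append(
                    {"aoi": j, "component": ci, "x": x, "y": y, "b": aoi.b, "e": aoi.e}
                )
    pd.DataFrame(
        aoi_rows, columns=["aoi", "component", "x", "y", "b", "e"]
    ).to_csv(aoi_path, index=False)
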