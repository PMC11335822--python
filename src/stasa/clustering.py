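"""Per-slice density clustering with an adaptive (eps*, minPt*) search.

Each time slice holds at most one fixation position per observer.  The goal
is a single *major* cluster per slice: the densest group of observers whose
gaze agrees at that moment, with stragglers rejected as noise.  DBSCAN
provides the clustering; the parameter search makes it parameter-free from
the caller's perspective:

1. start wide: eps0 = stimulus width, minPt0 = ceil(M / 2) with M the
   number of scanpaths in the sample — one cluster containing everything;
2. shrink eps by one pixel at a time, splitting the blob and shedding
   outliers;
3. eps* is the smallest eps at which exactly one cluster survives before
   clusters vanish entirely;
4. with eps fixed at eps*, grow minPt one at a time; minPt* is the largest
   value that still leaves exactly one cluster.

Neighbour counts include the point itself (|N_eps(p)| >= minPt with
p in N_eps(p)), the convention scikit-learn uses.

Real slices can skip the unique-survivor state (two clusters die
simultaneously).  The search then backs off to the smallest eps with at
least one cluster and keeps the largest cluster there, breaking ties by
smaller mean pairwise distance and then by lowest point index; the
``unique_survivor`` flag records that this happened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN

from .errors import ParameterError
from .model import StimulusFrame
from .slicing import SlicePoint, TimeSlice

__all__ = ["DbscanParams", "MajorCluster", "dbscan", "find_major_cluster"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DbscanParams:
    """DBSCAN search radius (px) and neighbourhood count threshold."""

    eps: float
    min_pt: int

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ParameterError("eps must be positive")
        if self.min_pt < 1:
            raise ParameterError("min_pt must be at least 1")


@dataclass(frozen=True)
class MajorCluster:
    """The single dense cluster found on one slice."""

    t: float
    members: tuple[SlicePoint, ...]
    member_indices: tuple[int, ...]
    params_used: DbscanParams
    unique_survivor: bool = True

    @property
    def xy(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.members], dtype=float).reshape(-1, 2)


def dbscan(
    points: np.ndarray, params: DbscanParams
) -> tuple[list[np.ndarray], np.ndarray]:
    """Run DBSCAN with Euclidean metric on an (n, 2) point array.

    Returns ``(clusters, noise)`` where ``clusters`` is a list of index
    arrays (ordered by each cluster's smallest member index) and ``noise``
    holds the unclustered indices.  An empty input yields no clusters and
    empty noise.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        return [], np.array([], dtype=int)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pt).fit(points).labels_
    clusters = [
        np.flatnonzero(labels == lab) for lab in sorted(set(labels) - {-1})
    ]
    clusters.sort(key=lambda idx: idx[0])
    return clusters, np.flatnonzero(labels == -1)


def _select_largest(
    clusters: list[np.ndarray], dists: np.ndarray
) -> np.ndarray:
    """Largest cluster; ties to smaller mean pairwise distance, then order."""
    def key(idx: np.ndarray) -> tuple:
        if len(idx) > 1:
            mean_d = float(dists[np.ix_(idx, idx)].sum() / (len(idx) * (len(idx) - 1)))
        else:
            mean_d = 0.0
        return (-len(idx), mean_d, tuple(idx))

    return min(clusters, key=key)


def find_major_cluster(
    slc: TimeSlice,
    stimulus: StimulusFrame,
    m_scanpaths: int,
    *,
    min_pt0: int | None = None,
    eps_stride: int = 1,
) -> MajorCluster | None:
    """Run the four-step (eps*, minPt*) search on one slice.

    Returns ``None`` when not even the initial, maximally permissive
    parameters produce a cluster (fewer than minPt0 points on the slice).
    ``eps_stride`` coarsens the eps schedule for speed; the default of one
    pixel is the reference behaviour.
    """
    if eps_stride < 1:
        raise ParameterError("eps_stride must be >= 1")
    pts = slc.xy
    n = len(pts)
    if min_pt0 is None:
        min_pt0 = int(np.ceil(m_scanpaths / 2))
    min_pt0 = max(1, min_pt0)
    if n == 0:
        return None

    dists = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))

    # eps descent.  The clustering only changes when the eps-neighbourhood
    # graph changes, i.e. when the schedule crosses a pairwise distance, so
    # cached results are reused between those events.
    eps_schedule = np.arange(float(int(np.ceil(stimulus.width))), 0.0, -float(eps_stride))
    if len(eps_schedule) == 0:
        eps_schedule = np.array([stimulus.width])
    pairwise = np.unique(dists[np.triu_indices(n, k=1)]) if n > 1 else np.array([])

    best_single: tuple[float, list[np.ndarray]] | None = None  # smallest eps, 1 cluster
    best_any: tuple[float, list[np.ndarray]] | None = None  # smallest eps, >=1 cluster
    prev_edges = None
    clusters: list[np.ndarray] = []
    for eps in eps_schedule:
        edges = int(np.searchsorted(pairwise, eps, side="right"))
        if edges != prev_edges:
            clusters, _ = dbscan(pts, DbscanParams(eps, min_pt0))
            prev_edges = edges
        if not clusters:
            if best_single is None and best_any is None and eps == eps_schedule[0]:
                return None  # even the widest radius forms no cluster
            break
        best_any = (eps, clusters)
        if len(clusters) == 1:
            best_single = (eps, clusters)
    if best_single is None and best_any is None:
        return None

    if best_single is not None:
        eps_star, clusters = best_single
        unique = True
        member_idx = clusters[0]
    else:
        eps_star, clusters = best_any
        unique = len(clusters) == 1
        member_idx = _select_largest(clusters, dists)
        logger.debug(
            "slice t=%s: no unique-survivor eps; backed off to eps=%s with %d clusters",
            slc.t, eps_star, len(clusters),
        )

    # minPt ascent at fixed eps*.  Both exits — splitting into several
    # clusters and dropping to zero — terminate the loop.
    min_pt_star = min_pt0
    if unique:
        while min_pt_star < n:
            trial, _ = dbscan(pts, DbscanParams(eps_star, min_pt_star + 1))
            if len(trial) != 1:
                break
            min_pt_star += 1
            member_idx = trial[0]

    params = DbscanParams(eps_star, min_pt_star)
    logger.debug(
        "slice t=%s: eps*=%s minPt*=%d members=%d/%d",
        slc.t, eps_star, min_pt_star, len(member_idx), n,
    )
    return MajorCluster(
        t=slc.t,
        members=tuple(slc.points[i] for i in member_idx),
        member_indices=tuple(int(i) for i in member_idx),
        params_used=params,
        unique_survivor=unique,
    )
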