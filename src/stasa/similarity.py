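"""Scanpath similarity and dissimilarity measures.

Four measures that all respect the spatial, temporal and ordinal structure
of scanpaths:

* **Scasim** — a duration-weighted edit dissimilarity in milliseconds.
  Matching two fixations costs little when they are close (full cost
  ``|d1 - d2|``) and approaches deleting one and inserting the other
  (``d1 + d2``) as their separation grows, following a perceptual drop-off
  ``modulator ** distance`` with distance in visual degrees.  Lower is more
  similar; 0 means identical.
* **ScanMatch** — scanpaths become strings of grid-cell letters, one letter
  per temporal bin of fixation duration, globally aligned with
  Needleman-Wunsch under a substitution score ``threshold - cell distance``;
  the alignment score is normalized into [0, 1].  Higher is more similar.
* **MultiMatch** — scanpaths become saccade-vector sequences, aligned by a
  minimum-cost monotone path over vector differences; five aspect scores
  (vector, direction, length, position, duration) in [0, 1].
* **AOI Levenshtein** — plain edit distance between grid-cell strings.

:func:`representativeness` averages any of these over a sample, and
:func:`best_existing` picks the sample member optimizing that average —
the minScasim / maxScanMatch baselines a synthesized representative
scanpath must beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .model import Scanpath, ScanpathSample, StimulusFrame

__all__ = [
    "GridSpec",
    "ScanMatchConfig",
    "ScasimConfig",
    "MultiMatchConfig",
    "MultiMatchScores",
    "scasim",
    "scanmatch",
    "multimatch",
    "aoi_levenshtein",
    "representativeness",
    "best_existing",
    "MEASURES",
    "measure_value",
    "higher_is_better",
]


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class GridSpec:
    """Rectangular AOI grid over the stimulus (xbin columns, ybin rows)."""

    xbin: int
    ybin: int
    stimulus: StimulusFrame

    def __post_init__(self) -> None:
        if self.xbin < 1 or self.ybin < 1:
            raise ParameterError("grid must have at least one cell per axis")

    def cell_of(self, x: float, y: float, *, strict: bool = False) -> int:
        """Cell id (row-major) of a pixel position.

        Off-stimulus positions are clamped to the nearest cell unless
        ``strict`` is set, in which case they raise.
        """
        w, h = self.stimulus.width, self.stimulus.height
        if strict and not (0 <= x <= w and 0 <= y <= h):
            raise ParameterError(f"fixation ({x}, {y}) outside the stimulus frame")
        col = min(self.xbin - 1, max(0, int(np.clip(x, 0, w) / w * self.xbin)))
        row = min(self.ybin - 1, max(0, int(np.clip(y, 0, h) / h * self.ybin)))
        return row * self.xbin + col

    def cell_center(self, cell: int) -> tuple[float, float]:
        """Cell centre in cell units (column, row)."""
        return (cell % self.xbin + 0.5, cell // self.xbin + 0.5)


@dataclass(frozen=True)
class ScanMatchConfig:
    grid: GridSpec
    threshold: float = 3.5
    gap_value: float = 0.0
    temp_bin: float = 100.0
    strict_frame: bool = False

    def __post_init__(self) -> None:
        if self.temp_bin <= 0:
            raise ParameterError("temp_bin must be positive")


@dataclass(frozen=True)
class ScasimConfig:
    """Perceptual parameters of the Scasim cost model.

    ``modulator`` is the per-degree drop-off of positional acuity (0.83 in
    the original formulation).  ``distance_scale`` converts pixel distances
    into degree-equivalents; the default of 30 px/degree approximates a
    desktop eye-tracking geometry.  Set it to 1.0 for a pure-pixel mode.
    ``center`` is accepted for API symmetry with angular conversions but
    does not affect pairwise distances.
    """

    modulator: float = 0.83
    distance_scale: float = 30.0
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.modulator <= 1:
            raise ParameterError("modulator must be in (0, 1]")
        if self.distance_scale <= 0:
            raise ParameterError("distance_scale must be positive")


@dataclass(frozen=True)
class MultiMatchConfig:
    """Simplification thresholds for MultiMatch.

    Simplification merges successive small or same-direction saccades
    separated by brief fixations; it is off by default so scores reflect
    the raw sequences.
    """

    simplify: bool = False
    direction_threshold: float = 45.0  # degrees
    amplitude_fraction: float = 0.1  # of the screen diagonal
    duration_threshold: float = 300.0  # ms


@dataclass(frozen=True)
class MultiMatchScores:
    vector: float
    direction: float
    length: float
    position: float
    duration: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.vector, self.direction, self.length, self.position, self.duration]
        )

    @property
    def mean(self) -> float:
        return float(self.as_array().mean())


# ---------------------------------------------------------------------------
# Scasim


def scasim(s1: Scanpath, s2: Scanpath, config: ScasimConfig | None = None) -> float:
    """Duration-weighted edit dissimilarity between two scanpaths, in ms.

    Insertion/deletion of a fixation costs its duration; substituting
    fixation ``f`` for ``g`` costs ``|df - dg| * a + (df + dg) * (1 - a)``
    with acuity ``a = modulator ** (distance / distance_scale)``.
    Symmetric, non-negative, and 0 exactly for identical paths.
    """
    if len(s1) == 0 or len(s2) == 0:
        raise ParameterError("scasim requires non-empty scanpaths")
    cfg = config or ScasimConfig()
    p1, p2 = s1.positions, s2.positions
    d1, d2 = s1.durations, s2.durations
    n, m = len(s1), len(s2)

    dist = np.hypot(
        p1[:, 0, None] - p2[None, :, 0], p1[:, 1, None] - p2[None, :, 1]
    )
    acuity = cfg.modulator ** (dist / cfg.distance_scale)
    sub = (
        np.abs(d1[:, None] - d2[None, :]) * acuity
        + (d1[:, None] + d2[None, :]) * (1.0 - acuity)
    )

    dp = np.empty((n + 1, m + 1))
    dp[0, :] = np.concatenate(([0.0], np.cumsum(d2)))
    dp[1:, 0] = np.cumsum(d1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = min(
                dp[i - 1, j] + d1[i - 1],
                dp[i, j - 1] + d2[j - 1],
                dp[i - 1, j - 1] + sub[i - 1, j - 1],
            )
    return float(dp[n, m])


# ---------------------------------------------------------------------------
# ScanMatch


def _encode(sp: Scanpath, cfg: ScanMatchConfig) -> list[int]:
    out: list[int] = []
    for f in sp:
        cell = cfg.grid.cell_of(f.x, f.y, strict=cfg.strict_frame)
        reps = max(1, int(f.duration // cfg.temp_bin))
        out.extend([cell] * reps)
    return out


def _needleman_wunsch(
    a: list[int], b: list[int], sub: np.ndarray, gap: float
) -> float:
    n, m = len(a), len(b)
    dp = np.empty((n + 1, m + 1))
    dp[0, :] = gap * np.arange(m + 1)
    dp[:, 0] = gap * np.arange(n + 1)
    ai = np.asarray(a)
    bi = np.asarray(b)
    for i in range(1, n + 1):
        row_sub = sub[ai[i - 1], bi]
        prev = dp[i - 1]
        cur = dp[i]
        cur[0] = gap * i
        for j in range(1, m + 1):
            cur[j] = max(
                prev[j] + gap, cur[j - 1] + gap, prev[j - 1] + row_sub[j - 1]
            )
    return float(dp[n, m])


def scanmatch(s1: Scanpath, s2: Scanpath, config: ScanMatchConfig) -> float:
    """Grid-string alignment similarity in [0, 1] (1 = identical).

    Each fixation contributes one letter per full ``temp_bin`` of duration
    (at least one), so long fixations weigh more in the alignment.  The
    substitution score of two cells is ``threshold`` minus the Euclidean
    distance of their centres in cell units, clamped at zero; the global
    alignment score is divided by ``threshold`` times the longer string's
    length.
    """
    if len(s1) == 0 or len(s2) == 0:
        raise ParameterError("scanmatch requires non-empty scanpaths")
    a, b = _encode(s1, config), _encode(s2, config)
    g = config.grid
    centers = np.array([g.cell_center(c) for c in range(g.xbin * g.ybin)])
    dist = np.hypot(
        centers[:, 0, None] - centers[None, :, 0],
        centers[:, 1, None] - centers[None, :, 1],
    )
    sub = np.maximum(0.0, config.threshold - dist)
    score = _needleman_wunsch(a, b, sub, config.gap_value)
    norm = config.threshold * max(len(a), len(b))
    return float(min(1.0, max(0.0, score / norm)))


# ---------------------------------------------------------------------------
# MultiMatch


def _saccade_vectors(sp: Scanpath) -> np.ndarray:
    pos = sp.positions
    return pos[1:] - pos[:-1]


def _simplify(sp: Scanpath, cfg: MultiMatchConfig, diag: float) -> Scanpath:
    """Merge successive small / same-direction saccades over brief fixations."""
    fixes = list(sp.fixations)
    changed = True
    while changed and len(fixes) > 2:
        changed = False
        pos = np.array([[f.x, f.y] for f in fixes])
        vec = pos[1:] - pos[:-1]
        amp = np.hypot(vec[:, 0], vec[:, 1])
        for i in range(len(vec) - 1):
            mid = fixes[i + 1]
            if mid.duration >= cfg.duration_threshold:
                continue
            small = (
                amp[i] < cfg.amplitude_fraction * diag
                and amp[i + 1] < cfg.amplitude_fraction * diag
            )
            ang = _angle_between(vec[i], vec[i + 1])
            straight = np.degrees(ang) < cfg.direction_threshold
            if small or straight:
                del fixes[i + 1]
                changed = True
                break
    return Scanpath(sp.observer_id, tuple(fixes))


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(c))


def _align_path(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-cost monotone path through the cost matrix (all cells on it)."""
    n, m = cost.shape
    dp = np.full((n, m), np.inf)
    dp[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, dp[i - 1, j])
            if j > 0:
                best = min(best, dp[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, dp[i - 1, j - 1])
            dp[i, j] = cost[i, j] + best
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        cands = []
        if i > 0 and j > 0:
            cands.append((dp[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            cands.append((dp[i - 1, j], (i - 1, j)))
        if j > 0:
            cands.append((dp[i, j - 1], (i, j - 1)))
        _, (i, j) = min(cands, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return path


def multimatch(
    s1: Scanpath,
    s2: Scanpath,
    stimulus: StimulusFrame,
    config: MultiMatchConfig | None = None,
) -> MultiMatchScores:
    """Five-aspect saccade-vector similarity, each score in [0, 1].

    Saccade vectors are aligned along the cheapest monotone path through
    the matrix of vector differences; per aligned pair the vector
    difference (normalized by twice the screen diagonal), angular
    difference (by pi), amplitude difference and onset-fixation position
    difference (by the diagonal) and onset-duration difference (by the
    larger duration) are averaged and flipped into similarities.
    """
    cfg = config or MultiMatchConfig()
    diag = stimulus.diagonal
    if cfg.simplify:
        s1 = _simplify(s1, cfg, diag)
        s2 = _simplify(s2, cfg, diag)
    if len(s1) < 2 or len(s2) < 2:
        raise ParameterError(
            "multimatch requires at least two fixations (one saccade vector) per scanpath"
        )
    u, v = _saccade_vectors(s1), _saccade_vectors(s2)
    cost = np.hypot(
        u[:, 0, None] - v[None, :, 0], u[:, 1, None] - v[None, :, 1]
    )
    pairs = _align_path(cost)

    p1, p2 = s1.positions, s2.positions
    d1, d2 = s1.durations, s2.durations
    vec_d, dir_d, len_d, pos_d, dur_d = [], [], [], [], []
    for i, j in pairs:
        vec_d.append(np.hypot(*(u[i] - v[j])) / (2 * diag))
        dir_d.append(_angle_between(u[i], v[j]) / np.pi)
        len_d.append(abs(np.hypot(*u[i]) - np.hypot(*v[j])) / diag)
        pos_d.append(np.hypot(*(p1[i] - p2[j])) / diag)
        dur_d.append(abs(d1[i] - d2[j]) / max(d1[i], d2[j]))
    clamp = lambda x: float(min(1.0, max(0.0, 1.0 - np.mean(x))))
    return MultiMatchScores(
        vector=clamp(vec_d),
        direction=clamp(dir_d),
        length=clamp(len_d),
        position=clamp(pos_d),
        duration=clamp(dur_d),
    )


# ---------------------------------------------------------------------------
# AOI-string Levenshtein


def aoi_levenshtein(s1: Scanpath, s2: Scanpath, grid: GridSpec) -> int:
    """Plain edit distance between the scanpaths' grid-cell strings."""
    if len(s1) == 0 or len(s2) == 0:
        raise ParameterError("levenshtein requires non-empty scanpaths")
    a = [grid.cell_of(f.x, f.y) for f in s1]
    b = [grid.cell_of(f.x, f.y) for f in s2]
    return levenshtein(a, b)


def levenshtein(a: list, b: list) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[len(b)]


# ---------------------------------------------------------------------------
# representativeness (mean score to a sample) and existing-scanpath baseline


def _measure_scalar(measure: str, s1: Scanpath, s2: Scanpath, sample_stimulus, config):
    if measure == "scasim":
        return scasim(s1, s2, config)
    if measure == "scanmatch":
        if config is None:
            config = ScanMatchConfig(GridSpec(12, 8, sample_stimulus))
        return scanmatch(s1, s2, config)
    if measure == "multimatch":
        return multimatch(s1, s2, sample_stimulus, config).mean
    if measure == "levenshtein":
        grid = config or GridSpec(12, 8, sample_stimulus)
        return aoi_levenshtein(s1, s2, grid)
    raise ParameterError(f"unknown measure id {measure!r}")


#: measure id -> True when larger values mean more similar
MEASURES: dict[str, bool] = {
    "scasim": False,
    "scanmatch": True,
    "multimatch": True,
    "levenshtein": False,
}


def higher_is_better(measure: str) -> bool:
    try:
        return MEASURES[measure]
    except KeyError:
        raise ParameterError(f"unknown measure id {measure!r}") from None


def measure_value(
    measure: str,
    s1: Scanpath,
    s2: Scanpath,
    stimulus: StimulusFrame,
    config=None,
) -> float:
    """Scalar value of any registered measure (MultiMatch: mean of five)."""
    return float(_measure_scalar(measure, s1, s2, stimulus, config))


def representativeness(
    s: Scanpath,
    sample: ScanpathSample,
    measure: str = "scasim",
    config=None,
) -> float:
    """Mean measure value of ``s`` against every sample member.

    For dissimilarities (Scasim, Levenshtein) lower means more
    representative; for similarities (ScanMatch, MultiMatch) higher does.
    When ``s`` itself belongs to the sample it is not excluded from the
    mean — its self-score is optimal and identical across candidates, so
    rankings are unaffected.
    """
    if len(sample) == 0:
        raise ParameterError("sample is empty")
    vals = [
        measure_value(measure, s, member, sample.stimulus, config)
        for member in sample
    ]
    return float(np.mean(vals))


def best_existing(
    sample: ScanpathSample, measure: str = "scasim", config=None
) -> Scanpath:
    """The sample member optimizing mean measure value to all members.

    This is the existing-scanpath baseline (minScasim for Scasim,
    maxScanMatch for ScanMatch); ties break toward the earlier member.
    """
    if len(sample) < 2:
        raise ParameterError("need at least two scanpaths")
    better = max if higher_is_better(measure) else min
    scores = [representativeness(sp, sample, measure, config) for sp in sample]
    best_val = better(scores)
    return sample.scanpaths[scores.index(best_val)]
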