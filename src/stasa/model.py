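"""Domain types and tabular I/O for fixation scanpaths.

A fixation is a gaze pause described by the quadruple ``(x, y, b, e)``:
spatial position in pixel coordinates plus start and end time in
milliseconds.  A scanpath is the time-ordered fixation sequence of one
observer on one stimulus, and a sample bundles the scanpaths of several
observers viewing the same stimulus.

Eye trackers disagree about export layout, so :func:`read_sample` takes an
explicit column mapping instead of hard-coding header names.  Duration-only
exports (columns ``x, y, dur`` without timestamps) are supported by
reconstructing start/end times: the total saccade time is spread evenly
over one gap per fixation (see :func:`reconstruct_times`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleDurationsError, SchemaError, ScanpathValidationError

__all__ = [
    "Fixation",
    "Scanpath",
    "StimulusFrame",
    "ScanpathSample",
    "Violation",
    "reconstruct_times",
    "read_sample",
    "write_sample",
    "sample_to_frame",
    "validate",
]


@dataclass(frozen=True)
class Fixation:
    """One gaze pause: position in px, start/end time in ms (``b < e``)."""

    x: float
    y: float
    b: float
    e: float

    @property
    def duration(self) -> float:
        return self.e - self.b


@dataclass(frozen=True)
class Scanpath:
    """Time-ordered fixation sequence of one observer.

    Fixation intervals must interleave strictly: ``b1 < e1 <= b2 < e2 <= ...``.
    A zero-length saccade (``e_i == b_{i+1}``) is accepted as the degenerate
    limit produced by duration-only records whose fixations fill the whole
    viewing time.
    """

    observer_id: str
    fixations: tuple[Fixation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixations", tuple(self.fixations))

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of fixation centres in px."""
        return np.array([[f.x, f.y] for f in self.fixations], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)

    def shifted(self, offset: float) -> "Scanpath":
        """Return a copy with all times shifted by ``offset`` ms."""
        return Scanpath(
            self.observer_id,
            tuple(replace(f, b=f.b + offset, e=f.e + offset) for f in self.fixations),
        )


@dataclass(frozen=True)
class StimulusFrame:
    """Stimulus geometry and viewing duration.

    ``width`` doubles as the initial DBSCAN search radius, so it must be the
    true pixel width of the presented stimulus.
    """

    width: float
    height: float
    viewing_duration: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("stimulus dimensions must be positive")
        if self.viewing_duration <= 0:
            raise ValueError("viewing duration must be positive")

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))


@dataclass(frozen=True)
class ScanpathSample:
    """Scanpaths of M >= 2 observers on one stimulus."""

    scanpaths: tuple[Scanpath, ...]
    stimulus: StimulusFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "scanpaths", tuple(self.scanpaths))

    def __len__(self) -> int:
        return len(self.scanpaths)

    def __iter__(self):
        return iter(self.scanpaths)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate`."""

    observer_id: str
    fixation_index: int
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.observer_id}[{self.fixation_index}]: {self.rule}"


def reconstruct_times(
    durations: Sequence[float], total_time: float
) -> list[tuple[float, float]]:
    """Rebuild (start, end) timestamps from fixation durations.

    The total saccade time ``ts = total_time - sum(durations)`` is divided
    evenly into ``n`` gaps of ``ts/n``, one following each fixation, so

        b_i = sum_{h<i} d_h + (i-1) * ts/n,   e_i = b_i + d_i,

    and the last fixation ends at ``total_time - ts/n``.

    Parameters
    ----------
    durations : sequence of positive fixation durations, ms.
    total_time : total viewing time, ms.

    Raises
    ------
    InfeasibleDurationsError
        If the durations sum to more than ``total_time``.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one duration")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    total_fix = float(d.sum())
    if total_fix > total_time + 1e-9:
        raise InfeasibleDurationsError(
            f"durations sum to {total_fix} ms > total time {total_time} ms"
        )
    n = d.size
    gap = (total_time - total_fix) / n
    starts = np.concatenate(([0.0], np.cumsum(d)[:-1])) + gap * np.arange(n)
    return [(float(b), float(b + di)) for b, di in zip(starts, d)]


def _resolve(schema: Mapping[str, str], key: str, columns: Iterable[str]) -> str:
    name = schema.get(key, key)
    if name not in columns:
        raise SchemaError(f"column {name!r} (for field {key!r}) not found")
    return name


def read_sample(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    stimulus: StimulusFrame | None = None,
    *,
    sep: str | None = None,
    align_start: bool = True,
) -> ScanpathSample:
    """Read a long-format fixation table into a :class:`ScanpathSample`.

    One fixation per row; required fields are ``observer``, ``x``, ``y`` and
    either (``b``, ``e``) or ``dur``.  ``schema`` maps these field names to
    the file's actual column headers; keys equal to header names may be
    omitted.  Duration-only rows keep their file order per observer and are
    routed through :func:`reconstruct_times` against the stimulus viewing
    duration.

    With ``align_start`` (default), every scanpath is shifted so its first
    fixation starts at t = 0; pass ``align_start=False`` for pre-aligned
    data.
    """
    schema = dict(schema or {})
    if stimulus is None:
        raise ValueError("a StimulusFrame is required")
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep)

    obs_col = _resolve(schema, "observer", table.columns)
    x_col = _resolve(schema, "x", table.columns)
    y_col = _resolve(schema, "y", table.columns)
    has_times = schema.get("b", "b") in table.columns and schema.get("e", "e") in table.columns
    has_dur = schema.get("dur", "dur") in table.columns
    if not has_times and not has_dur:
        raise SchemaError("need either (b, e) timestamp columns or a dur column")

    scanpaths: list[Scanpath] = []
    for obs, group in table.groupby(obs_col, sort=True):
        obs = str(obs)
        if has_times:
            b_col = _resolve(schema, "b", table.columns)
            e_col = _resolve(schema, "e", table.columns)
            group = group.sort_values(b_col, kind="stable")
            times = list(zip(group[b_col].astype(float), group[e_col].astype(float)))
        else:
            dur_col = _resolve(schema, "dur", table.columns)
            try:
                times = reconstruct_times(
                    group[dur_col].astype(float).to_numpy(), stimulus.viewing_duration
                )
            except InfeasibleDurationsError as err:
                raise ScanpathValidationError(f"observer {obs}: {err}") from err
        fixations = tuple(
            Fixation(float(x), float(y), float(b), float(e))
            for (x, y), (b, e) in zip(zip(group[x_col], group[y_col]), times)
        )
        sp = Scanpath(obs, fixations)
        problems = _scanpath_violations(sp)
        if problems:
            raise ScanpathValidationError(
                f"observer {obs}: " + "; ".join(v.rule for v in problems)
            )
        if align_start:
            sp = sp.shifted(-sp.fixations[0].b)
        scanpaths.append(sp)
    return ScanpathSample(tuple(scanpaths), stimulus)


def sample_to_frame(sample: ScanpathSample) -> pd.DataFrame:
    """Flatten a sample into the long CSV layout (observer, x, y, b, e)."""
    rows = [
        {"observer": sp.observer_id, "x": f.x, "y": f.y, "b": f.b, "e": f.e}
        for sp in sample
        for f in sp
    ]
    return pd.DataFrame(rows, columns=["observer", "x", "y", "b", "e"])


def write_sample(sample: ScanpathSample, path: str | Path) -> None:
    """Write a sample as long-format CSV (one fixation per row)."""
    sample_to_frame(sample).to_csv(path, index=False)


def _scanpath_violations(sp: Scanpath) -> list[Violation]:
    out: list[Violation] = []
    if len(sp) == 0:
        out.append(Violation(sp.observer_id, -1, "scanpath is empty"))
        return out
    prev_end = -np.inf
    for i, f in enumerate(sp):
        if not (np.isfinite(f.x) and np.isfinite(f.y)):
            out.append(Violation(sp.observer_id, i, "non-finite position"))
        if not f.b < f.e:
            out.append(Violation(sp.observer_id, i, "zero or negative duration"))
        if f.b < prev_end:
            out.append(Violation(sp.observer_id, i, "overlaps previous fixation"))
        prev_end = f.e
    return out


def validate(sample: ScanpathSample) -> list[Violation]:
    """Check all type invariants; returns violations instead of raising."""
    out: list[Violation] = []
    if len(sample) < 2:
        out.append(Violation("<sample>", -1, "fewer than two scanpaths"))
    for sp in sample:
        out.extend(_scanpath_violations(sp))
    return out
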