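# Methods

## Model and assumptions

The package treats a scanpath as a strictly time-interleaved fixation
sequence (x, y, b, e)ᵢ with b₁ < e₁ ≤ b₂ < e₂ ≤ ⋯ ; the gaps between
fixations are saccades and carry no position.  A sample is M ≥ 2 such
scanpaths on one stimulus, start-time aligned (each scanpath's first b is
subtracted, so t = 0 is viewing onset; this can be disabled for data that
is already aligned to stimulus onset).  Aggregation assumes that a common
viewing strategy exists for at least half the sample during the periods it
is expressed: the major-cluster search seeds minPt at ⌈M/2⌉, so moments
where fewer than half the observers agree produce no short-time AOI.

Units are milliseconds and pixels throughout; areas are px².

### Timestamp reconstruction for duration-only exports

Some trackers export (x, y, duration) without timestamps.  Timestamps are
rebuilt by spreading the total saccade time ts = T − Σdᵢ evenly into n gaps
of ts/n, one *after* each fixation:

    bᵢ = Σ_{h<i} d_h + (i−1)·ts/n,    eᵢ = bᵢ + dᵢ,

so the last fixation ends at T − ts/n, one trailing gap before the nominal
trial end.  The trailing gap is a deliberate consequence of allocating n
gaps rather than n−1: it keeps the per-gap formula uniform and the
round-trip exact (durations and the equal-gap property are tested to
1e−9 relative).  Real saccade durations scale with amplitude, which this
even split ignores; with saccades typically ~15–20% of trial time the
induced per-fixation timing error is tens of milliseconds, comparable to
the slice spacing.

## Pipeline parameters

| parameter | default | unit | role |
|---|---|---|---|
| δ (`delta`) | 30 | ms | slice spacing; smaller is more accurate and slower. A tracker's sampling interval or a video's frame interval are natural alternatives. |
| ε₀ | stimulus width | px | DBSCAN search start; must be the true stimulus width. |
| minPt₀ | ⌈M/2⌉ | points | majority-consensus seed of the cluster search. |
| θ (`theta`) | tuned over 0.1…0.9 | — | minimum adjacent-slice polygon overlap (strict >) inside one AOI. |
| min slices / min duration | 3 / 100 | — / ms | AOI exclusion rules, enforced jointly. At δ = 30 ms the duration rule binds (3 slices span 60 ms); at δ ≥ 50 ms the slice rule binds. |
| k₀ | 3 | neighbours | concave-hull starting neighbourhood; k grows until the polygon is simple and contains all points, reaching the convex hull at the cap. |

Slice membership uses the half-open convention b ≤ t < e so a fixation
ending at t and one starting at t never share a slice.  An AOI's interval
runs from its first to its last slice time (no trailing δ): slices are
point samples and the conservative duration avoids overlapping adjacent
AOIs.

### The (ε*, minPt*) search

ε decreases in 1-px steps.  Since the clustering can only change when the
ε-neighbourhood graph changes, DBSCAN is re-run only when the schedule
crosses a pairwise distance — an exact, not approximate, shortcut (a test
compares against the literal 1-px trace).  ε* is the smallest ε with
exactly one surviving cluster before clusters vanish; minPt then grows
while exactly one cluster remains.  Neighbour counts include the point
itself, the scikit-learn convention; with the other convention every
minPt* shifts by one.  When the descent jumps from ≥ 2 clusters straight
to 0 — possible on real slices — the search backs off to the smallest ε
with ≥ 1 cluster and keeps the largest cluster (ties: smaller mean
pairwise distance, then lower point index), recording the event in
`MajorCluster.unique_survivor`.  The minPt ascent is skipped in that case,
since its invariant ("exactly one cluster") never held.

Clusters of fewer than three distinct (or collinear) points cannot carry a
polygon; they are replaced by a 1-px buffered disc or segment rather than
dropped, because a tight consensus is evidence *for* an AOI, not against
it.  The centroid of a ring-like AOI may fall outside the AOI; this is
accepted behaviour (the centroid is still the least-distance summary of
the region), which is why plots draw fixations together with their AOI
polygons.

## Similarity measures

**Scasim** (dissimilarity, ms): edit distance over fixations where
insertion/deletion costs a fixation's duration and substituting f for g
costs |d_f − d_g|·a + (d_f + d_g)(1 − a), a = modulator^(distance in
degrees), modulator 0.83 per degree.  Distances are converted from pixels
with `distance_scale` (px/degree), default 30 — a nominal desktop viewing
geometry.  A pure-pixel mode (`distance_scale = 1`) exists but is not the
default: 0.83^pixels saturates within ~20 px, collapsing the measure to a
duration-sum comparison that is nearly blind to position at stimulus
scale.  Users who know their screen geometry should set `distance_scale`
to their true px/degree.

**ScanMatch** (similarity, [0, 1]): fixations become grid-cell letters
(default 12 × 8 for baselines; 24 × 18 also common), each repeated
⌊duration / temp_bin⌋ times (minimum 1, so brief fixations are never
deleted by binning; temp_bin 100 ms).  Substitution score = threshold
(3.5) − Euclidean cell-centre distance in cell units, clamped at 0; global
Needleman–Wunsch with gap 0; normalized by threshold × longer string
length.  Off-stimulus fixations are clamped to the nearest cell (a strict
mode rejects them).

**MultiMatch** (five similarities, each [0, 1]): scanpaths become saccade
vector sequences; the alignment is the minimum-cost monotone path through
the matrix of vector differences (the DAG equivalent of the original
shortest-path formulation).  Per aligned pair: vector difference / 2·diag,
angular difference / π, amplitude difference / diag, onset-fixation
distance / diag, and duration difference / max duration, each averaged and
flipped to a similarity.  Optional simplification merges saccade pairs
that are both small (< 10% of the diagonal) or nearly straight (< 45°)
across a brief fixation (< 300 ms); it is off by default so scores reflect
the raw sequences.

**θ tuning** evaluates the slicing/clustering/hull stage once (it does not
depend on θ) and re-runs only interval detection and scoring per grid
value; candidates with no surviving AOI are skipped and ties go to the
smaller θ.  The default objective is Scasim because it is a single score
that needs no stimulus gridding; ScanMatch or mean MultiMatch can be
selected when a study has committed to those measures.

## Synthetic data

The generator emulates the free-viewing setup the method targets: 15
observers, 3-s trials, 800 × 600-px stimuli, with the sample-level
strategy planted as ordered spatio-temporal boxes.  Non-outlier observers
place one fixation uniformly inside each box over the box's interval,
perturbed by independent Gaussian jitter (sd `jitter_sd`) on each endpoint
and clipped to keep ordering (bounded retries, then error).  Outlier
observers receive the same number of fixations uniformly over the whole
stimulus, with viewing time partitioned evenly (80% fixation, the rest
saccades).  Gaussian rather than uniform jitter gives a smooth
desynchronization dial.

What the generator does **not** emulate: saliency-driven gaze, spatial
fixation scatter correlated over time within an observer,
amplitude-dependent saccade durations, drift/blink artifacts, or unequal
scanpath lengths.  Passing the recovery and dominance tests therefore
shows the pipeline is correct and robust to the modeled contamination —
not that it will dominate on any particular real data set.

## Numerical choices

- Geometry is floating-point; boolean operations snap coordinates to a
  1e−9-px grid to suppress sliver artifacts in unions.
- Zero-area regions raise degenerate-region signals rather than NaNs.
- The concave-hull walk starts at the lowest-y (then lowest-x) point and
  always takes the largest counter-clockwise rotation from the reversed
  incoming direction whose edge keeps the polygon simple; deterministic
  tie-breaks (stable sorts by distance and index) make hulls reproducible.
- DBSCAN cluster lists are ordered by smallest member index; all search
  tie-breaks are index-based, so identical slices always yield identical
  clusters.
- Test and acceptance problem sizes (10–20 replicates, M = 15–20, 3-s
  trials at δ = 30 ms) match the defaults above; they were chosen as the
  smallest sizes at which the seeded success-rate properties (≥ 80–90%
  over replicates) are meaningful.

## Known limitations

- Runtime is dominated by the per-slice parameter search (seconds per
  sample); `eps_stride` coarsens the ε schedule for speed at the cost of
  exactness of ε*.
- Samples whose consensus relocates faster than 3 slices / 100 ms produce
  no AOI at any θ (an explicit empty-representative signal, not a crash).
- The back-off rule when no ε yields exactly one cluster is a pragmatic
  extension of the search; its tie-breaks are deterministic but not
  canonical.
- With M identical scanpaths the representative reproduces fixation
  centres exactly; interval endpoints are quantized to the slice grid
  (error ≤ δ per endpoint).
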