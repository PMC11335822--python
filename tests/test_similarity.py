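import itertools

import numpy as np
import pytest

from stasa.errors import ParameterError
from stasa.model import Fixation, Scanpath, ScanpathSample, StimulusFrame
from stasa.similarity import (
    GridSpec,
    MultiMatchConfig,
    ScanMatchConfig,
    ScasimConfig,
    aoi_levenshtein,
    best_existing,
    levenshtein,
    multimatch,
    representativeness,
    scanmatch,
    scasim,
)

from conftest import make_scanpath


def random_scanpath(rng, stimulus, n=None, observer="r"):
    n = n or int(rng.integers(2, 7))
    durs = rng.uniform(100, 500, size=n)
    total = durs.sum() + 100 * n
    from stasa.model import reconstruct_times

    times = reconstruct_times(durs, total)
    return Scanpath(
        observer,
        tuple(
            Fixation(
                float(rng.uniform(0, stimulus.width)),
                float(rng.uniform(0, stimulus.height)),
                b,
                e,
            )
            for (b, e) in times
        ),
    )


class TestScasim:
    def test_identity_and_symmetry(self, rng, stimulus):
        for _ in range(10):
            s1 = random_scanpath(rng, stimulus)
            s2 = random_scanpath(rng, stimulus)
            assert scasim(s1, s1) == 0.0
            assert scasim(s1, s2) == pytest.approx(scasim(s2, s1))
            assert scasim(s1, s2) >= 0

    def test_colocated_insertion_costs_its_duration(self):
        # matching the shared fixation is free; the extra co-located 200-ms
        # fixation can only be inserted, at a cost of its duration
        s1 = make_scanpath("a", [100], [100], [(0, 500)])
        s2 = make_scanpath("b", [100, 100], [100, 100], [(0, 500), (600, 800)])
        assert scasim(s1, s2) == pytest.approx(200.0)

    def test_distant_substitution_approaches_delete_insert(self):
        s1 = make_scanpath("a", [0], [0], [(0, 500)])
        s2 = make_scanpath("b", [4000], [0], [(0, 300)])
        # acuity ~ 0 at >100 degrees: substitution cost -> d1 + d2
        assert scasim(s1, s2) == pytest.approx(800.0, rel=1e-6)

    def test_modulator_softens_nearby_mismatch(self):
        s1 = make_scanpath("a", [0], [0], [(0, 500)])
        s2 = make_scanpath("b", [30], [0], [(0, 300)])
        cfg = ScasimConfig(modulator=0.83, distance_scale=30.0)
        # one degree apart: cost = |500-300|*0.83 + 800*0.17
        assert scasim(s1, s2, cfg) == pytest.approx(200 * 0.83 + 800 * 0.17)


class TestScanMatch:
    @pytest.fixture
    def config(self, stimulus):
        return ScanMatchConfig(GridSpec(24, 18, stimulus))

    def test_identity(self, rng, stimulus, config):
        for _ in range(5):
            s = random_scanpath(rng, stimulus)
            assert scanmatch(s, s, config) == pytest.approx(1.0)

    def test_symmetry_and_range(self, rng, stimulus, config):
        for _ in range(5):
            s1, s2 = random_scanpath(rng, stimulus), random_scanpath(rng, stimulus)
            v = scanmatch(s1, s2, config)
            assert v == pytest.approx(scanmatch(s2, s1, config))
            assert 0.0 <= v <= 1.0

    def test_opposite_corners_floor_score(self, stimulus, config):
        # cell distance hypot(23, 17) >> threshold 3.5, so the single
        # substitution scores 0 and the normalized score sits at the floor
        s1 = make_scanpath("a", [1], [1], [(0, 100)])
        s2 = make_scanpath("b", [799], [599], [(0, 100)])
        assert scanmatch(s1, s2, config) == 0.0

    def test_duration_scaling_invariance(self, stimulus, config):
        # doubling the durations of BOTH paths doubles every letter run and
        # the normalization alike, leaving the score unchanged
        a1 = make_scanpath("a", [100, 300], [100, 300], [(0, 200), (300, 500)])
        b1 = make_scanpath("b", [120, 500], [100, 250], [(0, 200), (300, 500)])
        a2 = make_scanpath("a", [100, 300], [100, 300], [(0, 400), (600, 1000)])
        b2 = make_scanpath("b", [120, 500], [100, 250], [(0, 400), (600, 1000)])
        assert scanmatch(a2, b2, config) == pytest.approx(scanmatch(a1, b1, config))
        assert scanmatch(a2, a2, config) == pytest.approx(1.0)

    def test_temporal_weighting_changes_encoding(self, stimulus, config):
        # a 250-ms fixation repeats its letter twice under a 100-ms bin
        near = make_scanpath("a", [100, 120], [100, 100], [(0, 250), (300, 400)])
        far = make_scanpath("b", [100, 700], [100, 500], [(0, 250), (300, 400)])
        assert scanmatch(near, near, config) == pytest.approx(1.0)
        assert scanmatch(near, far, config) < 1.0


class TestMultiMatch:
    def test_identity_all_ones(self, rng, stimulus):
        for _ in range(5):
            s = random_scanpath(rng, stimulus, n=4)
            scores = multimatch(s, s, stimulus)
            assert np.allclose(scores.as_array(), 1.0)

    def test_translation_only_moves_position(self, stimulus):
        s1 = make_scanpath("a", [100, 300, 200], [100, 200, 400],
                           [(0, 300), (400, 700), (800, 1100)])
        s2 = Scanpath(
            "b", tuple(Fixation(f.x + 100, f.y, f.b, f.e) for f in s1)
        )
        scores = multimatch(s1, s2, stimulus)
        assert scores.vector == pytest.approx(1.0)
        assert scores.direction == pytest.approx(1.0)
        assert scores.length == pytest.approx(1.0)
        assert scores.duration == pytest.approx(1.0)
        assert scores.position == pytest.approx(1.0 - 100 / stimulus.diagonal)

    def test_duration_doubling_halves_duration_score(self, stimulus):
        s1 = make_scanpath("a", [100, 300, 200], [100, 200, 400],
                           [(0, 300), (400, 700), (800, 1100)])
        s2 = make_scanpath("b", [100, 300, 200], [100, 200, 400],
                           [(0, 600), (800, 1400), (1600, 2200)])
        scores = multimatch(s1, s2, stimulus)
        assert scores.vector == pytest.approx(1.0)
        assert scores.position == pytest.approx(1.0)
        assert scores.duration == pytest.approx(0.5)

    def test_symmetry_and_range(self, rng, stimulus):
        for _ in range(5):
            s1 = random_scanpath(rng, stimulus, n=4)
            s2 = random_scanpath(rng, stimulus, n=3)
            a = multimatch(s1, s2, stimulus).as_array()
            b = multimatch(s2, s1, stimulus).as_array()
            assert np.allclose(a, b)
            assert np.all((0 <= a) & (a <= 1))

    def test_single_fixation_rejected(self, stimulus):
        s1 = make_scanpath("a", [1], [1], [(0, 100)])
        s2 = make_scanpath("b", [1, 2], [1, 2], [(0, 100), (200, 300)])
        with pytest.raises(ParameterError, match="two fixations"):
            multimatch(s1, s2, stimulus)

    def test_simplification_merges_straight_saccades(self, stimulus):
        # three collinear hops with a brief middle fixation reduce to one
        # saccade, making the simplified path identical to the direct one
        hops = make_scanpath("a", [100, 200, 300], [100, 100, 100],
                             [(0, 400), (450, 550), (600, 1000)])
        direct = make_scanpath("b", [100, 300], [100, 100], [(0, 400), (600, 1000)])
        cfg = MultiMatchConfig(simplify=True, duration_threshold=200.0)
        scores = multimatch(hops, direct, stimulus, cfg)
        assert scores.vector == pytest.approx(1.0)
        assert scores.position == pytest.approx(1.0)


def brute_levenshtein(a, b):
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        brute_levenshtein(a[1:], b) + 1,
        brute_levenshtein(a, b[1:]) + 1,
        brute_levenshtein(a[1:], b[1:]) + (a[0] != b[0]),
    )


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected", [("AB", "AB", 0), ("AB", "AC", 1), ("ABC", "BCA", 2)]
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(list(a), list(b)) == expected

    def test_matches_brute_force_short_strings(self, rng):
        for _ in range(50):
            a = list(rng.integers(0, 4, size=rng.integers(0, 7)))
            b = list(rng.integers(0, 4, size=rng.integers(0, 7)))
            assert levenshtein(a, b) == brute_levenshtein(a, b)

    def test_grid_encoding(self, stimulus):
        grid = GridSpec(12, 8, stimulus)
        s1 = make_scanpath("a", [10, 700], [10, 500], [(0, 100), (200, 300)])
        s2 = make_scanpath("b", [10, 10], [10, 10], [(0, 100), (200, 300)])
        assert aoi_levenshtein(s1, s1, grid) == 0
        assert aoi_levenshtein(s1, s2, grid) == 1


class TestRepresentativeness:
    def test_self_sample_optima(self, simple_scanpath, stimulus):
        sample = ScanpathSample(
            tuple(
                Scanpath(f"o{i}", simple_scanpath.fixations) for i in range(4)
            ),
            stimulus,
        )
        assert representativeness(simple_scanpath, sample, "scasim") == 0.0
        assert representativeness(simple_scanpath, sample, "scanmatch") == pytest.approx(1.0)

    def test_mean_of_pairwise_values(self, stimulus):
        s = make_scanpath("s", [100], [100], [(0, 500)])
        a = make_scanpath("a", [100], [100], [(0, 500)])
        b = make_scanpath("b", [4000], [100], [(0, 300)])
        sample = ScanpathSample((a, b), stimulus)
        expected = (scasim(s, a) + scasim(s, b)) / 2
        assert representativeness(s, sample, "scasim") == pytest.approx(expected)


class TestBestExisting:
    def test_middle_of_three_wins(self, stimulus):
        sps = tuple(
            make_scanpath(f"o{i}", [x], [100], [(0, 500)])
            for i, x in enumerate([0, 50, 100])
        )
        sample = ScanpathSample(sps, stimulus)
        assert best_existing(sample, "scasim").observer_id == "o1"

    def test_matches_exhaustive_enumeration(self, rng, stimulus):
        sps = tuple(random_scanpath(rng, stimulus, observer=f"o{i}") for i in range(5))
        sample = ScanpathSample(sps, stimulus)
        for measure, better in [("scasim", min), ("scanmatch", max)]:
            means = [
                np.mean([
                    __import__("stasa.similarity", fromlist=["measure_value"])
                    .measure_value(measure, s, t, stimulus)
                    for t in sps
                ])
                for s in sps
            ]
            expected = sps[means.index(better(means))]
            assert best_existing(sample, measure) == expected

    def test_duplicate_pair_ties_to_first(self, stimulus):
        a = make_scanpath("a", [100], [100], [(0, 500)])
        b = make_scanpath("b", [100], [100], [(0, 500)])
        sample = ScanpathSample((a, b), stimulus)
        assert best_existing(sample, "scasim").observer_id == "a"
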