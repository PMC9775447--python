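import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from opibs.ordinal import (
    OPConfig,
    coarse_grain,
    opibs_distance,
    ordinal_pattern,
    parameter_sweep,
    pattern_sequence,
    rank_profile,
    rank_profile_from_ids,
    recording_opibs,
)
from opibs.preprocess import PPISeries, SegmentSet, segment

from _oracles import (
    brute_coarse,
    brute_distance,
    brute_pattern_id,
    brute_profile_from_probs,
    brute_recording_opibs,
)


class TestCoarseGrain:
    def test_scale_one_is_identity(self, rng):
        x = rng.uniform(0.5, 1.5, 37)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_block_means(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5, 6], 3), [2.0, 5.0])

    def test_matches_loop_oracle_at_scale_seven(self, rng):
        x = rng.uniform(0.5, 1.5, 100)
        out = coarse_grain(x, 7)
        assert len(out) == 14
        np.testing.assert_allclose(out, brute_coarse(list(x), 7), atol=1e-15)

    def test_scale_exceeding_length_raises(self):
        with pytest.raises(ValueError):
            coarse_grain([1.0, 2.0], 3)


class TestOrdinalPattern:
    def test_tied_triple_maps_to_catalogue_index_five(self):
        # ties resolve by time of appearance: (1.01, 1.01, 0.90) -> (3, 1, 2)
        assert ordinal_pattern([1.01, 1.01, 0.90]) == 5

    def test_monotone_triples_bound_the_catalogue(self):
        assert ordinal_pattern([0.8, 0.9, 1.0]) == 1
        assert ordinal_pattern([1.0, 0.9, 0.8]) == 6

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_bijection_onto_catalogue(self, m):
        """Strict orderings of m distinct values hit each id in 1..m! once."""
        ids = {
            ordinal_pattern(list(p)) for p in itertools.permutations(range(m))
        }
        assert ids == set(range(1, math.factorial(m) + 1))

    @given(st.lists(st.floats(0.3, 3.0), min_size=2, max_size=6))
    def test_agrees_with_brute_force_catalogue(self, window):
        assert ordinal_pattern(window) == brute_pattern_id(window)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            ordinal_pattern([1.0])


class TestPatternSequence:
    def test_monotone_series_gives_all_first_patterns(self):
        ops = pattern_sequence(np.linspace(0.5, 1.5, 12), OPConfig(s=1, m=3))
        assert np.all(ops.pattern_ids == 1)

    def test_sequence_length(self):
        ops = pattern_sequence(np.arange(10.0), OPConfig(s=1, m=3, tau=1))
        assert len(ops) == 8

    def test_sawtooth_alternates_for_word_length_two(self):
        saw = np.array([1.0, 2.0] * 5)
        ops = pattern_sequence(saw, OPConfig(s=1, m=2))
        np.testing.assert_array_equal(ops.pattern_ids, [1, 2, 1, 2, 1, 2, 1, 2, 1])

    def test_delay_two_skips_intermediate_samples(self):
        x = np.array([1.0, 9.0, 2.0, 8.0, 3.0, 7.0])  # odd samples fall, even rise
        ops = pattern_sequence(x, OPConfig(s=1, m=3, tau=2))
        np.testing.assert_array_equal(ops.pattern_ids, [1, 6])

    def test_coarse_grain_scale_one_then_embed_matches_direct(self, rng):
        x = rng.uniform(0.5, 1.5, 50)
        cfg = OPConfig(s=1, m=4)
        direct = pattern_sequence(x, cfg)
        via_cg = pattern_sequence(coarse_grain(x, 1), cfg)
        np.testing.assert_array_equal(direct.pattern_ids, via_cg.pattern_ids)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            pattern_sequence(np.ones(3), OPConfig(s=1, m=5))


class TestRankProfile:
    def test_frequency_ranking_with_serial_tie_rule(self):
        rp = rank_profile_from_ids(np.array([5, 5, 1, 6, 1, 1]), 6)
        np.testing.assert_array_equal(rp.ranks, [1, 4, 5, 6, 2, 3])
        np.testing.assert_allclose(rp.probs.sum(), 1.0)

    def test_single_repeated_pattern(self):
        rp = rank_profile_from_ids(np.array([4, 4, 4]), 6)
        assert rp.ranks[3] == 1 and rp.probs[3] == 1.0

    def test_uniform_occurrence_ranks_by_serial_number(self):
        rp = rank_profile_from_ids(np.arange(1, 7), 6)
        np.testing.assert_array_equal(rp.ranks, np.arange(1, 7))

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            rank_profile_from_ids(np.array([], dtype=int), 6)


def _profile_from_probs(probs_by_id, T):
    """Build a package RankProfile through the public counting path."""
    counts = {i: int(round(probs_by_id.get(i, 0.0) * 10))
              for i in range(1, T + 1)}
    ids = np.repeat(list(counts), list(counts.values()))
    return rank_profile_from_ids(ids, T)


class TestOpibsDistance:
    def test_identical_profiles_have_zero_distance(self, rng):
        rp = rank_profile_from_ids(rng.integers(1, 7, 50), 6)
        assert opibs_distance(rp, rp) == 0.0

    def test_hand_computed_six_class_value(self):
        p1 = _profile_from_probs({1: 0.5, 2: 0.3, 3: 0.2}, 6)
        p2 = _profile_from_probs({1: 0.2, 2: 0.5, 3: 0.3}, 6)
        d = opibs_distance(p1, p2)
        # frozen from the spreadsheet-style evaluation of the weighted rank sum
        assert d == pytest.approx(0.2207675112906912, abs=1e-12)
        oracle = brute_distance(
            brute_profile_from_probs({1: 0.5, 2: 0.3, 3: 0.2}, 6),
            brute_profile_from_probs({1: 0.2, 2: 0.5, 3: 0.3}, 6),
        )
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_profiles_use_uniform_weights(self):
        p1 = rank_profile_from_ids(np.full(5, 2), 6)
        p2 = rank_profile_from_ids(np.full(5, 5), 6)
        # ranks differ only via the swapped top class: |dr| = (1,0,0,0,1,0)*?
        d = opibs_distance(p1, p2)
        expected = np.abs(p1.ranks - p2.ranks).sum() / 6 / 6
        assert d == pytest.approx(expected, abs=1e-15)

    def test_mismatched_class_counts_raise(self):
        p1 = rank_profile_from_ids(np.array([1, 2]), 6)
        p2 = rank_profile_from_ids(np.array([1, 2]), 24)
        with pytest.raises(ValueError):
            opibs_distance(p1, p2)


class TestRecordingOpibs:
    def _segments(self, arrays):
        return SegmentSet(segments=[PPISeries(np.asarray(a)) for a in arrays],
                          segment_length_s=300.0, recording_id="t")

    def test_identical_segments_give_zero(self, rng):
        x = rng.uniform(0.7, 1.3, 150)
        segs = self._segments([x, x, x])
        assert recording_opibs(segs, OPConfig(s=2, m=3)) == 0.0

    def test_mean_of_adjacent_pair_distances(self, rng):
        arrays = [rng.uniform(0.7, 1.3, 150) for _ in range(3)]
        cfg = OPConfig(s=2, m=3)
        mean, pairs = recording_opibs(self._segments(arrays), cfg, return_pairs=True)
        assert len(pairs) == 2
        assert mean == pytest.approx(sum(pairs) / 2)

    def test_matches_brute_force_on_synthetic_recording(self):
        from opibs.synth import SynthConfig, generate_recording

        cfg = SynthConfig(duration_s=1800.0, event_rate_per_h=40.0, seed=21)
        ppi, _ = generate_recording(cfg)
        segs = segment(ppi, 300.0)
        opcfg = OPConfig(s=7, m=5)
        val = recording_opibs(segs, opcfg)
        oracle = brute_recording_opibs(
            [list(s.intervals) for s in segs], s=7, m=5
        )
        assert val == pytest.approx(oracle, abs=1e-12)

    def test_short_segments_are_skipped(self, rng):
        arrays = [rng.uniform(0.7, 1.3, 150), np.array([1.0, 1.1, 0.9]),
                  rng.uniform(0.7, 1.3, 150)]
        cfg = OPConfig(s=2, m=3)
        _, pairs = recording_opibs(self._segments(arrays), cfg, return_pairs=True)
        assert len(pairs) == 1  # the 3-beat segment cannot be embedded

    def test_fewer_than_two_usable_segments_raises(self, rng):
        segs = self._segments([rng.uniform(0.7, 1.3, 150)])
        with pytest.raises(ValueError):
            recording_opibs(segs, OPConfig(s=2, m=3))


class TestParameterSweep:
    def test_matrix_shape_and_range(self, small_cohort):
        recs = [segment(r.ppi, 300.0, recording_id=r.recording_id)
                for r in small_cohort]
        ahi = np.array([r.ahi for r in small_cohort])
        mat, best = parameter_sweep(recs, ahi, range(4, 11), range(2, 7))
        assert mat.shape == (7, 5)
        vals = mat.to_numpy().ravel()
        assert np.all((vals[np.isfinite(vals)] >= 0) & (vals[np.isfinite(vals)] <= 1))
        assert best[0] in range(4, 11) and best[1] in range(2, 7)

    def test_zero_variance_ahi_rejected(self, small_cohort):
        recs = [segment(r.ppi, 300.0) for r in small_cohort[:3]]
        with pytest.raises(ValueError, match="zero variance"):
            parameter_sweep(recs, np.array([5.0, 5.0, 5.0]))

    def test_identical_recordings_with_distinct_ahi_flagged(self):
        x = np.linspace(0.5, 1.5, 150)  # monotone -> single pattern everywhere
        recs = [SegmentSet([PPISeries(x), PPISeries(x)]) for _ in range(3)]
        with pytest.raises(ValueError, match="undefined"):
            parameter_sweep(recs, np.array([1.0, 10.0, 40.0]),
                            s_range=[2], m_range=[3, 4])
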