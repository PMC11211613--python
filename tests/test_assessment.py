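"""Cycle segmentation, episode/sequence detection, success tables."""

import numpy as np
import pytest

from thetagamma.assessment import (
    SuccessTable,
    detect_episode,
    detect_sequence,
    episode_crossing_time,
    find_hybrids,
    success_table,
    superposition_score,
    theta_cycles,
)
from thetagamma.sequences import Episode, SequenceSet


DT = 1e-4


def _square_theta(freq, duty, dur, dt=DT):
    t = np.arange(0, dur, dt)
    return np.where((t * freq) % 1.0 < duty, 5.0, 0.0)


class TestThetaCycles:
    def test_four_hz_segmentation(self):
        # the wave starts on, so the first upward crossing is at 0.25 s
        cycles, periodic = theta_cycles(_square_theta(4.0, 0.5, 1.3), DT)
        assert periodic
        assert len(cycles) == 4  # only fully contained cycles count
        for c in cycles:
            assert c.start < c.on_end <= c.end
            assert (c.end - c.start) * DT == pytest.approx(0.25, abs=2 * DT)

    def test_six_hz_has_more_cycles(self):
        cycles, _ = theta_cycles(_square_theta(6.0, 0.5, 1.3), DT)
        assert len(cycles) == 6

    def test_constant_trace_flagged_degenerate(self):
        cycles, periodic = theta_cycles(np.full(10000, 2.4), DT)
        assert cycles == [] and not periodic

    def test_cycles_are_ordered_and_non_overlapping(self):
        cycles, _ = theta_cycles(_square_theta(4.0, 0.4, 2.0), DT)
        for a, b in zip(cycles, cycles[1:]):
            assert a.end == b.start


class TestDetectEpisode:
    ep = Episode(id=1, features=frozenset({1, 2, 3}))
    cyc = (0, 100)

    def test_all_zero_trace_never_detects(self):
        z = np.zeros((100, 5))
        assert not detect_episode(z, self.ep, self.cyc)

    def test_constructed_simultaneous_crossing_detects(self):
        z = np.zeros((100, 5))
        z[40, [0, 1, 2]] = 4.0
        assert detect_episode(z, self.ep, self.cyc)
        assert episode_crossing_time(z, self.ep, self.cyc) == 40

    def test_disjoint_crossings_never_detect(self):
        """Features crossing threshold at different steps (never together)
        must not count; verified against an exhaustive per-step scan."""
        z = np.zeros((100, 5))
        z[10, 0] = 4.5
        z[20, 1] = 4.5
        z[30, 2] = 4.5
        assert not detect_episode(z, self.ep, self.cyc)
        brute = any((z[t, [0, 1, 2]] > 3.5).all() for t in range(100))
        assert not brute

    def test_feature_outside_layer_raises(self):
        from thetagamma.units import ConfigurationError

        with pytest.raises(ConfigurationError):
            detect_episode(np.zeros((10, 3)), Episode(id=1, features=frozenset({9})),
                           (0, 10))


class TestDetectSequence:
    seq = [Episode(id=1, features=frozenset({1})),
           Episode(id=2, features=frozenset({2})),
           Episode(id=3, features=frozenset({3}))]

    def _trace(self, times):
        z = np.zeros((100, 3))
        for col, t in enumerate(times):
            if t is not None:
                z[t, col] = 4.0
        return z

    def test_all_in_order(self):
        ok, whole = detect_sequence(self._trace([10, 20, 30]), self.seq, (0, 100))
        assert ok == [True, True, True] and whole

    def test_missing_episode_does_not_forfeit_later_ones(self):
        ok, whole = detect_sequence(self._trace([None, 20, 30]), self.seq, (0, 100))
        assert ok == [False, True, True] and not whole

    def test_out_of_order_detection_is_incorrect(self):
        """Scrambled first-crossing order fails exactly the out-of-order
        position; verified against brute-force comparison of crossing
        times."""
        times = [30, 10, 50]
        ok, whole = detect_sequence(self._trace(times), self.seq, (0, 100))
        assert ok == [True, False, True] and not whole
        # brute force: position k is correct iff detected later than every
        # detected earlier position
        brute = []
        prev = -1
        for t in times:
            brute.append(t is not None and t > prev)
            prev = t if t is not None else prev
        assert ok == brute

    def test_tie_counts_as_ordering_failure(self):
        ok, _ = detect_sequence(self._trace([10, 10, 30]), self.seq, (0, 100))
        assert ok == [True, False, True]


class TestSuccessTable:
    def test_zero_weight_network_scores_all_zero(self, orth_set):
        from thetagamma.network import build_network

        tab = success_table(build_network(), orth_set, n_runs=2, duration=1.0, seed=1)
        assert np.all(tab.values == 0.0)

    def test_percentage_granularity_matches_cycle_count(self, basal_table_orth):
        """Every table entry must be an exact multiple of
        100 / (evaluated cycles per sequence)."""
        tab = basal_table_orth
        n_cycles = tab.n_runs * tab.cycles_per_run[0]
        step = 100.0 / n_cycles
        assert np.allclose(np.round(tab.values / step), tab.values / step, atol=1e-6)

    def test_mean_row_is_unweighted_sequence_mean(self, basal_table_orth):
        assert np.allclose(basal_table_orth.mean_row,
                           basal_table_orth.values.mean(axis=0))

    def test_table_frame_layout(self, basal_table_orth):
        df = basal_table_orth.to_frame()
        assert list(df.index) == ["Sequence 1", "Sequence 2", "Sequence 3", "Mean"]
        assert list(df.columns) == [f"Episode {k}" for k in range(1, 6)]


class TestSuperposition:
    def test_single_episode_scores_zero(self, orth_set):
        z = np.zeros((100, 75))
        ep = orth_set.episodes[1]
        z[40, [f - 1 for f in ep.sorted_features]] = 4.5
        assert superposition_score(z, orth_set, (0, 100)) == 0

    def test_two_disjoint_episodes_counted_by_exhaustive_scan(self, orth_set):
        z = np.zeros((100, 75))
        cols = [f - 1 for f in orth_set.episodes[1].sorted_features]
        cols += [f - 1 for f in orth_set.episodes[6].sorted_features]
        z[40:43, cols] = 4.5
        assert superposition_score(z, orth_set, (0, 100)) == 3

    def test_shared_feature_pair_excluded(self, nonorth_set):
        """Co-activation of two episodes that share a feature is not
        delusion-like superposition."""
        z = np.zeros((100, 75))
        cols = [f - 1 for f in nonorth_set.episodes[2].sorted_features]
        cols += [f - 1 for f in nonorth_set.episodes[14].sorted_features]
        z[40, cols] = 4.5
        assert superposition_score(z, nonorth_set, (0, 100)) == 0


class TestHybridDetector:
    def _trace_for(self, ss, order, spacing=10):
        z = np.zeros((40 + spacing * len(order), 75))
        for k, eid in enumerate(order):
            cols = [f - 1 for f in ss.episodes[eid].sorted_features]
            z[10 + spacing * k, cols] = 4.5
        return z

    def test_prefix_plus_suffix_at_shared_junction(self, nonorth_set):
        """Episodes [6,7] then [4,5]: episode 7 shares feature 33 with
        episode 3, whose successor is episode 4 — a dream-like hybrid."""
        z = self._trace_for(nonorth_set, [6, 7, 4, 5])
        hy = find_hybrids(z, nonorth_set, (0, z.shape[0]))
        assert any(pre == [6, 7] and suf[0] == 4 for pre, suf in hy)

    def test_plain_sequences_produce_no_hybrid(self, nonorth_set):
        z = self._trace_for(nonorth_set, [6, 7, 8, 9, 10])
        assert find_hybrids(z, nonorth_set, (0, z.shape[0])) == []

    def test_orthogonal_material_cannot_hybridize(self, orth_set):
        z = self._trace_for(orth_set, [1, 2, 8, 9])
        assert find_hybrids(z, orth_set, (0, z.shape[0])) == []
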