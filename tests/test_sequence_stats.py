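import math
from datetime import date, datetime, time, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from songseq.annotation_io import END
from songseq.sequence_stats import (
    BinPoint,
    UndefinedLearningError,
    best_training_day,
    binned_learning_curve,
    bout_transition_entropy,
    branch_renditions,
    chunk_durations,
    degree_of_learning,
    last_complete_bin,
    mean_transition_entropy,
    relative_learning_speed,
    song_rate,
    targeting_accuracy,
    transition_table,
)

from conftest import T0, bout_from_labels, random_bouts


class TestTransitionTable:
    def test_direct_count_including_end(self):
        bouts = [bout_from_labels(s) for s in ("xa", "xl", "xa", "x")]
        tab = transition_table(bouts, "x")
        assert tab.counts == {"a": 2, "l": 1, END: 1}
        assert tab.probability("a") == 0.5
        assert tab.n_renditions == 4

    def test_catch_only_counts_flagged_renditions(self):
        bouts = [bout_from_labels(s) for s in ("xa", "xl", "xa")]
        for b in bouts:
            rends = branch_renditions(b, "x")
            for r in rends:
                r.is_catch = r.outcome == "l"  # only non-target are catch
            b.renditions = rends
        tab = transition_table(bouts, "x", catch_only=True)
        assert tab.counts == {"l": 1}
        assert tab.probability("a") == 0.0

    def test_absent_branch_flagged_undefined(self):
        tab = transition_table([bout_from_labels("abc")], "q")
        assert not tab.defined
        assert math.isnan(tab.probability("a"))

    def test_matches_recount_oracle_on_random_instances(self, rng):
        from oracles import recount_transitions

        for _ in range(100):
            bouts = random_bouts(rng, int(rng.integers(5, 25)))
            tab = transition_table(bouts, "x")
            assert tab.counts == recount_transitions([b.labels for b in bouts], "x")
            if tab.defined:
                assert sum(tab.probabilities.values()) == pytest.approx(1.0)

    def test_counts_invariant_under_bout_reordering(self, rng):
        bouts = random_bouts(rng, 30)
        tab1 = transition_table(bouts, "x")
        tab2 = transition_table(list(reversed(bouts)), "x")
        assert tab1.counts == tab2.counts


class TestDegreeOfLearning:
    @pytest.mark.parametrize("baseline,best,expected",
                             [(0.5, 0.25, 50.0), (0.4, 0.4, 0.0), (0.2, 0.3, -50.0)])
    def test_formula(self, baseline, best, expected):
        assert degree_of_learning(baseline, best) == pytest.approx(expected)

    def test_zero_baseline_is_undefined(self):
        with pytest.raises(UndefinedLearningError):
            degree_of_learning(0.0, 0.1)


class TestBestTrainingDay:
    def test_argmin(self):
        per_day = {"T1": (0.4, 10), "T2": (0.2, 10), "T3": (0.3, 10)}
        assert best_training_day(per_day) == "T2"

    def test_tie_goes_to_earliest(self):
        assert best_training_day({"T2": (0.2, 5), "T1": (0.2, 5)}) == "T1"

    def test_empty_days_rejected(self):
        with pytest.raises(ValueError):
            best_training_day({"T1": (0.4, 0)})

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            per_day = {f"T{i}": (float(rng.integers(0, 5)) / 10.0, 5)
                       for i in range(1, int(rng.integers(2, 6)))}
            best = best_training_day(per_day)
            lo = min(tp for tp, _ in per_day.values())
            candidates = sorted(p for p, (tp, _) in per_day.items() if tp == lo)
            assert best == candidates[0]


class TestTransitionEntropy:
    def test_deterministic_alternation_is_zero(self):
        b = bout_from_labels("abababa")
        assert bout_transition_entropy(b, include_end=False) == 0.0

    def test_half_bit_construction(self):
        # 'a' emits half of all transitions, split 50/50; others deterministic
        b = bout_from_labels("abac")
        assert bout_transition_entropy(b, log_base=2) == pytest.approx(0.5)

    def test_end_counts_as_outcome(self):
        # 'aaaa': successors of 'a' are {a,a,a,END} -> H = entropy(3/4, 1/4)
        b = bout_from_labels("aaaa")
        h = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert bout_transition_entropy(b, log_base=2) == pytest.approx(h)

    def test_matches_tally_oracle_on_random_bouts(self, rng):
        from oracles import te_tally

        for _ in range(100):
            b = random_bouts(rng, 1, max_len=20)[0]
            for include_end in (True, False):
                assert bout_transition_entropy(b, include_end=include_end) == \
                    pytest.approx(te_tally(b.labels, include_end=include_end))

    def test_log_base_conversion_exact(self, rng):
        for _ in range(20):
            b = random_bouts(rng, 1, max_len=25)[0]
            te2 = bout_transition_entropy(b, log_base=2)
            te_e = bout_transition_entropy(b, log_base=math.e)
            assert te_e == pytest.approx(te2 * math.log(2), abs=1e-12)

    @given(stn.text(alphabet="abx", min_size=1, max_size=30))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_nonnegative_and_zero_iff_deterministic(self, labels):
        b = bout_from_labels(labels)
        te = bout_transition_entropy(b, include_end=False)
        assert te >= 0.0
        succ = {}
        for x, y in zip(labels, labels[1:]):
            succ.setdefault(x, set()).add(y)
        deterministic = all(len(s) == 1 for s in succ.values())
        assert (te == 0.0) == deterministic

    def test_mean_over_identical_bouts(self):
        b = bout_from_labels("abac")
        summary = mean_transition_entropy([b, b, b])
        assert summary.mean_te == pytest.approx(0.5)
        assert summary.log_base == 2.0

    def test_mean_of_deterministic_bouts_is_zero(self):
        bouts = [bout_from_labels("ab") for _ in range(5)]
        # include END: 'a'->b always, 'b'->END always
        assert mean_transition_entropy(bouts).mean_te == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_transition_entropy([])


class TestSongRateAndSpeed:
    def _bout_at(self, clock: time, day=date(2024, 1, 8)):
        return bout_from_labels("xa", file_start=datetime.combine(day, clock))

    def test_window_is_half_open(self):
        day = date(2024, 1, 8)
        bouts = [self._bout_at(time(9, 30)), self._bout_at(time(17, 0)),
                 self._bout_at(time(12, 0)), self._bout_at(time(9, 29, 59))]
        assert song_rate(bouts, day) == 2  # 9:30 counted, 17:00 and 9:29:59 not

    def test_empty_window(self):
        assert song_rate([self._bout_at(time(8, 0))], date(2024, 1, 8)) == 0

    def test_matches_linear_scan_oracle(self, rng):
        day = date(2024, 1, 8)
        secs = rng.uniform(0, 24 * 3600, size=200)
        bouts = [bout_from_labels(
            "xa", file_start=datetime.combine(day, time(0)) + timedelta(seconds=float(s)))
            for s in secs]
        expected = int(np.sum((secs >= 9.5 * 3600) & (secs < 17 * 3600)))
        assert song_rate(bouts, day) == expected

    def test_chunk_duration_arithmetic(self):
        b = bout_from_labels("ab", dur=0.1, gap=0.05)
        # a@[0,0.1], b@[0.15,0.25] -> duration 0.25
        assert chunk_durations([b], ["a", "b"]) == [pytest.approx(0.25)]

    def test_absent_chunk_gives_empty(self):
        assert chunk_durations([bout_from_labels("xyz")], ["a", "b"]) == []

    def test_overlapping_candidates_leftmost_nonoverlapping(self):
        b = bout_from_labels("aaa")
        durs = chunk_durations([b], ["a", "a"])
        assert len(durs) == 1
        assert durs[0] == pytest.approx(b.events[1].offset - b.events[0].onset)

    def test_matches_greedy_matching_oracle(self, rng):
        from oracles import greedy_chunk_starts

        for _ in range(100):
            b = random_bouts(rng, 1, alphabet="ab", max_len=20)[0]
            k = int(rng.integers(2, 4))
            chunk = ["a", "b", "a"][:k]
            starts = greedy_chunk_starts(b.labels, chunk)
            expected = [b.events[i + k - 1].offset - b.events[i].onset
                        for i in starts]
            assert chunk_durations([b], chunk) == pytest.approx(expected)


class TestBinnedCurves:
    def test_bin_partitioning(self, rng):
        bouts = random_bouts(rng, 120)
        curve = binned_learning_curve(bouts, "x", "a", bin_size=50)
        assert [p.complete for p in curve] == [True, True, False]
        assert [p.index for p in curve] == [1, 2, 3]

    def test_constant_stream_all_bins_at_one(self):
        bouts = [bout_from_labels("xa") for _ in range(60)]
        curve = binned_learning_curve(bouts, "x", "a", bin_size=20)
        assert all(p.tp == 1.0 for p in curve)

    def test_matches_windowed_recount(self, rng):
        from oracles import recount_transitions

        for _ in range(100):
            bouts = random_bouts(rng, int(rng.integers(10, 60)))
            size = int(rng.integers(3, 15))
            curve = binned_learning_curve(bouts, "x", "a", bin_size=size)
            for pt in curve:
                block = bouts[(pt.index - 1) * size: pt.index * size]
                counts = recount_transitions([b.labels for b in block], "x")
                n = sum(counts.values())
                assert pt.n == n
                if n:
                    assert pt.tp == pytest.approx(counts.get("a", 0) / n)

    def test_last_complete_bin_example(self):
        def curve_for(n_bouts):
            bouts = [bout_from_labels("xa") for _ in range(n_bouts)]
            return binned_learning_curve(bouts, "x", "a", bin_size=50)

        curves = {"MA": curve_for(400), "MF": curve_for(210), "MM": curve_for(320)}
        assert last_complete_bin(curves) == 4  # floor(210/50)

    def test_last_complete_bin_equal_counts(self):
        bouts = [bout_from_labels("xa") for _ in range(100)]
        c = binned_learning_curve(bouts, "x", "a", bin_size=50)
        assert last_complete_bin({"MA": c, "MF": c, "MM": c}) == 2

    def test_last_complete_bin_brute_force(self, rng):
        for _ in range(100):
            counts = {ctx: int(rng.integers(20, 300)) for ctx in ("MA", "MF", "MM")}
            curves = {ctx: binned_learning_curve(
                [bout_from_labels("xa")] * n, "x", "a", bin_size=20)
                for ctx, n in counts.items()}
            assert last_complete_bin(curves) == min(n // 20 for n in counts.values())

    def test_missing_complete_bin_names_context(self):
        short = binned_learning_curve([bout_from_labels("xa")] * 10, "x", "a",
                                      bin_size=50)
        with pytest.raises(ValueError, match="MM"):
            last_complete_bin({"MM": short})


class TestRelativeSpeedAndAccuracy:
    def test_relative_speed(self):
        assert relative_learning_speed(50.0, 500) == pytest.approx(0.1)
        assert relative_learning_speed(0.0, 123) == 0.0
        assert relative_learning_speed(40.0, 200) == \
            pytest.approx(relative_learning_speed(40.0, 100) / 2)
        with pytest.raises(ValueError):
            relative_learning_speed(50.0, 0)

    @staticmethod
    def _rends(hits=0, misses=0, fps=0, catches=0):
        from songseq.annotation_io import BranchRendition

        out = []
        out += [BranchRendition(0, "a", wn_delivered=True) for _ in range(hits)]
        out += [BranchRendition(0, "a") for _ in range(misses)]
        out += [BranchRendition(0, "l", wn_delivered=True) for _ in range(fps)]
        out += [BranchRendition(0, "a", is_catch=True) for _ in range(catches)]
        return out

    def test_accuracy_arithmetic(self):
        acc = targeting_accuracy(self._rends(hits=93, fps=4, misses=3), "a")
        assert acc.accuracy_percent == pytest.approx(93.0)
        assert not acc.excluded

    def test_exclusion_threshold(self):
        acc = targeting_accuracy(self._rends(hits=70, misses=30), "a")
        assert acc.accuracy_percent == pytest.approx(70.0)
        assert acc.excluded

    def test_catch_trials_outside_denominator(self):
        acc = targeting_accuracy(self._rends(hits=9, misses=1, catches=50), "a")
        assert acc.accuracy_percent == pytest.approx(90.0)

    def test_empty_denominator_flagged(self):
        acc = targeting_accuracy(self._rends(catches=10), "a")
        assert not acc.defined
        assert math.isnan(acc.accuracy_percent)

    def test_simulated_log_matches_programmed_rates(self, rng):
        from songseq.annotation_io import BranchRendition
        from songseq.simulator import FeedbackModel, LearningDynamics, apply_feedback

        import test_simulator

        m = test_simulator.tiny_branch_model()
        fb = FeedbackModel(hit_rate=0.9, false_positive_rate=0.05,
                           catch_fraction=0.1)
        dyn = LearningDynamics(learning_rate=0.0, floor=0.0, relaxation_rate=0.0)
        rends = []
        n = 4000
        for _ in range(n):
            out = "a" if rng.random() < 0.6 else "l"
            _, r = apply_feedback(m, BranchRendition(0, out), fb, dyn, rng)
            rends.append(r)
        acc = targeting_accuracy(rends, "a")
        # expectation: hits / (hits + fp + misses) with programmed rates
        expect = (0.6 * 0.9) / (0.6 + 0.4 * 0.05) * 100.0
        se = 100 * np.sqrt(0.9 * 0.1 / (0.6 * 0.9 * n))
        assert abs(acc.accuracy_percent - expect) <= 3 * se
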