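"""Level tallies, binomial classification, threshold estimation, grouping."""

import math

import numpy as np
import pytest

from fattaste import (
    StaircaseConfig,
    TrialLog,
    TrialRecord,
    assign_groups,
    classify_level,
    classify_levels,
    estimate_threshold,
    group_cuts,
    tally_levels,
    threshold_from_log,
)
from fattaste.thresholds import LevelTally, ThresholdResult, quartile_groups


def make_log(levels, corrects, pid="p1"):
    trials = [TrialRecord(i, lv, bool(c)) for i, (lv, c) in enumerate(zip(levels, corrects))]
    return TrialLog(participant_id=pid, trials=trials)


class TestTally:
    def test_counts_per_level(self):
        tallies = tally_levels(make_log([1, 3, 2, 2], [0, 1, 1, 1]))
        by_level = {t.level_index: t for t in tallies}
        assert by_level[2].n_presented == 2 and by_level[2].n_correct == 2
        assert by_level[2].pct_correct == 100.0
        assert sum(t.n_presented for t in tallies) == 4

    def test_single_trial_log(self):
        (t,) = tally_levels(make_log([4], [1]))
        assert (t.n_presented, t.n_correct) == (1, 1)

    def test_chance_tail_three_of_three(self):
        t = LevelTally(level_index=0, n_presented=3, n_correct=3)
        assert t.chance_tail == pytest.approx(1 / 27, rel=1e-12)

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            tally_levels(TrialLog(participant_id="x"))


class TestClassify:
    # chance tails computed by hand: P(X>=1 | 2, 1/3) = 1 - (2/3)^2 = 5/9
    def test_one_of_two_is_false_positive(self):
        t = LevelTally(0, 2, 1)
        assert t.chance_tail == pytest.approx(5 / 9, rel=1e-12)
        assert classify_level(t, "tail", 0.05) == "false_positive"

    def test_three_of_three_is_true_positive(self):
        assert classify_level(LevelTally(0, 3, 3), "tail", 0.05) == "true_positive"

    def test_zero_correct_is_incorrect_under_any_rule(self):
        for rule in ("tail", "fraction"):
            assert classify_level(LevelTally(0, 5, 0), rule) == "incorrect"

    def test_fraction_rule_compares_to_chance_percentage(self):
        assert classify_level(LevelTally(0, 2, 1), "fraction") == "true_positive"
        assert classify_level(LevelTally(0, 3, 1), "fraction") == "false_positive"

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            classify_level(LevelTally(0, 2, 1), "bayes")


class TestEstimate:
    def test_geometric_mean_of_anchors(self, series9):
        # lowest TP at level 1 (0.55 mM), highest incorrect at level 0 (0.31 mM)
        log = make_log([1, 0, 1, 0, 1, 1], [1, 0, 1, 0, 1, 1])
        res = threshold_from_log(log, series9)
        assert res.censored == "none"
        expected = math.sqrt(series9.mM[1] * series9.mM[0])
        assert res.threshold_mM == pytest.approx(expected, rel=1e-9)
        assert res.threshold_mM == pytest.approx(0.415, abs=0.005)

    def test_printed_concentration_arithmetic(self):
        # with the printed (rounded) anchor values 0.55 and 0.31 mM
        assert math.sqrt(0.55 * 0.31) == pytest.approx(0.413, abs=5e-4)

    def test_true_positive_at_bottom_censors_low(self, series9):
        log = make_log([0, 0, 0], [1, 1, 1])
        res = threshold_from_log(log, series9)
        assert res.censored == "low"
        expected = series9.mM[0] / 10 ** (series9.log_step / 2)
        assert res.threshold_mM == pytest.approx(expected, rel=1e-9)
        assert res.threshold_mM == pytest.approx(0.23, abs=0.005)

    def test_no_true_positive_censors_high(self, series9):
        log = make_log([1, 3, 5], [0, 0, 0])
        res = threshold_from_log(log, series9)
        assert res.censored == "high"
        assert res.threshold_mM == pytest.approx(
            series9.mM[-1] * 10 ** (series9.log_step / 2), rel=1e-9
        )

    def test_threshold_between_anchor_concentrations(self, series9):
        log = make_log([2, 1, 2, 1, 2], [1, 0, 1, 0, 1])
        res = threshold_from_log(log, series9)
        assert series9.mM[res.highest_incorrect_index] < res.threshold_mM < series9.mM[res.lowest_TP_index]

    def test_unclassified_tallies_rejected(self, series9):
        with pytest.raises(ValueError):
            estimate_threshold(tally_levels(make_log([1], [1])), series9)

    def test_false_positive_ignored_as_threshold_anchor(self, series9):
        # level 2 has 1/2 correct (false positive) and must not become the
        # lowest true positive, but does count as an incorrect-answer anchor
        log = make_log([2, 2, 3, 3, 3], [1, 0, 1, 1, 1])
        res = threshold_from_log(log, series9)
        assert res.lowest_TP_index == 3
        assert res.highest_incorrect_index == 2

    def test_global_scope_ignores_lucky_levels_below_misses(self, series9):
        # 3/3 correct at level 1 (lucky), misses at level 3, TP at level 4
        log = make_log([1, 1, 1, 3, 3, 4, 4, 4], [1, 1, 1, 0, 0, 1, 1, 1])
        below = threshold_from_log(log, series9)
        glob = threshold_from_log(log, series9, incorrect_scope="global")
        assert below.lowest_TP_index == 1
        assert glob.lowest_TP_index == 4 and glob.highest_incorrect_index == 3

    def test_flipping_a_miss_to_correct_never_raises_threshold(self, series9):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = rng.integers(4, 20)
            levels = rng.integers(0, series9.n_levels, size=n).tolist()
            corrects = (rng.random(n) < 0.5).tolist()
            base = threshold_from_log(make_log(levels, corrects), series9)
            misses = [i for i, c in enumerate(corrects) if not c]
            if not misses:
                continue
            flip = int(rng.choice(misses))
            corrects2 = list(corrects)
            corrects2[flip] = True
            flipped = threshold_from_log(make_log(levels, corrects2), series9)
            assert flipped.threshold_mM <= base.threshold_mM * (1 + 1e-12)


class TestGrouping:
    def test_study1_display_cuts(self, series9):
        g = group_cuts(series9)
        assert round(g.display_low_cut_mM, 2) == 1.45
        assert round(g.display_high_cut_mM, 2) == 6.73

    def test_study2_display_low_cut(self, series12):
        g = group_cuts(series12)
        assert round(g.display_low_cut_mM, 2) == 0.81

    def test_exact_cuts_partition_log_span_in_thirds(self, series9):
        g = group_cuts(series9)
        span = math.log10(series9.mM[-1] / series9.mM[0])
        assert math.log10(g.low_cut_mM / series9.mM[0]) == pytest.approx(span / 3, rel=1e-9)
        assert math.log10(g.high_cut_mM / series9.mM[0]) == pytest.approx(2 * span / 3, rel=1e-9)

    def test_assignment_unit_invariance(self, series9):
        # computing the exact cuts in mM directly gives the same partition
        g = group_cuts(series9)
        span = math.log10(series9.mM[-1] / series9.mM[0])
        low_mM = series9.mM[0] * 10 ** (span / 3)
        high_mM = series9.mM[0] * 10 ** (2 * span / 3)
        assert g.low_cut_mM == pytest.approx(low_mM, rel=1e-12)
        assert g.high_cut_mM == pytest.approx(high_mM, rel=1e-12)

    def test_labels_partition_cohort(self, series9):
        results = [
            ThresholdResult(f"p{i}", thr, None, None)
            for i, thr in enumerate([0.4, 1.0, 2.0, 5.0, 8.0, 30.0])
        ]
        g = assign_groups(results, series9)
        assert len(g.labels) == 6
        assert g.labels["p0"] == "high" and g.labels["p5"] == "low"
        counts = {lab: sum(v == lab for v in g.labels.values()) for lab in ("high", "medium", "low")}
        assert sum(counts.values()) == 6

    def test_empty_cohort_rejected(self, series9):
        with pytest.raises(ValueError):
            assign_groups([], series9)

    def test_quartile_alternative(self):
        results = [ThresholdResult(f"p{i}", v, None, None) for i, v in enumerate([0.1, 1, 2, 3, 10, 20, 30, 40])]
        labels = quartile_groups(results)
        assert labels["p0"] == "high" and labels["p7"] == "low"
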