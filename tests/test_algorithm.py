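"""Round-wise classification, stop rules, mask selection, detection metrics."""

import numpy as np
import pytest

from truecoloc import (
    AlgorithmConfig,
    ImagePair,
    evaluate_detection,
    run_colocalization,
)
from truecoloc.algorithm import (
    NoSignalError,
    RoundRecord,
    classify_round,
    mixed_map,
    run_classification,
    select_mask,
)

from conftest import make_sim_pair


class TestMixedMap:
    def test_background_pixels_are_exactly_zero(self, sim_pair):
        pair, _ = sim_pair
        remaining = np.ones(pair.shape, bool)
        mm = mixed_map(pair, remaining)
        background = (pair.s1 == 0) | (pair.s2 == 0)
        assert np.all(mm[background] == 0.0)

    def test_bright_in_both_channels_is_positive(self):
        s1 = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 2.0], [1.0, 2.0, 90.0]])
        s2 = np.array([[1.0, 0.0, 2.0], [2.0, 1.0, 0.0], [2.0, 1.0, 80.0]])
        mm = mixed_map(ImagePair(s1, s2), np.ones((3, 3), bool))
        assert mm[2, 2] > 0

    def test_single_zero_channel_pixel_is_zero(self):
        s1 = np.array([[0.0, 1.0], [3.0, 2.0]])
        s2 = np.array([[90.0, 1.0], [3.0, 2.0]])
        mm = mixed_map(ImagePair(s1, s2), np.ones((2, 2), bool))
        assert mm[0, 0] == 0.0


class TestClassifyRound:
    def test_unique_positive_pixel_is_classified(self):
        s1 = np.array([[1.0, 1.0, 1.0], [1.0, 50.0, 1.0], [1.0, 1.0, 2.0]])
        s2 = np.array([[1.0, 1.0, 1.0], [1.0, 60.0, 1.0], [2.0, 1.0, 1.0]])
        pair = ImagePair(s1, s2)
        newly_c, _, _, _ = classify_round(pair, np.ones((3, 3), bool))
        assert newly_c[1, 1]

    def test_partition_of_remaining(self, sim_pair):
        pair, _ = sim_pair
        remaining = np.ones(pair.shape, bool)
        newly_c, newly_a, new_rem, _ = classify_round(pair, remaining)
        assert not (newly_c & newly_a).any()
        assert not (newly_c & new_rem).any()
        assert not (newly_a & new_rem).any()
        assert np.array_equal(newly_c | newly_a | new_rem, remaining)

    def test_all_background_round_has_fraction_one(self):
        s1 = np.array([[0.0, 5.0, 0.0, 0.0]])
        s2 = np.array([[3.0, 0.0, 0.0, 7.0]])
        pair = ImagePair(s1, s2)
        newly_c, newly_a, _, bg = classify_round(pair, np.ones((1, 4), bool))
        # every pixel is zero in one channel: mixed map is identically zero
        # and the zero-threshold sweep classifies them all as background
        assert bg == 1.0
        assert (newly_c | newly_a).sum() == 4


class TestRunClassification:
    def test_partition_and_monotonicity_every_round(self, sim_pair):
        pair, _ = sim_pair
        rounds, stop = run_classification(pair)
        assert stop == "background_limit"
        prev_remaining = np.ones(pair.shape, bool)
        prev_coloc = np.zeros(pair.shape, bool)
        prev_anti = np.zeros(pair.shape, bool)
        for rec in rounds:
            union = rec.newly_coloc | rec.newly_anticoloc | rec.remaining
            assert np.array_equal(union, prev_remaining)
            assert not (rec.newly_coloc & rec.newly_anticoloc).any()
            assert np.all(prev_coloc <= rec.cumulative_coloc)
            assert np.all(prev_anti <= rec.cumulative_anticoloc)
            prev_remaining = rec.remaining
            prev_coloc = rec.cumulative_coloc
            prev_anti = rec.cumulative_anticoloc

    def test_coloc_mask_excludes_background_before_terminal_round(
        self, sim_pair
    ):
        pair, _ = sim_pair
        rounds, _ = run_classification(pair)
        final = rounds[-1].cumulative_coloc
        assert np.all(pair.s1[final] * pair.s2[final] > 0)

    def test_recovers_truth_mask_on_simulated_pair(self):
        pair, truth = make_sim_pair(density=0.10, coloc_fraction=0.5, seed=42)
        rounds, stop = run_classification(pair)
        assert stop == "background_limit"
        metrics = evaluate_detection(
            rounds[-1].cumulative_coloc, truth.truth_mask
        )
        assert metrics.jaccard >= 0.8

    def test_no_signal_raises(self):
        zero = np.zeros((4, 4))
        with pytest.raises(NoSignalError):
            run_classification(ImagePair(zero, np.ones((4, 4))))

    def test_disjoint_supports_detect_no_colocalization(self):
        rng = np.random.default_rng(0)
        s1 = np.zeros((16, 16))
        s2 = np.zeros((16, 16))
        s1[:8] = rng.uniform(10, 50, size=(8, 16))
        s2[8:] = rng.uniform(10, 50, size=(8, 16))
        result = run_colocalization(ImagePair(s1, s2))
        assert result.no_colocalization
        assert not result.coloc_mask.any()

    def test_deterministic_rerun_is_bit_identical(self, sim_pair):
        pair, _ = sim_pair
        res1 = run_colocalization(pair)
        res2 = run_colocalization(pair)
        assert res1.selected_round == res2.selected_round
        assert np.array_equal(res1.coloc_mask, res2.coloc_mask)
        assert res1.R == res2.R and res1.m1 == res2.m1


def _fake_rounds(pair, R_values):
    """RoundRecords with prescribed in-mask R values on growing masks."""
    shape = pair.shape
    rounds = []
    cum = np.zeros(shape, bool)
    for k, R in enumerate(R_values, start=1):
        newly = np.zeros(shape, bool)
        newly.flat[k - 1] = True
        cum = cum | newly
        rounds.append(
            RoundRecord(
                round_index=k,
                newly_coloc=newly,
                newly_anticoloc=np.zeros(shape, bool),
                cumulative_coloc=cum.copy(),
                cumulative_anticoloc=np.zeros(shape, bool),
                remaining=~cum,
                R_in_coloc_mask=R,
                background_fraction_this_round=0.0,
            )
        )
    return rounds


class TestSelectMask:
    def test_hand_trapezoid_example(self, random_pair):
        # y = [0, 0.3, 0.4, 0.42]; cumulative fractions [0.165, 0.549, 1.0]
        rounds = _fake_rounds(random_pair, [0.2, 0.5, 0.6, 0.62])
        result = select_mask(rounds, random_pair)
        assert result.selected_round == 4
        np.testing.assert_allclose(
            result.area_cumulative_fraction,
            [0.0, 0.15 / 0.91, 0.50 / 0.91, 1.0],
            atol=1e-12,
        )

    def test_single_round_selects_it(self, random_pair):
        rounds = _fake_rounds(random_pair, [0.4])
        assert select_mask(rounds, random_pair).selected_round == 1

    def test_flat_curve_selects_first_round(self, random_pair):
        rounds = _fake_rounds(random_pair, [0.5, 0.5, 0.5])
        assert select_mask(rounds, random_pair).selected_round == 1

    def test_no_defined_rounds_flags_no_colocalization(self, random_pair):
        result = select_mask([], random_pair)
        assert result.no_colocalization
        assert not result.coloc_mask.any()
        assert result.m1 == 0.0 and result.m2 == 0.0

    def test_selected_round_never_exceeds_last(self, sim_pair):
        pair, _ = sim_pair
        result = run_colocalization(pair)
        assert 1 <= result.selected_round <= result.rounds[-1].round_index
        sel = next(
            rec for rec in result.rounds
            if rec.round_index == result.selected_round
        )
        assert np.array_equal(result.coloc_mask, sel.cumulative_coloc)


class TestEvaluateDetection:
    def test_perfect_prediction(self, rng):
        truth = rng.random((10, 10)) > 0.5
        m = evaluate_detection(truth, truth)
        assert m.precision == m.recall == m.jaccard == 1.0

    def test_empty_prediction_nonempty_truth(self):
        truth = np.ones((4, 4), bool)
        m = evaluate_detection(np.zeros((4, 4), bool), truth)
        assert m.recall == 0.0
        assert m.precision == 1.0  # empty prediction: no false positives

    def test_half_of_truth_predicted(self):
        truth = np.zeros((4, 4), bool)
        truth[:2] = True
        predicted = np.zeros((4, 4), bool)
        predicted[0] = True
        m = evaluate_detection(predicted, truth)
        assert m.precision == 1.0
        assert m.recall == 0.5
        assert m.jaccard == 0.5

    def test_both_empty_convention(self):
        empty = np.zeros((3, 3), bool)
        m = evaluate_detection(empty, empty)
        assert m.precision == m.recall == m.jaccard == 1.0
        assert m.detected_fraction == m.true_fraction == 0.0
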