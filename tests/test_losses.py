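"""Loss definitions against hand-computed values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesiongan.errors import ContractError
from lesiongan.losses import adversarial_bce, combined_loss, dice_loss, smoothing_loss
from lesiongan.nn import Tensor

from conftest import finite_difference_grad


def brute_force_smoothing(pred: np.ndarray, target: np.ndarray) -> float:
    """Quadruple-loop oracle: ordered 4-neighbour pairs, borders skipped."""
    h, w = pred.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < h and 0 <= jj < w and target[i, j] == target[ii, jj]:
                    total += target[i, j] * abs(pred[i, j] - pred[ii, jj])
    return total


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        t = np.array([[1, 1], [0, 1]], float)
        assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_is_one(self):
        assert dice_loss(np.zeros((3, 3)), np.ones((3, 3))) == pytest.approx(1.0, abs=1e-6)

    def test_hand_worked_example(self):
        # numerator 2*(0.5+1) = 3; denominator (0.25+1+0.25) + 2 = 3.5
        t = np.array([[1, 1], [0, 0]], float)
        p = np.array([[0.5, 1], [0.5, 0]], float)
        # the eps denominator guard perturbs the exact ratio at the 1e-8 level
        assert dice_loss(p, t) == pytest.approx(1 - 3 / 3.5, abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ContractError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_nonbinary_target_raises(self):
        with pytest.raises(ContractError):
            dice_loss(np.zeros((2, 2)), np.full((2, 2), 0.5))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(1, 9, 2)
        p = rng.random((h, w))
        t = rng.integers(0, 2, (h, w)).astype(float)
        assert -1e-12 <= dice_loss(p, t) <= 1.0 + 1e-12


class TestSmoothingLoss:
    def test_constant_prediction_is_zero(self, rng):
        t = rng.integers(0, 2, (5, 5)).astype(float)
        assert smoothing_loss(np.full((5, 5), 0.37), t) == 0.0

    def test_empty_target_is_zero(self, rng):
        assert smoothing_loss(rng.random((5, 5)), np.zeros((5, 5))) == 0.0

    def test_hand_worked_example(self):
        # four ordered pairs touch the single 0-pixel, each contributing 1
        t = np.ones((2, 2))
        p = np.array([[1, 0], [1, 1]], float)
        assert smoothing_loss(p, t) == pytest.approx(4.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            h, w = rng.integers(1, 9, 2)
            p = rng.random((h, w))
            t = rng.integers(0, 2, (h, w)).astype(float)
            assert smoothing_loss(p, t) == pytest.approx(
                brute_force_smoothing(p, t), abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(1, 9, 2)
        assert smoothing_loss(rng.random((h, w)),
                              rng.integers(0, 2, (h, w)).astype(float)) >= 0.0

    def test_normalized_variant_divides_by_pixel_count(self, rng):
        p = rng.random((6, 4))
        t = rng.integers(0, 2, (6, 4)).astype(float)
        raw = smoothing_loss(p, t)
        assert smoothing_loss(p, t, normalize=True) == pytest.approx(raw / 24.0)


class TestCombinedLoss:
    def test_perfect_binary_prediction_is_zero(self):
        t = np.array([[1, 0], [1, 1]], float)
        assert combined_loss(t, t) == pytest.approx(0.0, abs=1e-6)

    def test_additivity_on_worked_example(self):
        t = np.ones((2, 2))
        p = np.array([[1, 0], [1, 1]], float)
        # dice part 1 - 6/7, smoothing part 4
        assert combined_loss(p, t) == pytest.approx(1 / 7 + 4.0, abs=1e-6)
        assert combined_loss(p, t) == pytest.approx(
            dice_loss(p, t) + smoothing_loss(p, t), abs=1e-12)

    def test_smoothing_weight_scales_second_term(self):
        t = np.ones((2, 2))
        p = np.array([[1, 0], [1, 1]], float)
        assert combined_loss(p, t, smoothing_weight=0.5) == pytest.approx(
            dice_loss(p, t) + 2.0, abs=1e-6)


class TestAdversarialBce:
    def test_confident_correct_is_near_zero(self):
        assert adversarial_bce(np.ones((4, 4)), True) == pytest.approx(0.0, abs=1e-5)
        assert adversarial_bce(np.zeros((4, 4)), False) == pytest.approx(0.0, abs=1e-5)

    def test_half_score_gives_log_two(self):
        assert adversarial_bce(np.array([[0.5]]), True) == pytest.approx(np.log(2), rel=1e-6)

    def test_out_of_range_scores_raise(self):
        with pytest.raises(ContractError):
            adversarial_bce(np.array([[1.5]]), True)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_real_plus_fake_at_least_two_log_two(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random((4, 4))
        total = adversarial_bce(s, True) + adversarial_bce(s, False)
        assert total >= 2 * np.log(2) - 1e-9

    def test_equality_at_one_half(self):
        s = np.full((3, 3), 0.5)
        total = adversarial_bce(s, True) + adversarial_bce(s, False)
        assert total == pytest.approx(2 * np.log(2), rel=1e-6)


class TestLossGradients:
    """Autograd path agrees with finite differences (subgradients at ties aside)."""

    def test_dice_gradient(self, rng):
        t = rng.integers(0, 2, (5, 5)).astype(np.float32)
        p0 = rng.uniform(0.1, 0.9, (5, 5)).astype(np.float32)
        pt = Tensor(p0, requires_grad=True)
        dice_loss(pt, t).backward()
        num = finite_difference_grad(lambda a: dice_loss(Tensor(a), t).item(), p0.copy(),
                                     eps=5e-3)
        assert np.max(np.abs(pt.grad - num)) / np.max(np.abs(num)) < 5e-2

    def test_smoothing_gradient(self, rng):
        t = rng.integers(0, 2, (5, 5)).astype(np.float32)
        # keep neighbour differences away from the |.| kink
        p0 = (np.indices((5, 5)).sum(0) % 2 * 0.5 + 0.2).astype(np.float32)
        p0 += rng.uniform(-0.05, 0.05, (5, 5)).astype(np.float32)
        pt = Tensor(p0, requires_grad=True)
        smoothing_loss(pt, t).backward()
        num = finite_difference_grad(lambda a: smoothing_loss(Tensor(a), t).item(),
                                     p0.copy(), eps=5e-3)
        assert np.max(np.abs(pt.grad - num)) / (np.max(np.abs(num)) + 1e-9) < 5e-2

    def test_bce_gradient(self, rng):
        s0 = rng.uniform(0.2, 0.8, (4, 4)).astype(np.float32)
        for is_real in (True, False):
            st_ = Tensor(s0, requires_grad=True)
            adversarial_bce(st_, is_real).backward()
            num = finite_difference_grad(
                lambda a: adversarial_bce(Tensor(a), is_real).item(), s0.copy(), eps=5e-3)
            assert np.max(np.abs(st_.grad - num)) / np.max(np.abs(num)) < 5e-2
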