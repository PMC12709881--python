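import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kernelct import (
    LossConfig, boundary_smoothness_loss, dice_score, focal_tversky_loss,
    iou_score, multiclass_scores, total_loss, tversky_index,
)
from kernelct.losses import cross_entropy_loss, dice_loss, gradient_magnitude
from kernelct.nn import Tensor

from oracles import (
    boundary_loss_oracle, focal_tversky_oracle, gradient_magnitude_oracle,
)

EPS = 1e-6


def _mask_pair():
    """|X|=4, |Y|=3, |X∩Y|=2 — the worked counting example."""
    x = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]])
    y = np.array([[1, 1, 0], [0, 0, 0], [1, 0, 0]])
    return x, y


class TestTverskyIndex:
    def test_identical_sets_score_one(self):
        x = np.array([[1, 0], [1, 1]])
        for beta in (0.1, 0.5, 0.75, 0.9):
            assert tversky_index(x, x, beta=beta) == pytest.approx(1.0, abs=1e-5)

    def test_counting_example_beta_half_equals_dice(self):
        x, y = _mask_pair()
        t = tversky_index(x, y, beta=0.5, epsilon=EPS)
        assert t == pytest.approx(2 / 3.5, rel=1e-5)
        assert t == pytest.approx(dice_score(x, y), rel=1e-5)

    def test_counting_example_beta_075(self):
        x, y = _mask_pair()
        assert tversky_index(x, y, beta=0.75, epsilon=EPS) == pytest.approx(2 / 3.75, rel=1e-5)

    def test_printed_and_standard_forms_agree_on_hard_masks(self, rng):
        for _ in range(50):
            x = rng.integers(0, 2, (6, 6))
            y = rng.integers(0, 2, (6, 6))
            assert tversky_index(x, y, variant="printed") == pytest.approx(
                tversky_index(x, y, variant="standard"), rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            tversky_index(np.zeros((2, 2)), np.zeros((3, 3)))


class TestFocalTverskyLoss:
    def test_perfect_prediction_is_zero(self):
        x = np.array([[1, 1], [0, 1]])
        assert focal_tversky_loss(x, x) == pytest.approx(0.0, abs=1e-5)

    def test_arithmetic_on_known_tversky(self):
        x, y = _mask_pair()
        cfg = LossConfig(alpha=1.0, beta=0.75, gamma=2.0, lambda_smooth=0.0, epsilon=EPS)
        t = 2 / 3.75
        assert focal_tversky_loss(x, y, cfg) == pytest.approx((1 - t) ** 2, rel=1e-4)
        assert focal_tversky_loss(x, y, cfg) == pytest.approx(0.2178, abs=5e-4)

    def test_disjoint_masks_approach_alpha(self):
        x = np.array([[1, 0], [0, 0]])
        y = np.array([[0, 0], [0, 1]])
        assert focal_tversky_loss(x, y, LossConfig(epsilon=1e-12)) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_nonincreasing_in_overlap(self):
        y = np.ones((4, 4), dtype=int)
        losses = []
        for k in range(0, 17, 4):
            x = np.zeros(16, dtype=int)
            x[:k] = 1
            losses.append(focal_tversky_loss(x.reshape(4, 4), y))
        assert all(a >= b - 1e-9 for a, b in zip(losses, losses[1:]))

    def test_bounded_by_alpha(self, rng):
        cfg = LossConfig(alpha=2.5)
        for _ in range(20):
            x = rng.random((5, 5))
            y = rng.integers(0, 2, (5, 5))
            assert 0.0 <= focal_tversky_loss(x, y, cfg) <= 2.5 + 1e-9


class TestBoundarySmoothness:
    def test_identical_maps_cost_nothing(self, rng):
        m = rng.random((6, 6))
        assert boundary_smoothness_loss(m, m, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weight_costs_nothing(self, rng):
        assert boundary_smoothness_loss(rng.random((5, 5)), rng.random((5, 5)), 0.0) == 0.0

    def test_step_edge_matches_hand_rolled_double_loop(self):
        pred = np.zeros((4, 4))
        pred[:, 2:] = 1.0          # vertical step edge
        true = np.zeros((4, 4))    # flat
        lam = 0.7
        got = boundary_smoothness_loss(pred, true, lam)
        want = boundary_loss_oracle(pred.tolist(), true.tolist(), lam)
        assert got == pytest.approx(want, rel=1e-9)

    def test_gradient_magnitude_matches_oracle(self, rng):
        img = rng.random((5, 7))
        np.testing.assert_allclose(gradient_magnitude(img),
                                   gradient_magnitude_oracle(img.tolist()), rtol=1e-9)

    def test_differentiable_through_tensor_path(self):
        pred = Tensor(np.random.default_rng(0).random((4, 4), dtype=np.float32), requires_grad=True)
        true = np.zeros((4, 4))
        loss = boundary_smoothness_loss(pred, true, 0.5)
        loss.backward()
        assert pred.grad is not None and np.isfinite(pred.grad).all()


class TestTotalLoss:
    def test_zero_lambda_reduces_to_focal_tversky(self, rng):
        x, y = rng.random((6, 6)), rng.integers(0, 2, (6, 6))
        cfg = LossConfig(lambda_smooth=0.0)
        assert total_loss(x, y, cfg) == focal_tversky_loss(x, y, cfg)

    def test_perfect_prediction_costs_nothing(self):
        x = np.array([[1, 0], [1, 1]], dtype=float)
        assert total_loss(x, x.astype(int)) == pytest.approx(0.0, abs=1e-5)

    def test_equals_sum_of_independently_checked_terms(self, rng):
        x, y = rng.random((8, 8)), rng.integers(0, 2, (8, 8))
        cfg = LossConfig(alpha=1.3, beta=0.6, gamma=1.5, lambda_smooth=0.2, epsilon=EPS)
        ft = focal_tversky_oracle(x.tolist(), y.tolist(), 0.6, 1.5, 1.3, EPS)
        sm = boundary_loss_oracle(x.tolist(), y.astype(float).tolist(), 0.2)
        assert total_loss(x, y, cfg) == pytest.approx(ft + sm, rel=1e-7)

    def test_three_class_softmax_input_averages_foreground(self, rng):
        probs = rng.random((3, 8, 8))
        probs /= probs.sum(axis=0, keepdims=True)
        labels = rng.integers(0, 3, (8, 8))
        cfg = LossConfig(lambda_smooth=0.0)
        per_class = [
            focal_tversky_loss(probs[k], (labels == k).astype(float), cfg)
            for k in (1, 2)
        ]
        assert focal_tversky_loss(probs, labels, cfg) == pytest.approx(np.mean(per_class), rel=1e-6)

    def test_nonnegative_always(self, rng):
        for _ in range(20):
            x, y = rng.random((5, 5)), rng.integers(0, 2, (5, 5))
            assert total_loss(x, y) >= 0.0


class TestDiceIoU:
    def test_identical_masks(self):
        x = np.array([[1, 0], [1, 1]])
        assert dice_score(x, x) == 1.0 and iou_score(x, x) == 1.0

    def test_counting_example_and_identity(self):
        x, y = _mask_pair()
        d, j = dice_score(x, y), iou_score(x, y)
        assert d == pytest.approx(2 * 2 / 7, rel=1e-9)
        assert j == pytest.approx(2 / 5, rel=1e-9)
        assert d == pytest.approx(2 * j / (1 + j), rel=1e-9)

    def test_disjoint_masks_score_zero(self):
        x = np.array([[1, 0], [0, 0]])
        y = np.array([[0, 0], [0, 1]])
        assert dice_score(x, y) == 0.0 and iou_score(x, y) == 0.0

    def test_empty_vs_empty_is_perfect_agreement(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice_score(z, z) == 1.0 and iou_score(z, z) == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50)
    def test_dice_iou_identity_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.integers(0, 2, (7, 7)), rng.integers(0, 2, (7, 7))
        d, j = dice_score(x, y), iou_score(x, y)
        assert d == pytest.approx(2 * j / (1 + j), rel=1e-12)

    def test_multiclass_report_structure(self, rng):
        pred = rng.integers(0, 3, (6, 6))
        true = rng.integers(0, 3, (6, 6))
        rep = multiclass_scores(pred, true)
        assert set(rep) == {"dice_starchy", "iou_starchy", "dice_vitreous",
                            "iou_vitreous", "dice_mean", "iou_mean"}
        assert rep["dice_mean"] == pytest.approx(
            (rep["dice_starchy"] + rep["dice_vitreous"]) / 2)


class TestAblationLosses:
    def test_dice_loss_is_beta_half_tversky_complement(self, rng):
        x, y = rng.random((6, 6)), rng.integers(0, 2, (6, 6))
        assert dice_loss(x, y) == pytest.approx(1 - tversky_index(x, y, beta=0.5), rel=1e-9)

    def test_cross_entropy_decreases_with_confidence(self):
        labels = np.array([[1, 2], [0, 1]])
        good = np.full((3, 2, 2), 0.05)
        for k in range(3):
            good[k][labels == k] = 0.9
        bad = np.full((3, 2, 2), 1 / 3)
        assert cross_entropy_loss(good, labels) < cross_entropy_loss(bad, labels)


class TestLossConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(beta=1.5), dict(gamma=0.0), dict(alpha=-1.0),
        dict(lambda_smooth=-0.1), dict(epsilon=0.0), dict(variant="other"),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LossConfig(**kwargs)
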