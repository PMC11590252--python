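"""The five loss functions: exact fixtures, invariants and gradients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryosse.losses import (
    LossConfig, OneHotLabels, ProbabilityMap, combined_loss, cross_entropy,
    dice_coefficient, dice_loss, focal_loss, loss_and_logit_grad, loss_value,
    onehot_from_labels, softmax,
)


def one_voxel(y_channel, probs):
    """(y, p) pair with a single voxel."""
    y = np.zeros((3, 1, 1, 1))
    y[y_channel, 0, 0, 0] = 1.0
    p = np.asarray(probs, dtype=float).reshape(3, 1, 1, 1)
    return y, p


def random_pair(rng, shape=(4, 4, 4)):
    y = onehot_from_labels(rng.integers(0, 3, shape)).onehot
    p = softmax(rng.standard_normal((3,) + shape))
    return y, p


class TestCrossEntropy:
    def test_perfect_prediction_is_zero_up_to_clamp(self):
        y, _ = one_voxel(0, [1, 0, 0])
        assert cross_entropy(y, y.copy()) == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_gives_ln2(self):
        y, p = one_voxel(0, [0.5, 0.25, 0.25])
        assert cross_entropy(y, p) == pytest.approx(math.log(2), abs=1e-9)

    def test_uniform_gives_ln3(self):
        y, p = one_voxel(1, [1 / 3, 1 / 3, 1 / 3])
        assert cross_entropy(y, p) == pytest.approx(math.log(3), abs=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        y, p = random_pair(rng)
        with pytest.raises(ValueError):
            cross_entropy(y, p[:, :2])


class TestFocalLoss:
    def test_gamma_zero_reduces_to_ce(self, rng):
        cfg = LossConfig("FL", gamma=0.0)
        for _ in range(100):
            y, p = random_pair(rng, shape=(3, 3, 3))
            assert focal_loss(y, p, cfg) == pytest.approx(
                cross_entropy(y, p), abs=1e-10
            )

    def test_hand_value_gamma2(self):
        y, p = one_voxel(0, [0.5, 0.3, 0.2])
        cfg = LossConfig("FL", gamma=2.0)
        assert focal_loss(y, p, cfg) == pytest.approx(0.25 * math.log(2), abs=1e-9)

    def test_perfect_prediction_zero(self):
        y, _ = one_voxel(2, [0, 0, 1])
        assert focal_loss(y, y.copy(), LossConfig("FL", gamma=2.0)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            LossConfig("FL", gamma=-1.0)

    def test_fl_not_above_ce_for_positive_gamma(self, rng):
        for _ in range(20):
            y, p = random_pair(rng)
            ce = cross_entropy(y, p)
            for gamma in (1.0, 2.0, 5.0, 8.0):
                assert focal_loss(y, p, LossConfig("FL", gamma=gamma)) <= ce + 1e-12

    def test_fl_non_increasing_in_gamma(self, rng):
        gammas = [0.0, 1.0, 2.0, 5.0, 8.0]
        for _ in range(20):
            y, p = random_pair(rng)
            vals = [focal_loss(y, p, LossConfig("FL", gamma=g)) for g in gammas]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestDice:
    def test_perfect_prediction_d_equals_2(self, rng):
        labels = rng.integers(0, 3, (4, 4, 4))
        labels[0, 0, 0], labels[0, 0, 1] = 1, 2  # both foregrounds present
        y = onehot_from_labels(labels).onehot
        assert dice_coefficient(y, y.copy()) == pytest.approx(2.0, abs=1e-12)
        assert dice_loss(y, y.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_all_background_prediction_gives_d0_dl2(self):
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[0, 0, 0], labels[1, 1, 1] = 1, 2
        y = onehot_from_labels(labels).onehot
        p = onehot_from_labels(np.zeros((3, 3, 3), dtype=int)).onehot
        assert dice_coefficient(y, p) == pytest.approx(0.0)
        assert dice_loss(y, p) == pytest.approx(2.0)

    def test_zero_denominator_convention(self):
        y = onehot_from_labels(np.zeros((2, 2, 2), dtype=int)).onehot
        assert dice_coefficient(y, y.copy()) == 0.0

    def test_dl_plus_d_is_2(self, rng):
        y, p = random_pair(rng)
        assert dice_loss(y, p) + dice_coefficient(y, p) == pytest.approx(2.0)

    def test_matches_scalar_loop_oracle(self, rng):
        y, p = random_pair(rng, shape=(3, 3, 3))
        # independent per-class scalar-loop computation
        total = 0.0
        for ch in (0, 1):
            num = den_y = den_p = 0.0
            for idx in np.ndindex(y.shape[1:]):
                num += y[(ch,) + idx] * p[(ch,) + idx]
                den_y += y[(ch,) + idx]
                den_p += p[(ch,) + idx]
            if den_y + den_p > 0:
                total += num / (den_y + den_p)
        assert dice_coefficient(y, p) == pytest.approx(2 * total, abs=1e-12)


class TestCombined:
    @pytest.mark.parametrize("name", ["CE_DL", "FL_DL"])
    def test_perfect_prediction_zero(self, name, rng):
        labels = rng.integers(0, 3, (3, 3, 3))
        labels[0, 0, 0], labels[0, 0, 1] = 1, 2
        y = onehot_from_labels(labels).onehot
        cfg = LossConfig(name, gamma=2.0)
        assert combined_loss(y, y.copy(), cfg) == pytest.approx(0.0, abs=1e-5)

    def test_fl_dl_gamma0_equals_ce_dl(self, rng):
        y, p = random_pair(rng)
        assert combined_loss(y, p, LossConfig("FL_DL", gamma=0.0)) == pytest.approx(
            combined_loss(y, p, LossConfig("CE_DL")), abs=1e-10
        )

    def test_additivity(self, rng):
        for _ in range(5):
            y, p = random_pair(rng)
            cfg = LossConfig("FL_DL", gamma=2.0)
            assert combined_loss(y, p, cfg) == pytest.approx(
                focal_loss(y, p, cfg) + dice_loss(y, p, cfg), abs=1e-10
            )
            cfg2 = LossConfig("CE_DL")
            assert combined_loss(y, p, cfg2) == pytest.approx(
                cross_entropy(y, p, cfg2) + dice_loss(y, p, cfg2), abs=1e-10
            )

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            LossConfig("XX")


class TestRegionMask:
    def test_mask_excludes_padding_voxels(self, rng):
        y, p = random_pair(rng, shape=(4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        for name, gamma in [("CE", 1), ("FL", 2), ("DL", 1), ("CE_DL", 1), ("FL_DL", 2)]:
            cfg = LossConfig(name, gamma=float(gamma), region=mask)
            before = loss_value(y, p, cfg)
            y2, p2 = y.copy(), p.copy()
            # scramble everything outside the mask
            outside = ~mask
            y2[:, outside] = onehot_from_labels(
                rng.integers(0, 3, (int(outside.sum()), 1, 1))
            ).onehot.reshape(3, -1)
            p2[:, outside] = softmax(rng.standard_normal((3, int(outside.sum()))))
            assert loss_value(y2, p2, cfg) == pytest.approx(before, abs=1e-12)


class TestInvariantsProperty:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.sampled_from(["CE", "FL", "DL", "CE_DL", "FL_DL"]))
    def test_losses_nonnegative(self, seed, name):
        rng = np.random.default_rng(seed)
        y, p = random_pair(rng, shape=(3, 3, 3))
        cfg = LossConfig(name, gamma=float(rng.integers(0, 9)))
        assert loss_value(y, p, cfg) >= -1e-10


class TestGradients:
    @pytest.mark.parametrize(
        "name,gamma",
        [("CE", 1.0), ("FL", 1.0), ("FL", 2.0), ("FL", 5.0), ("FL", 8.0),
         ("DL", 1.0), ("CE_DL", 1.0), ("FL_DL", 2.0)],
    )
    def test_analytic_matches_central_differences(self, name, gamma, rng):
        cfg = LossConfig(name, gamma=gamma)
        y = onehot_from_labels(rng.integers(0, 3, (2, 2, 2))).onehot
        z = rng.standard_normal((3, 2, 2, 2))
        _, dz = loss_and_logit_grad(y, z, cfg)
        num = np.zeros_like(z)
        h = 1e-4
        for idx in np.ndindex(z.shape):
            zp, zm = z.copy(), z.copy()
            zp[idx] += h
            zm[idx] -= h
            num[idx] = (
                loss_and_logit_grad(y, zp, cfg)[0]
                - loss_and_logit_grad(y, zm, cfg)[0]
            ) / (2 * h)
        rel = np.abs(num - dz).max() / max(np.abs(num).max(), 1e-12)
        assert rel < 1e-4


class TestContainers:
    def test_probability_map_validation(self):
        with pytest.raises(ValueError):
            ProbabilityMap(np.full((3, 2, 2, 2), 0.5))  # sums to 1.5

    def test_onehot_validation(self):
        bad = np.zeros((3, 1, 1, 1))
        with pytest.raises(ValueError):
            OneHotLabels(bad)

    def test_onehot_from_labels_channel_layout(self):
        labels = np.array([[[0, 1]], [[2, 1]]])
        y = onehot_from_labels(labels).onehot
        # background is the LAST channel
        assert y[2, 0, 0, 0] == 1.0  # class 0 -> background channel
        assert y[0, 0, 0, 1] == 1.0  # class 1 -> helix channel
        assert y[1, 1, 0, 0] == 1.0  # class 2 -> sheet channel
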