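"""Adversarial and dual-domain fidelity losses against elementwise oracles."""

import numpy as np
import pytest

from picgan.encoding import adjoint_encode, fft2c, ifft2c
from picgan.losses import (
    LossWeights,
    adv_loss_d,
    adv_loss_g,
    fidelity_losses_and_grad,
    image_mae,
    kspace_acquired_mae,
    kspace_unacquired_mae,
    total_g_loss,
)
from picgan.types import SamplingMask, ValidationError


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestAdversarialLosses:
    def test_saturated_correct_is_zero(self):
        assert adv_loss_d(np.array([20.0]), np.array([-20.0])) < 1e-6
        assert adv_loss_g(np.array([20.0])) < 1e-6

    def test_closed_form_at_zero_logit(self):
        assert np.isclose(adv_loss_d(np.zeros(3), np.zeros(3)), 2 * np.log(2))
        assert np.isclose(adv_loss_g(np.zeros(5)), np.log(2))

    def test_matches_elementwise_oracle(self, rng):
        r = rng.normal(scale=3, size=8)
        f = rng.normal(scale=3, size=8)
        expected_d = np.mean(-np.log(sigmoid(r))) + np.mean(-np.log(1 - sigmoid(f)))
        assert abs(adv_loss_d(r, f) - expected_d) < 1e-8
        expected_g = np.mean(-np.log(sigmoid(f)))
        assert abs(adv_loss_g(f) - expected_g) < 1e-8
        expected_mm = np.mean(np.log(1 - sigmoid(f)))
        assert abs(adv_loss_g(f, form="minimax") - expected_mm) < 1e-8

    def test_empty_batch_rejected(self):
        with pytest.raises(ValidationError):
            adv_loss_g(np.array([]))


@pytest.fixture()
def loss_instance(small_sample):
    s = small_sample
    x_coils = ifft2c(s.kspace_full.data)
    return s, x_coils


class TestFidelityTerms:
    def test_zero_at_ground_truth(self, loss_instance):
        s, x_coils = loss_instance
        gt = s.ground_truth.data
        assert image_mae(x_coils, gt, s.maps) < 1e-8
        assert kspace_acquired_mae(s.kspace_full.data, gt, s.maps, s.mask) < 1e-8
        assert kspace_unacquired_mae(s.kspace_full.data, gt, s.maps, s.mask) < 1e-8

    def test_strictly_positive_when_perturbed(self, loss_instance, rng):
        s, x_coils = loss_instance
        bad = s.ground_truth.data + 0.01 * rng.normal(size=(32, 32))
        assert image_mae(x_coils, bad, s.maps) > 0
        assert kspace_acquired_mae(s.kspace_full.data, bad, s.maps, s.mask) > 0
        assert kspace_unacquired_mae(s.kspace_full.data, bad, s.maps, s.mask) > 0

    def test_image_mae_of_zero_recon_is_data_norm(self, loss_instance):
        s, x_coils = loss_instance
        expected = np.mean(np.abs(x_coils))
        assert np.isclose(image_mae(x_coils, np.zeros((32, 32)), s.maps), expected)

    def test_image_mae_matches_pixel_oracle(self, loss_instance, rng):
        s, x_coils = loss_instance
        xh = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        acc = 0.0
        for q in range(4):
            for i in range(32):
                for j in range(32):
                    acc += abs(x_coils[q, i, j] - s.maps.data[q, i, j] * xh[i, j])
        assert abs(image_mae(x_coils, xh, s.maps) - acc / (4 * 32 * 32)) < 1e-8

    def test_kspace_terms_match_masked_oracle(self, loss_instance, rng):
        s, _ = loss_instance
        xh = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        pred = np.stack([fft2c(s.maps.data[q] * xh) for q in range(4)])
        m = s.mask.data
        oracle_r = np.sum(np.abs(m * (s.kspace_full.data - pred))) / pred.size
        oracle_1r = np.sum(np.abs((1 - m) * (s.kspace_full.data - pred))) / pred.size
        assert abs(kspace_acquired_mae(s.kspace_full.data, xh, s.maps, s.mask) - oracle_r) < 1e-8
        assert abs(kspace_unacquired_mae(s.kspace_full.data, xh, s.maps, s.mask) - oracle_1r) < 1e-8

    def test_complementary_decomposition(self, loss_instance, rng):
        """acquired + unacquired MAE = unmasked full-k-space MAE, any mask."""
        s, _ = loss_instance
        xh = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        pred = np.stack([fft2c(s.maps.data[q] * xh) for q in range(4)])
        full = np.sum(np.abs(s.kspace_full.data - pred)) / pred.size
        for seed in range(3):
            mask = SamplingMask(
                (np.random.default_rng(seed).random((32, 32)) > 0.5).astype(np.uint8)
            )
            total = kspace_acquired_mae(
                s.kspace_full.data, xh, s.maps, mask
            ) + kspace_unacquired_mae(s.kspace_full.data, xh, s.maps, mask)
            assert abs(total - full) < 1e-8

    def test_full_mask_makes_unacquired_zero(self, loss_instance, rng):
        s, _ = loss_instance
        xh = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        full = SamplingMask(np.ones((32, 32), dtype=np.uint8))
        assert kspace_unacquired_mae(s.kspace_full.data, xh, s.maps, full) == 0.0

    def test_linear_scaling_of_residual(self, loss_instance):
        s, x_coils = loss_instance
        gt = s.ground_truth.data
        d = 0.1 * np.ones((32, 32))
        l1 = image_mae(x_coils, gt + d, s.maps)
        l2 = image_mae(x_coils, gt + 2 * d, s.maps)
        assert np.isclose(l2, 2 * l1, rtol=1e-10)


class TestTotalLoss:
    def test_study_weights_hand_computed(self):
        w = LossWeights(alpha=1.0, beta=10.0, gamma=10.0)
        assert np.isclose(total_g_loss(0.5, 0.1, 0.01, 0.02, w), 0.9)

    def test_zero_components(self):
        assert total_g_loss(0.0, 0.0, 0.0, 0.0, LossWeights()) == 0.0
        assert total_g_loss(0.7, 1.0, 1.0, 1.0, LossWeights(0, 0, 0)) == 0.7

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            total_g_loss(np.nan, 0, 0, 0, LossWeights())

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            LossWeights(alpha=-1.0)


class TestFidelityGradient:
    def test_matches_central_differences(self, loss_instance, rng):
        s, x_coils = loss_instance
        w = LossWeights(alpha=1.0, beta=2.0, gamma=3.0)
        xu = adjoint_encode(s.kspace_full.data, s.maps, s.mask)
        xh = xu + 0.01 * (rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32)))
        li, lfr, lf1r, grad = fidelity_losses_and_grad(
            xh, x_coils, s.kspace_full.data, s.maps, s.mask, w
        )
        assert np.isclose(li, image_mae(x_coils, xh, s.maps))
        assert np.isclose(lfr, kspace_acquired_mae(s.kspace_full.data, xh, s.maps, s.mask))
        assert np.isclose(lf1r, kspace_unacquired_mae(s.kspace_full.data, xh, s.maps, s.mask))

        def total(x):
            a, b, c, _ = fidelity_losses_and_grad(
                x, x_coils, s.kspace_full.data, s.maps, s.mask, w
            )
            return w.alpha * a + w.beta * b + w.gamma * c

        eps = 1e-6
        for _ in range(6):
            i = tuple(rng.integers(0, 32, size=2))
            for comp, part in ((1.0, "real"), (1j, "imag")):
                xp, xm = xh.copy(), xh.copy()
                xp[i] += eps * comp
                xm[i] -= eps * comp
                num = (total(xp) - total(xm)) / (2 * eps)
                ana = grad[i].real if part == "real" else grad[i].imag
                assert abs(num - ana) <= 1e-6 + 1e-4 * abs(num)
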