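"""Image metrics against direct-formula oracles and exact Wilcoxon enumeration."""

import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from picgan.encoding import fft2c, zero_filled_recon
from picgan.evaluation import (
    evaluate_methods,
    hard_data_consistency,
    nmse,
    psnr,
    ssim,
    wilcoxon_signed_rank,
)
from picgan.losses import kspace_acquired_mae
from picgan.phantom import MaskConfig, PhantomSpec, make_sample
from picgan.types import ComplexImage, ValidationError


class TestPSNR:
    def test_identical_images_give_inf(self, small_sample):
        assert psnr(small_sample.ground_truth, small_sample.ground_truth) == np.inf

    def test_closed_form(self):
        ref = np.zeros((16, 16))
        ref[0, 0] = 1.0  # peak 1
        rec = ref + 0.1  # MSE = 0.01
        assert np.isclose(psnr(ref.astype(complex), rec.astype(complex)), 20.0)

    def test_matches_direct_formula(self, rng):
        ref = rng.random((16, 16)) + 1j * rng.random((16, 16))
        rec = ref + 0.05 * rng.normal(size=(16, 16))
        r, x = np.abs(ref), np.abs(rec)
        expected = 10 * np.log10(r.max() ** 2 / np.mean((r - x) ** 2))
        assert abs(psnr(ref, rec) - expected) < 1e-10

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            psnr(np.zeros((8, 8), dtype=complex), np.ones((8, 8), dtype=complex))


class TestNMSE:
    def test_extremes(self, rng):
        ref = rng.random((12, 12)).astype(complex)
        assert nmse(ref, ref) == 0.0
        assert np.isclose(nmse(ref, np.zeros_like(ref)), 1.0)

    def test_matches_direct_formula(self, rng):
        ref = rng.random((12, 12)) + 1j * rng.random((12, 12))
        rec = ref * (1 + 0.1 * rng.normal(size=(12, 12)))
        r, x = np.abs(ref), np.abs(rec)
        expected = np.sum((r - x) ** 2) / np.sum(r ** 2)
        assert abs(nmse(ref, rec) - expected) < 1e-12

    def test_scale_invariance(self, rng):
        ref = rng.random((12, 12)).astype(complex)
        rec = ref + 0.1 * rng.random((12, 12))
        assert np.isclose(nmse(ref, rec), nmse(3.7 * ref, 3.7 * rec))


def ssim_oracle(ref, rec, sigma=1.5, k1=0.01, k2=0.03):
    """Gaussian-weighted SSIM from the standard definition, via scipy only."""
    peak = ref.max()
    x, y = ref / peak, rec / peak
    c1, c2 = (k1 * 1.0) ** 2, (k2 * 1.0) ** 2
    # truncate the Gaussian to an 11x11 window (radius 5 = 3.33 sigma)
    t = 5 / sigma
    mu_x = gaussian_filter(x, sigma, truncate=t)
    mu_y = gaussian_filter(y, sigma, truncate=t)
    xx = gaussian_filter(x * x, sigma, truncate=t) - mu_x ** 2
    yy = gaussian_filter(y * y, sigma, truncate=t) - mu_y ** 2
    xy = gaussian_filter(x * y, sigma, truncate=t) - mu_x * mu_y
    s = ((2 * mu_x * mu_y + c1) * (2 * xy + c2)) / (
        (mu_x ** 2 + mu_y ** 2 + c1) * (xx + yy + c2)
    )
    pad = 5
    return float(np.mean(s[pad:-pad, pad:-pad]))


class TestSSIM:
    def test_identical_images_give_one(self, small_sample):
        assert np.isclose(ssim(small_sample.ground_truth, small_sample.ground_truth), 1.0)

    def test_contrast_inversion_below_one(self, small_sample):
        ref = np.abs(small_sample.ground_truth.data)
        inverted = (1.0 - ref).astype(complex)
        assert ssim(small_sample.ground_truth, inverted) < 0.9

    def test_matches_independent_formula(self, rng):
        ref = rng.random((48, 48))
        rec = np.clip(ref + 0.1 * rng.normal(size=(48, 48)), 0, None)
        ours = ssim(ref.astype(complex), rec.astype(complex))
        assert abs(ours - ssim_oracle(ref, rec)) < 1e-6

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValidationError):
            ssim(np.ones((8, 8), dtype=complex), np.ones((8, 8), dtype=complex))


def wilcoxon_brute_force(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    stats = np.asarray(stats)
    p_le = np.mean(stats <= w_obs + 1e-12)
    p_ge = np.mean(stats >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_equal_rejected(self):
        a = np.arange(6.0)
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank(a, a)

    def test_n6_all_positive_closed_form(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = a - np.array([0.5, 0.4, 0.3, 0.2, 0.6, 0.1])
        _, p = wilcoxon_signed_rank(a, b)
        assert np.isclose(p, 2 / 64)  # 0.03125

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=10)
        b = a + rng.normal(scale=0.8, size=10)
        _, p = wilcoxon_signed_rank(a, b)
        assert abs(p - wilcoxon_brute_force(a - b)) < 1e-12

    def test_matches_scipy_exact_mode(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(scale=0.5, size=12)
        _, p = wilcoxon_signed_rank(a, b)
        _, p_ref = scipy_wilcoxon(a, b, mode="exact", alternative="two-sided")
        assert np.isclose(p, p_ref)

    def test_large_n_normal_approximation_close_to_scipy(self, rng):
        a = rng.normal(size=40)
        b = a + 0.3 + rng.normal(scale=1.0, size=40)
        _, p = wilcoxon_signed_rank(a, b)
        _, p_ref = scipy_wilcoxon(a, b, correction=False, mode="approx")
        assert abs(p - p_ref) < 1e-6


class TestEvaluateMethods:
    def test_perfect_method_row(self, small_sample):
        refs = [small_sample.ground_truth]
        table = evaluate_methods({"perfect": refs}, refs)
        row = table.iloc[0]
        assert row["psnr_mean"] == np.inf
        assert row["nmse_e5_mean"] == 0.0
        assert np.isclose(row["ssim_mean"], 1.0)

    def test_identical_methods_not_comparable(self, small_sample):
        refs = [small_sample.ground_truth] * 6
        zf = [zero_filled_recon(small_sample)] * 6
        table = evaluate_methods({"zf": zf, "also_zf": zf}, refs, baseline="zf")
        row = table[table.method == "also_zf"].iloc[0]
        assert np.isnan(row["p_vs_baseline_psnr"])

    def test_misaligned_lengths_rejected(self, small_sample):
        with pytest.raises(ValidationError):
            evaluate_methods({"m": []}, [small_sample.ground_truth])


class TestHardDataConsistency:
    def test_single_coil_projection_zeroes_acquired_residual(self, rng):
        sample = make_sample(
            PhantomSpec(size=(32, 32), n_coils=1, seed=13),
            MaskConfig(kind="random", af=2.0, acs_lines=8, seed=13),
        )
        guess = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        proj = hard_data_consistency(guess, sample)
        assert kspace_acquired_mae(
            sample.kspace_full.data, proj.data, sample.maps, sample.mask
        ) < 1e-10

    def test_full_mask_returns_ground_truth(self, full_sample, rng):
        guess = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        proj = hard_data_consistency(guess, full_sample)
        assert np.max(np.abs(proj.data - full_sample.ground_truth.data)) < 1e-8

    def test_idempotent_single_coil(self, rng):
        sample = make_sample(
            PhantomSpec(size=(32, 32), n_coils=1, seed=14),
            MaskConfig(kind="random", af=2.0, acs_lines=8, seed=14),
        )
        guess = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        once = hard_data_consistency(guess, sample)
        twice = hard_data_consistency(once, sample)
        assert np.max(np.abs(twice.data - once.data)) < 1e-10
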