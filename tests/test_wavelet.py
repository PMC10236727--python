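import numpy as np
import pytest
import pywt

from erpcode.preprocess import bandpass_filter
from erpcode.wavelet import (NORMAL_MAD_SCALE, WaveletConfig, dwt_decompose,
                             energy_ratio, estimate_sigma, hard_threshold,
                             idwt_reconstruct, threshold_with_energy_guard,
                             universal_threshold)


def conv_decimate(x, filt, pad):
    """Brute-force single-level analysis: symmetric half-point extension,
    full convolution, dyadic decimation."""
    ext = np.concatenate([x[:pad][::-1], x, x[-pad:][::-1]])
    return np.convolve(ext, filt, mode="valid")[1::2]


class TestDecomposeReconstruct:
    def test_trial_length_gives_five_bands(self):
        d = dwt_decompose(np.random.default_rng(0).standard_normal(150))
        assert d.levels == 4
        assert len(d.coeffs) == 5          # A4, D4, D3, D2, D1

    def test_zero_signal_gives_zero_bands(self):
        d = dwt_decompose(np.zeros(150))
        assert all(np.all(c == 0) for c in d.coeffs)

    def test_single_level_matches_conv_decimate_oracle(self):
        w = pywt.Wavelet("bior3.5")
        pad = len(w.dec_lo) - 1
        rng = np.random.default_rng(3)
        config = WaveletConfig(levels=1)
        for n in (16, 33, 64):
            x = rng.standard_normal(n)
            d = dwt_decompose(x, config)
            np.testing.assert_allclose(d.approx,
                                       conv_decimate(x, w.dec_lo, pad),
                                       atol=1e-10)
            np.testing.assert_allclose(d.detail(1),
                                       conv_decimate(x, w.dec_hi, pad),
                                       atol=1e-10)

    def test_unit_impulse_matches_oracle(self):
        x = np.zeros(64)
        x[20] = 1.0
        w = pywt.Wavelet("bior3.5")
        d = dwt_decompose(x, WaveletConfig(levels=1))
        np.testing.assert_allclose(
            d.approx, conv_decimate(x, w.dec_lo, len(w.dec_lo) - 1),
            atol=1e-12)

    @pytest.mark.parametrize("n", [64, 150, 321, 1024])
    def test_perfect_reconstruction(self, n):
        x = np.random.default_rng(n).standard_normal(n)
        rec = idwt_reconstruct(dwt_decompose(x))
        assert np.max(np.abs(rec - x)) / np.max(np.abs(x)) <= 1e-8

    def test_signal_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            dwt_decompose(np.ones(8), WaveletConfig(levels=4))

    def test_inconsistent_band_lengths_rejected(self):
        d = dwt_decompose(np.random.default_rng(1).standard_normal(150))
        d.coeffs[2] = d.coeffs[2][:-3]
        with pytest.raises(ValueError, match="inconsistent"):
            idwt_reconstruct(d)


class TestSigmaAndThreshold:
    def test_worked_example(self):
        assert estimate_sigma([1, -2, 3, -4, 5]) == pytest.approx(
            3 / NORMAL_MAD_SCALE, abs=1e-12)
        assert estimate_sigma([1, -2, 3, -4, 5]) == pytest.approx(4.4477,
                                                                  abs=5e-4)

    def test_zero_vector_gives_zero(self):
        assert estimate_sigma(np.zeros(7)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.array([]))

    def test_mad_consistency_for_gaussian(self):
        d = 2.0 * np.random.default_rng(11).standard_normal(10_000)
        assert 1.9 <= estimate_sigma(d) <= 2.1

    def test_universal_threshold_examples(self):
        assert universal_threshold(0.0, 50) == 0.0
        assert universal_threshold(3.7, 1) == 0.0
        assert universal_threshold(2.0, 100) == pytest.approx(6.0697,
                                                              abs=5e-4)

    def test_universal_threshold_rejects_zero_count(self):
        with pytest.raises(ValueError):
            universal_threshold(1.0, 0)


class TestHardThreshold:
    def test_worked_example(self):
        d = dwt_decompose(np.random.default_rng(5).standard_normal(150))
        d.coeffs = [np.array([0.5, -3.0, 2.0, -0.9])] * 5
        out = hard_threshold(d, 1.0)
        np.testing.assert_array_equal(out.coeffs[0], [0.0, -3.0, 2.0, 0.0])
        assert out.retained_count == 10     # 2 survivors x 5 bands

    def test_zero_alpha_is_identity(self):
        d = dwt_decompose(np.random.default_rng(6).standard_normal(150))
        out = hard_threshold(d, 0.0)
        for a, b in zip(out.coeffs, d.coeffs):
            np.testing.assert_array_equal(a, b)

    def test_alpha_above_max_zeroes_everything(self):
        d = dwt_decompose(np.random.default_rng(7).standard_normal(150))
        big = max(np.max(np.abs(c)) for c in d.coeffs) + 1.0
        assert hard_threshold(d, big).retained_count == 0

    def test_survivors_at_least_alpha(self):
        d = dwt_decompose(np.random.default_rng(8).standard_normal(150))
        out = hard_threshold(d, 0.7)
        for band in out.coeffs:
            nz = band[band != 0]
            assert np.all(np.abs(nz) >= 0.7)

    def test_retention_monotone_in_alpha(self):
        """Retained count is non-increasing in alpha for any wavelet; the
        energy ratio is additionally non-increasing for an orthonormal
        wavelet (for the biorthogonal pair, cross terms in the non-orthogonal
        expansion can locally raise E, so only the endpoints are pinned)."""
        x = np.random.default_rng(9).standard_normal(150)
        alphas = np.linspace(0.0, 3.0, 13)

        d = dwt_decompose(x)
        counts = [hard_threshold(d, a).retained_count for a in alphas]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))
        energies = [energy_ratio(x, idwt_reconstruct(hard_threshold(d, a)))
                    for a in alphas]
        assert energies[0] == pytest.approx(100.0)
        big = max(np.max(np.abs(c)) for c in d.coeffs) + 1.0
        assert energy_ratio(x, idwt_reconstruct(hard_threshold(d, big))) == 0

        ortho = WaveletConfig(family="db4")
        d_o = dwt_decompose(x, ortho)
        energies_o = [energy_ratio(x, idwt_reconstruct(hard_threshold(d_o, a),
                                                       ortho))
                      for a in alphas]
        assert all(e1 >= e2 - 1e-9
                   for e1, e2 in zip(energies_o, energies_o[1:]))


class TestEnergyRatio:
    def test_identical_signals_full_energy(self):
        x = np.random.default_rng(10).standard_normal(150)
        assert energy_ratio(x, x) == pytest.approx(100.0)

    def test_zero_reconstruction_zero_energy(self):
        assert energy_ratio(np.ones(10), np.zeros(10)) == 0.0

    def test_worked_example(self):
        assert energy_ratio([3.0, 4.0], [3.0, 0.0]) == pytest.approx(36.0)

    def test_zero_energy_original_rejected(self):
        with pytest.raises(ValueError):
            energy_ratio(np.zeros(5), np.zeros(5))


class TestEnergyGuard:
    def test_guard_holds_on_bandpassed_noise(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = bandpass_filter(10.0 * rng.standard_normal(150), 250.0)
            out = threshold_with_energy_guard(x)
            assert out.energy > 99.0

    def test_clean_template_keeps_nearly_everything(self):
        t = np.exp(-0.5 * ((np.arange(150) - 100) / 8.0) ** 2) * 10.0
        out = threshold_with_energy_guard(t)
        assert out.energy > 99.0
        assert out.alpha_used < universal_threshold(
            estimate_sigma(dwt_decompose(t).detail(4)), 19) + 1e-12

    def test_relaxation_reduces_alpha_when_guard_binds(self):
        rng = np.random.default_rng(13)
        x = bandpass_filter(10.0 * rng.standard_normal(150), 250.0)
        d = dwt_decompose(x)
        alpha0 = universal_threshold(estimate_sigma(d.detail(4)),
                                     len(d.detail(4)))
        initial_e = energy_ratio(x, idwt_reconstruct(hard_threshold(d,
                                                                    alpha0)))
        out = threshold_with_energy_guard(x)
        if initial_e <= 99.0:
            assert out.alpha_used < alpha0

    def test_geometric_relaxation_mode(self):
        rng = np.random.default_rng(14)
        x = bandpass_filter(10.0 * rng.standard_normal(150), 250.0)
        out = threshold_with_energy_guard(x, relax_factor=0.9)
        assert out.energy > 99.0

    def test_sigma_recovery_over_replicates(self):
        """Median MAD-based sigma-hat over 200 seeded Gaussian trials within
        5% of the true sd.

        The estimator is applied to the Gaussian samples themselves: the
        biorthogonal analysis filters are not orthonormal (||g||_2 ~ 0.79),
        so detail coefficients of white noise carry a known filter-norm
        factor rather than the raw noise sd.
        """
        true_sd = 4.0
        rng = np.random.default_rng(15)
        estimates = [estimate_sigma(true_sd * rng.standard_normal(150))
                     for _ in range(200)]
        assert abs(np.median(estimates) - true_sd) / true_sd < 0.05
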