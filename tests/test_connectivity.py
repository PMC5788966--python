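import numpy as np
import pytest

from nirsdecode.connectivity import (BandSpec, MorletSpec, WelchSpec,
                                     all_pairs, band_average, covariance,
                                     morlet_cwt, pearson, spearman,
                                     spectral_coherence, wavelet_coherence)
from nirsdecode.features_batch import (pair_indices, time_domain_pair_features,
                                       welch_band_coherence,
                                       wavelet_band_coherence)
from nirsdecode.preprocessing import WINDOW_SLICE
from oracles import (slow_covariance, slow_pearson, slow_spearman,
                     slow_wavelet_coherence, slow_welch_coherence)

FS = 7.8125


class TestTimeDomainMeasures:
    def test_covariance_definitions(self, rng):
        x = rng.standard_normal(50)
        assert covariance(x, x) == pytest.approx(np.var(x, ddof=1))
        assert covariance(x, -x) == pytest.approx(-np.var(x, ddof=1))
        assert covariance(np.array([1.0, 2, 3]),
                          np.array([2.0, 4, 6])) == pytest.approx(2.0)

    def test_pearson_affine_extremes(self, rng):
        x = rng.standard_normal(40)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_independent_noise_small(self, rng):
        x = rng.standard_normal(10 ** 4)
        y = rng.standard_normal(10 ** 4)
        assert abs(pearson(x, y)) < 0.05

    def test_spearman_monotone_maps(self, rng):
        x = rng.standard_normal(60)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        xd = rng.permutation(60).astype(float)  # distinct values
        assert spearman(xd, -xd ** 3) == pytest.approx(-1.0)

    def test_spearman_ties_match_average_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 2.0, 3.0, 4.0]
        assert spearman(np.array(x), np.array(y)) == pytest.approx(
            slow_spearman(x, y), rel=1e-12)

    def test_degenerate_inputs_flagged_missing(self):
        const = np.full(20, 3.0)
        x = np.arange(20, dtype=float)
        assert np.isnan(pearson(const, x))
        assert np.isnan(spearman(const, x))

    def test_matches_loop_oracles_on_random_pairs(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 100))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.5 * x
            assert covariance(x, y) == pytest.approx(slow_covariance(x, y),
                                                     rel=1e-12)
            assert pearson(x, y) == pytest.approx(slow_pearson(x, y), rel=1e-12)
            assert spearman(x, y) == pytest.approx(slow_spearman(x, y),
                                                   rel=1e-12)


class TestWelchCoherence:
    def test_proportional_signals_give_unit_coherence(self, rng):
        x = rng.standard_normal(200)
        c = spectral_coherence(x, 3 * x, FS)
        np.testing.assert_allclose(c.cxy, 1.0, atol=1e-10)

    def test_single_segment_rejected(self, rng):
        # a single-segment estimate is algebraically 1 -> must be refused
        with pytest.raises(ValueError, match="segment"):
            spectral_coherence(rng.standard_normal(100),
                               rng.standard_normal(100), FS,
                               WelchSpec(nperseg=100, noverlap=0))

    def test_default_epoch_gives_three_segments(self, rng):
        c = spectral_coherence(rng.standard_normal(200),
                               rng.standard_normal(200), FS)
        assert c.n_segments == 3

    def test_independence_bias_close_to_one_over_k(self):
        """With K disjoint segments the estimator's mean under independence
        is 1/K (Beta(1, K-1)); checked over 200 Monte-Carlo reps."""
        rng = np.random.default_rng(42)
        spec = WelchSpec(nperseg=64, noverlap=0)
        k = 3
        acc = []
        for _ in range(200):
            x = rng.standard_normal(192)
            y = rng.standard_normal(192)
            acc.append(spectral_coherence(x, y, FS, spec).cxy[1:-1])
        means = np.mean(acc, axis=0)
        assert abs(means.mean() - 1 / k) < 0.03
        # per-bin 4-sigma sanity bound (sd of a 200-rep Beta(1,2) mean)
        assert np.abs(means - 1 / k).max() < 4 * 0.236 / np.sqrt(200)

    def test_matches_explicit_dft_oracle(self, rng):
        spec = WelchSpec(nperseg=64, noverlap=32)
        for _ in range(5):
            x = rng.standard_normal(160)
            y = rng.standard_normal(160) + 0.3 * x
            fast = spectral_coherence(x, y, FS, spec)
            f_ref, c_ref = slow_welch_coherence(x, y, FS, 64, 32, "hamming")
            np.testing.assert_allclose(fast.f, f_ref, atol=1e-9)
            np.testing.assert_allclose(fast.cxy, c_ref, atol=1e-9)


class TestWaveletCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(200)
        m = wavelet_coherence(x, x, FS)
        np.testing.assert_allclose(m.r2, 1.0, atol=1e-6)

    def test_proportional_signals_give_one(self, rng):
        x = rng.standard_normal(200)
        m = wavelet_coherence(x, -4 * x, FS)
        np.testing.assert_allclose(m.r2, 1.0, atol=1e-6)

    def test_unsmoothed_estimator_is_identically_one(self, rng):
        # the algebraic identity that makes the smoothing operator mandatory
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        m = wavelet_coherence(x, y, FS, smoothing=False)
        np.testing.assert_allclose(m.r2, 1.0, atol=1e-9)

    def test_too_short_signal_rejected(self, rng):
        with pytest.raises(ValueError, match="64"):
            wavelet_coherence(rng.standard_normal(32),
                              rng.standard_normal(32), FS)

    def test_periods_follow_fourier_factor(self):
        spec = MorletSpec()
        scales = spec.scales(1 / FS)
        ff = 4 * np.pi / (6 + np.sqrt(2 + 36))
        np.testing.assert_allclose(spec.fourier_factor, ff, rtol=1e-12)
        assert np.all(np.diff(scales) > 0)
        assert ff * scales[-1] <= 12.8 + 1e-9
        assert ff * scales[-1] * 2 ** spec.dj > 12.8  # largest grid scale

    def test_band_selects_expected_scales(self, rng):
        """The default band must select exactly the scales whose equivalent
        period lies in [3.2, 12.8] s, per period = fourier_factor * scale."""
        spec = MorletSpec()
        scales = spec.scales(1 / FS)
        periods = spec.fourier_factor * scales
        expected = int(np.sum((periods >= 3.2) & (periods <= 12.8)))
        m = wavelet_coherence(rng.standard_normal(200),
                              rng.standard_normal(200), FS, spec)
        band = BandSpec()
        mask = (m.frequencies >= band.low_hz) & (m.frequencies <= band.high_hz)
        assert int(mask.sum()) == expected
        assert expected > 0

    def test_band_outside_grid_rejected(self, rng):
        m = wavelet_coherence(rng.standard_normal(200),
                              rng.standard_normal(200), FS)
        # smallest default period is ~0.264 s, so 3.8 Hz lies above the grid
        with pytest.raises(ValueError, match="band"):
            band_average(m, BandSpec(low_hz=3.8, high_hz=3.85))

    def test_constant_map_band_average_is_one(self, rng):
        x = rng.standard_normal(200)
        m = wavelet_coherence(x, 2 * x, FS)
        assert band_average(m, BandSpec()) == pytest.approx(1.0, abs=1e-6)

    def test_matches_explicit_dft_oracle(self, rng):
        """Full R2 map equals a brute-force DFT-matrix evaluation of the
        same Morlet/smoothing construction."""
        spec = MorletSpec()
        for _ in range(3):
            x = rng.standard_normal(200)
            y = rng.standard_normal(200) + 0.4 * x
            fast = wavelet_coherence(x, y, FS, spec)
            ref = slow_wavelet_coherence(x, y, FS, spec)
            np.testing.assert_allclose(fast.r2, np.clip(ref, 0, 1), atol=1e-9)

    def test_ar1_null_band_average_consistent_with_oracle(self):
        """Band-averaged null level for independent AR(1) pairs agrees with
        the brute-force implementation of the same estimator."""
        rng = np.random.default_rng(7)
        spec = MorletSpec()
        band = BandSpec()
        fast_vals, slow_vals = [], []
        for i in range(30):
            x = ar1(rng, 200, 0.7)
            y = ar1(rng, 200, 0.7)
            m = wavelet_coherence(x, y, FS, spec, crop=WINDOW_SLICE)
            fast_vals.append(band_average(m, band))
            if i < 10:
                ref = slow_wavelet_coherence(x, y, FS, spec)
                freqs = 1 / (spec.fourier_factor * spec.scales(1 / FS))
                sel = (freqs >= band.low_hz) & (freqs <= band.high_hz)
                slow_vals.append(float(ref[sel][:, WINDOW_SLICE].mean()))
        assert abs(np.mean(fast_vals) - np.mean(slow_vals)) < 0.05
        np.testing.assert_allclose(fast_vals[:10], slow_vals, atol=1e-9)


def ar1(rng, n, phi):
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.standard_normal()
    return x


class TestMeasureProperties:
    @pytest.mark.parametrize("measure", [covariance, pearson, spearman])
    def test_symmetry_time_domain(self, measure, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        assert measure(x, y) == pytest.approx(measure(y, x), rel=1e-12)

    def test_symmetry_coherences(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        a = spectral_coherence(x, y, FS)
        b = spectral_coherence(y, x, FS)
        np.testing.assert_allclose(a.cxy, b.cxy, atol=1e-12)
        ma = wavelet_coherence(x, y, FS)
        mb = wavelet_coherence(y, x, FS)
        np.testing.assert_allclose(ma.r2, mb.r2, atol=1e-9)

    def test_ranges(self, rng):
        for _ in range(10):
            x = rng.standard_normal(200)
            y = rng.standard_normal(200)
            assert -1 - 1e-9 <= pearson(x, y) <= 1 + 1e-9
            assert -1 - 1e-9 <= spearman(x, y) <= 1 + 1e-9
            c = spectral_coherence(x, y, FS)
            assert np.all(c.cxy >= -1e-9) and np.all(c.cxy <= 1 + 1e-9)
            m = wavelet_coherence(x, y, FS)
            assert np.all(m.r2 >= -1e-9) and np.all(m.r2 <= 1 + 1e-9)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        a, b = 2.5, -1.0
        assert pearson(a * x + b, y) == pytest.approx(pearson(x, y), abs=1e-9)
        assert spearman(a * x + b, y) == pytest.approx(spearman(x, y), abs=1e-9)
        assert covariance(a * x + b, y) == pytest.approx(a * covariance(x, y),
                                                         rel=1e-9)
        c0 = spectral_coherence(x, y, FS).cxy
        c1 = spectral_coherence(a * x + b, y, FS).cxy
        np.testing.assert_allclose(c1, c0, atol=1e-9)
        m0 = wavelet_coherence(x, y, FS).r2
        m1 = wavelet_coherence(a * x + b, y, FS).r2
        np.testing.assert_allclose(m1, m0, atol=1e-8)

    def test_spearman_invariant_under_increasing_transform(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        s0 = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(s0, abs=1e-12)
        assert spearman(x, y ** 3 + 5 * y) == pytest.approx(s0, abs=1e-12)


class TestAllPairs:
    def test_pair_counts(self):
        assert len(all_pairs([f"C{i}" for i in range(42)])) == 861
        assert len(all_pairs(["a", "b"])) == 1
        assert len(all_pairs(list("abcdef"))) == 15

    def test_canonical_order(self):
        pairs = all_pairs(["a", "b", "c"])
        assert pairs == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            all_pairs(["a"])


class TestBatchEquivalence:
    def test_time_domain_batch_matches_scalar(self, rng):
        W = rng.standard_normal((3, 5, 80))
        batch = time_domain_pair_features(W)
        ia, ib = pair_indices(5)
        for e in range(3):
            for p, (i, j) in enumerate(zip(ia, ib)):
                assert batch["covariance"][e, p] == pytest.approx(
                    covariance(W[e, i], W[e, j]), rel=1e-10)
                assert batch["pearson"][e, p] == pytest.approx(
                    pearson(W[e, i], W[e, j]), rel=1e-10)
                assert batch["spearman"][e, p] == pytest.approx(
                    spearman(W[e, i], W[e, j]), rel=1e-10)

    def test_welch_batch_matches_scalar(self, rng):
        E = rng.standard_normal((2, 5, 200))
        band = BandSpec()
        batch = welch_band_coherence(E, FS)
        ia, ib = pair_indices(5)
        for e in range(2):
            for p, (i, j) in enumerate(zip(ia, ib)):
                ref = band_average(spectral_coherence(E[e, i], E[e, j], FS),
                                   band)
                assert batch[e, p] == pytest.approx(ref, abs=1e-10)

    def test_wavelet_batch_matches_scalar(self, rng):
        E = rng.standard_normal((2, 4, 200))
        band = BandSpec()
        batch = wavelet_band_coherence(E, FS)
        ia, ib = pair_indices(4)
        for e in range(2):
            for p, (i, j) in enumerate(zip(ia, ib)):
                m = wavelet_coherence(E[e, i], E[e, j], FS, crop=WINDOW_SLICE)
                ref = band_average(m, band)
                assert batch[e, p] == pytest.approx(ref, abs=1e-9)

    def test_single_precision_close_to_double(self, rng):
        E = rng.standard_normal((2, 4, 200))
        a = wavelet_band_coherence(E, FS, precision="double")
        b = wavelet_band_coherence(E, FS, precision="single")
        np.testing.assert_allclose(a, b, atol=1e-5)
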