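"""Feature-battery unit tests: closed forms, brute-force oracles,
scale/time-reversal invariances."""

import dataclasses
import math

import numpy as np
import pytest

from eggpipe import GeneratorParams, generate_recording, preprocess_recording
from eggpipe.features import (
    FEATURE_NAMES,
    FeatureConfig,
    PSDEstimate,
    approx_entropy,
    band_powers,
    dominant_freq_power,
    extract_features,
    hjorth_params,
    hurst_exponent,
    lempel_ziv,
    line_length,
    mean_power_frequency,
    median_frequency,
    permutation_entropy,
    petrosian_fd,
    pmmp,
    psd_crest_factor,
    rms,
    sample_entropy,
    spectral_entropy,
    statistical_moments,
    svd_entropy,
    welch_psd,
)
from oracles import (
    apen_brute,
    lz76_brute,
    pren_brute,
    sampen_brute,
    svden_brute,
)


def _psd(power, f0=1.0, df=1.0):
    power = np.asarray(power, dtype=float)
    return PSDEstimate(
        freqs_cpm=f0 + df * np.arange(len(power)), power=power, resolution_cpm=df
    )


class TestTimeDomain:
    def test_moments_small_example(self):
        mean, var, mode, median, skew, kurt = statistical_moments([1, 2, 2, 3])
        assert (mean, median) == (2.0, 2.0)
        assert var == pytest.approx(0.5)
        assert mode == pytest.approx(2.0, abs=0.05)  # 64-bin midpoint
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(-1.0)

    def test_moments_constant(self):
        with pytest.warns(UserWarning):
            assert statistical_moments(np.full(10, 5.0)) == (5, 0, 5, 5, 0, 0)

    def test_moments_gaussian_sanity(self, rng):
        x = rng.standard_normal(100_000)
        *_, skew, kurt = statistical_moments(x)
        assert abs(skew) < 0.05 and abs(kurt) < 0.05

    def test_rms(self):
        assert rms(np.full(7, -3.0)) == 3.0
        t = np.linspace(0, 1, 1000, endpoint=False)
        assert rms(2 * np.sin(2 * np.pi * 5 * t)) == pytest.approx(np.sqrt(2), abs=1e-3)
        assert rms([3.0, -4.0]) == pytest.approx(math.sqrt(12.5))

    def test_line_length(self):
        assert line_length([0, 1, 0, 1]) == 3.0
        assert line_length(np.full(9, 2.0)) == 0.0
        assert line_length(np.linspace(0, 10, 50)) == pytest.approx(10.0)

    def test_entropies_constant_signal(self):
        x = np.full(50, 3.0)
        with pytest.warns(UserWarning):
            assert approx_entropy(x) == 0.0
        with pytest.warns(UserWarning):
            assert sample_entropy(x) == 0.0

    def test_sampen_period_two_alternation(self):
        x = np.tile([0.0, 1.0], 40)
        assert sample_entropy(x, m=2) == pytest.approx(0.0, abs=1e-12)
        r = 0.2 * x.std()
        assert sampen_brute(x, 2, r) == pytest.approx(0.0, abs=1e-12)

    def test_apen_sampen_match_brute_force(self, rng):
        """Vectorized ApEn/SampEn equal the naive double-loop oracles."""
        for _ in range(5):
            x = rng.uniform(size=rng.integers(60, 200))
            r = 0.2 * x.std()
            assert approx_entropy(x, 2, 0.2) == pytest.approx(
                apen_brute(x, 2, r), abs=1e-10
            )
            se = sample_entropy(x, 2, 0.2)
            if math.isfinite(se):
                assert se == pytest.approx(sampen_brute(x, 2, r), abs=1e-10)

    def test_permutation_entropy(self, rng):
        assert permutation_entropy(np.arange(50.0)) == 0.0
        big = rng.standard_normal(10_000)
        assert permutation_entropy(big) >= 0.99
        for _ in range(5):
            x = rng.standard_normal(rng.integers(20, 300))
            assert permutation_entropy(x, 3, 1) == pytest.approx(
                pren_brute(x, 3, 1), abs=1e-10
            )

    def test_svd_entropy(self, rng):
        assert svd_entropy(np.full(30, 2.0)) == pytest.approx(0.0)
        assert svd_entropy(rng.standard_normal(5000)) > 0.9
        for _ in range(5):
            x = rng.standard_normal(rng.integers(10, 300))
            assert svd_entropy(x, 3, 1) == pytest.approx(
                svden_brute(x, 3, 1), abs=1e-10
            )

    def test_lempel_ziv(self, rng):
        assert lempel_ziv(np.full(16, 7.0)) == 2.0  # "0", rest reproducible
        x = np.tile([1.0, 2.0], 8)
        assert lempel_ziv(x) == lz76_brute("01" * 8)
        for _ in range(5):
            y = rng.standard_normal(200)
            bits = "".join("1" if v >= np.median(y) else "0" for v in y)
            assert lempel_ziv(y) == lz76_brute(bits)
        # asymptotic sanity: mean count over seeds near n / log2(n)
        counts = [
            lempel_ziv(np.random.default_rng(s).standard_normal(1000))
            for s in range(5)
        ]
        assert np.mean(counts) == pytest.approx(1000 / math.log2(1000), rel=0.10)

    def test_hjorth_pure_sine(self):
        fs, f = 1000.0, 5.0
        t = np.arange(0, 10, 1 / fs)
        mob, comp = hjorth_params(np.sin(2 * np.pi * f * t))
        assert comp == pytest.approx(1.0, abs=0.01)
        assert mob == pytest.approx(2 * math.sin(math.pi * f / fs), rel=1e-3)

    def test_hjorth_definition_oracle(self, rng):
        x = rng.standard_normal(500)
        mob, comp = hjorth_params(x)
        d1, d2 = np.diff(x), np.diff(np.diff(x))
        mob_ref = math.sqrt(d1.var() / x.var())
        assert mob == pytest.approx(mob_ref, abs=1e-12)
        assert comp == pytest.approx(
            math.sqrt(d2.var() / d1.var()) / mob_ref, abs=1e-12
        )

    def test_petrosian_closed_forms(self):
        assert petrosian_fd(np.arange(100.0)) == 1.0
        # N=1000 with exactly 100 derivative sign changes: 899 ascending
        # steps followed by 50 down-up pairs (1 boundary flip + 99 inside)
        diffs = np.concatenate([np.ones(899), np.tile([-1.0, 1.0], 50)])
        x = np.concatenate([[0.0], np.cumsum(diffs)])
        d = np.sign(np.diff(x))
        assert int(np.count_nonzero(d[1:] * d[:-1] < 0)) == 100
        assert petrosian_fd(x) == pytest.approx(1.00571, abs=1e-5)
        alt = np.empty(100)
        alt[::2], alt[1::2] = 0.0, 1.0
        assert petrosian_fd(alt) == pytest.approx(1.07737, abs=1e-5)

    def test_hurst(self, rng):
        white = rng.standard_normal(10_000)
        assert hurst_exponent(white) == pytest.approx(0.5, abs=0.05)
        assert hurst_exponent(np.cumsum(white)) == pytest.approx(1.0, abs=0.1)
        with pytest.raises(ValueError):
            hurst_exponent(np.full(1000, 1.0))


class TestFrequencyDomain:
    def test_welch_grid_and_peak(self):
        t = np.arange(0, 60, 0.25)
        x = np.sin(2 * np.pi * (10 / 60) * t)  # 10 cpm
        psd = welch_psd(x, 4.0)
        assert psd.resolution_cpm == pytest.approx(0.1)
        assert psd.freqs_cpm[np.argmax(psd.power)] == pytest.approx(10.0, abs=0.05)

    def test_welch_parseval(self):
        # deterministic unit-variance signal (amplitude sqrt(2) sine)
        t = np.arange(0, 60, 0.25)
        x = np.sqrt(2) * np.sin(2 * np.pi * (10 / 60) * t)
        psd = welch_psd(x, 4.0)
        assert np.sum(psd.power) * psd.resolution_cpm == pytest.approx(1.0, rel=0.05)

    def test_dominant_freq_tie_break(self):
        psd = _psd([1.0, 5.0, 2.0, 5.0], f0=5.0, df=1.0)
        df, dp = dominant_freq_power(psd, (5.0, 8.0))
        assert (df, dp) == (6.0, 5.0)  # ties resolve to the lower frequency

    def test_pmmp(self):
        assert pmmp(_psd(np.ones(10)), (1.0, 10.0)) == 100.0
        assert pmmp(_psd([8.0, 2.0, 1.0, 1.0]), (1.0, 4.0)) == 25.0
        single = np.zeros(50)
        single[7] = 3.0
        assert pmmp(_psd(single), (1.0, 50.0)) == 2.0

    def test_spectral_entropy(self):
        one = np.zeros(8)
        one[3] = 2.0
        assert spectral_entropy(_psd(one), (1.0, 8.0)) == 0.0
        assert spectral_entropy(_psd(np.ones(16)), (1.0, 16.0)) == pytest.approx(1.0)
        assert spectral_entropy(_psd([0.5, 0.5]), (1.0, 2.0)) == pytest.approx(1.0)
        expected = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1)) / math.log(2)
        assert spectral_entropy(_psd([0.9, 0.1]), (1.0, 2.0)) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.4690, abs=1e-3)

    def test_band_powers_sine_and_edge(self):
        t = np.arange(0, 600, 0.25)
        psd = welch_psd(np.sin(2 * np.pi * (10 / 60) * t), 4.0)
        bp1, bp2, bp3 = band_powers(psd)
        assert bp2 >= 0.95 and bp1 + bp3 <= 0.05
        spike = np.zeros(30)
        spike[19] = 4.0  # power entirely at 20 cpm on a 1..30 cpm grid
        assert band_powers(_psd(spike), total_band_cpm=(0.6, 30.0)) == (0, 0, 0)

    def test_band_powers_flat_spectrum_ratio(self, rng):
        """White in-band power splits 5:3:4 across the gastric bands."""
        psd = _psd(np.ones(295), f0=0.6, df=0.1)
        bp = band_powers(psd)
        total_bins = 295
        widths = np.array([51, 31, 41], dtype=float)  # inclusive 0.1 cpm bins
        np.testing.assert_allclose(bp, widths / total_bins, atol=0.005)

    def test_crest_factor(self):
        assert psd_crest_factor(_psd(np.ones(12)), (1.0, 12.0)) == pytest.approx(1.0)
        assert psd_crest_factor(_psd([3.0, 4.0]), (1.0, 2.0)) == pytest.approx(
            4.0 / math.sqrt(12.5)
        )
        k = 25
        spike = np.zeros(k)
        spike[4] = 7.0
        assert psd_crest_factor(_psd(spike), (1.0, k)) == pytest.approx(math.sqrt(k))

    def test_median_and_mean_power_frequency(self, rng):
        two = np.zeros(11)
        two[0], two[10] = 1.0, 1.0  # equal bins at 5 and 15 cpm
        psd = _psd(two, f0=5.0, df=1.0)
        assert mean_power_frequency(psd, (5.0, 15.0)) == pytest.approx(10.0)
        assert median_frequency(psd, (5.0, 15.0)) == 5.0  # first crossing
        single = np.zeros(11)
        single[5] = 2.0
        psd1 = _psd(single, f0=5.0, df=1.0)
        assert median_frequency(psd1, (5.0, 15.0)) == 10.0
        assert mean_power_frequency(psd1, (5.0, 15.0)) == 10.0
        p = rng.uniform(size=40)
        psd2 = _psd(p)
        f = psd2.freqs_cpm
        assert mean_power_frequency(psd2, (1.0, 40.0)) == pytest.approx(
            float(np.sum(f * p) / p.sum()), abs=1e-10
        )


class TestExtractFeatures:
    def test_clean_window(self, clean_window):
        feats = extract_features(clean_window)
        assert feats["df"] == pytest.approx(10.0, abs=0.05)
        assert feats["bp2"] > max(feats["bp1"], feats["bp3"])
        assert feats["pfd"] < 1.01
        assert all(np.isfinite(feats[k]) for k in FEATURE_NAMES)

    def test_constant_window_uses_fallbacks(self, clean_window):
        w = dataclasses.replace(clean_window, samples=np.full(240, 5.0))
        with pytest.warns(UserWarning):
            feats = extract_features(w)
        assert feats["mean"] == 5.0 and feats["variance"] == 0.0
        assert all(np.isfinite(feats[k]) for k in FEATURE_NAMES)

    def test_amplitude_scale_invariance(self, clean_window):
        """Doubling the amplitude leaves the r-proportional entropies and
        all spectral shape features untouched; RMS/LL double, variance x4."""
        w2 = dataclasses.replace(clean_window, samples=2.0 * clean_window.samples)
        a = extract_features(clean_window)
        b = extract_features(w2)
        for k in ("apen", "sampen", "pren", "svden", "pfd", "spen",
                  "bp1", "bp2", "bp3", "mf", "mpf", "crest_factor",
                  "hjorth_mobility", "hjorth_complexity", "lz", "df", "pmmp"):
            assert b[k] == pytest.approx(a[k], rel=1e-9), k
        assert b["rms"] == pytest.approx(2 * a["rms"], rel=1e-12)
        assert b["line_length"] == pytest.approx(2 * a["line_length"], rel=1e-12)
        assert b["variance"] == pytest.approx(4 * a["variance"], rel=1e-12)

    def test_time_reversal_invariance(self, clean_window):
        wr = dataclasses.replace(clean_window, samples=clean_window.samples[::-1])
        a = extract_features(clean_window)
        b = extract_features(wr)
        for k in ("mean", "variance", "median", "skewness", "kurtosis",
                  "rms", "line_length", "pfd"):
            assert b[k] == pytest.approx(a[k], rel=1e-9), k
        # zero-padding makes the PSD only approximately reversal-symmetric
        for k in ("spen", "dp", "bp1", "bp2", "bp3", "mf", "mpf",
                  "crest_factor", "pmmp"):
            assert b[k] == pytest.approx(a[k], rel=1e-3, abs=1e-6), k
        assert b["df"] == pytest.approx(a["df"], abs=0.1)

    def test_feature_table_complete_on_default_synthetic(self):
        rec = generate_recording("baseline", GeneratorParams(seed=2), 180, 2000)
        from eggpipe import build_feature_table

        table = build_feature_table(preprocess_recording(rec))
        assert not table[FEATURE_NAMES].isna().any().any()
        assert list(table.columns[: len(FEATURE_NAMES)]) == FEATURE_NAMES
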