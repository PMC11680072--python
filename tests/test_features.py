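import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgcrypt import features as feat
from ecgcrypt.errors import InputError, TooShortError
from ecgcrypt.preprocess import preprocess
from ecgcrypt.signal import ECGSignal
from ecgcrypt.synthetic import NoiseSpec, SyntheticECGConfig, generate_ecg
from tests.conftest import NO_NOISE


# ---------------------------------------------------------------------------
# R peaks / RR / HRV
# ---------------------------------------------------------------------------


class TestRPeaks:
    def test_flat_signal_no_peaks(self):
        assert feat.detect_r_peaks(ECGSignal(np.zeros(2000), fs=500)).size == 0

    def test_short_signal_rejected(self):
        with pytest.raises(TooShortError):
            feat.detect_r_peaks(ECGSignal(np.zeros(100), fs=500))

    def test_clean_fixture_all_beats_within_10ms(self, clean_ecg):
        peaks = feat.detect_r_peaks(preprocess(clean_ecg))
        tol = int(0.010 * clean_ecg.fs)
        matched = sum(
            np.any(np.abs(peaks - a) <= tol) for a in clean_ecg.annotations
        )
        assert matched == len(clean_ecg.annotations)

    def test_snr10_recovers_95_percent(self, clean_ecg, rng):
        power = np.mean(clean_ecg.samples**2)
        noisy = ECGSignal(
            clean_ecg.samples + rng.normal(0, np.sqrt(power / 10), len(clean_ecg)),
            fs=clean_ecg.fs,
        )
        peaks = feat.detect_r_peaks(preprocess(noisy))
        tol = int(0.010 * clean_ecg.fs)
        matched = sum(
            np.any(np.abs(peaks - a) <= tol) for a in clean_ecg.annotations
        )
        assert matched / len(clean_ecg.annotations) >= 0.95


class TestRRSeries:
    def test_interval_computation(self):
        rr = feat.rr_intervals(np.array([0, 500, 1000]), fs=500)
        assert np.allclose(rr.intervals, [1.0, 1.0])

    def test_single_peak_rejected(self):
        with pytest.raises(InputError):
            feat.rr_intervals(np.array([42]), fs=500)

    def test_intervals_match_brute_force(self, rng):
        for _ in range(200):
            n = rng.integers(2, 40)
            peaks = np.cumsum(rng.integers(100, 800, size=n))
            rr = feat.rr_intervals(peaks, fs=500)
            oracle = [(peaks[i + 1] - peaks[i]) / 500 for i in range(n - 1)]
            assert np.array_equal(rr.intervals, oracle)

    def test_ibi_histogram_counts_everything(self, rng):
        peaks = np.cumsum(rng.integers(300, 600, size=30))
        rr = feat.rr_intervals(peaks, fs=500)
        _, counts = feat.ibi_histogram(rr)
        assert counts.sum() == rr.count


class TestHRV:
    def test_constant_series(self):
        out = feat.hrv_metrics(feat.RRSeries([0.8] * 4, np.arange(5)))
        assert out["sdnn"] == 0 and out["rmssd"] == 0
        assert out["nn50"] == 0 and out["pnn50"] == 0
        assert out["mean_hr"] == pytest.approx(75.0)

    def test_hand_computed_pair(self):
        out = feat.hrv_metrics(feat.RRSeries([0.7, 0.9], np.arange(3)))
        assert out["sdnn"] == pytest.approx(0.1414213562, abs=1e-9)
        assert out["rmssd"] == pytest.approx(0.2, abs=1e-12)

    def test_nn50_threshold(self):
        out = feat.hrv_metrics(feat.RRSeries([0.80, 0.86], np.arange(3)))
        assert out["nn50"] == 1 and out["pnn50"] == pytest.approx(100.0)

    def test_oracle_equivalence_explicit_loops(self, rng):
        """Formula-by-formula loop oracle agrees to 1e-12 on random series."""
        for _ in range(300):
            n = int(rng.integers(2, 50))
            x = rng.uniform(0.4, 1.5, size=n)
            out = feat.hrv_metrics(feat.RRSeries(x, np.arange(n + 1)))
            mean = sum(x) / n
            sdnn = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
            rmssd = (sum((x[i + 1] - x[i]) ** 2 for i in range(n - 1)) / (n - 1)) ** 0.5
            nn50 = sum(1 for i in range(n - 1) if abs(x[i + 1] - x[i]) > 0.050)
            assert abs(out["sdnn"] - sdnn) < 1e-12
            assert abs(out["rmssd"] - rmssd) < 1e-12
            assert out["nn50"] == nn50


# ---------------------------------------------------------------------------
# time-domain moments
# ---------------------------------------------------------------------------


class TestTimeDomain:
    def test_alternating_unit(self):
        out = feat.time_domain_features([1, -1, 1, -1])
        assert out["mean"] == 0 and out["rms"] == 1

    def test_constant_degenerate(self):
        out = feat.time_domain_features(np.zeros(10))
        assert out["degenerate"] and out["skewness"] == 0 and out["kurtosis"] == 0

    def test_normal_draws_have_zero_skew_excess_kurtosis(self, rng):
        x = rng.standard_normal(100_000)
        out = feat.time_domain_features(x)
        assert abs(out["skewness"]) < 0.05
        assert abs(out["kurtosis"]) < 0.1

    def test_population_flag_switches_std(self, rng):
        x = rng.normal(size=50)
        assert feat.time_domain_features(x, population=True)["std"] == pytest.approx(
            x.std(ddof=0)
        )
        assert feat.time_domain_features(x)["std"] == pytest.approx(x.std(ddof=1))


# ---------------------------------------------------------------------------
# DFT / spectra
# ---------------------------------------------------------------------------


class TestDFT:
    def test_constant_concentrates_in_dc(self):
        spec = feat.dft(np.full(16, 3.0), fs=500, side="two-sided")
        nonzero = np.abs(spec.coefficients) > 1e-12
        assert nonzero.sum() == 1
        assert np.abs(spec.coefficients[spec.frequencies == 0][0]) == pytest.approx(48.0)

    def test_cosine_two_bins_magnitude_half_n(self):
        N, k = 64, 5
        x = np.cos(2 * np.pi * k * np.arange(N) / N)
        spec = feat.dft(x, fs=N, side="two-sided")
        mags = np.abs(spec.coefficients)
        big = np.sort(mags)[-2:]
        assert np.allclose(big, N / 2, atol=1e-9)
        assert np.sum(mags > 1e-6) == 2

    @pytest.mark.parametrize("n", [1, 17, 256, 1001])
    def test_inversion_identity(self, rng, n):
        x = rng.normal(size=n)
        for side in ("one-sided", "two-sided"):
            back = feat.idft(feat.dft(x, fs=500, side=side))
            assert np.max(np.abs(back - x)) < 1e-9

    def test_parseval(self, rng):
        x = rng.normal(size=512)
        spec = feat.dft(x, fs=500, side="two-sided")
        lhs = np.sum(np.abs(x) ** 2)
        rhs = np.sum(np.abs(spec.coefficients) ** 2) / spec.N
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestFrequencyFeatures:
    def _single_bin(self, freq=10.0):
        f = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        X = np.zeros(5, dtype=complex)
        X[f == freq] = 3.0
        return feat.Spectrum(X, f, N=10, fs=40)

    def test_single_bin_degenerate_distribution(self):
        out = feat.frequency_features(self._single_bin())
        assert out["dominant_frequency"] == 10
        assert out["spectral_centroid"] == 10
        assert out["spectral_spread"] == 0
        assert out["spectral_entropy"] == 0
        assert out["spectral_rolloff"] == 10

    def test_two_equal_bins_centroid_midpoint(self):
        f = np.array([0.0, 10.0, 20.0])
        X = np.array([0.0, 2.0, 2.0], dtype=complex)
        out = feat.frequency_features(feat.Spectrum(X, f, N=6, fs=40))
        assert out["spectral_centroid"] == pytest.approx(15.0)

    def test_flat_spectrum_entropy_log2_n(self):
        n = 32
        spec = feat.Spectrum(np.ones(n, dtype=complex), np.arange(n, dtype=float), n, 64)
        assert feat.frequency_features(spec)["spectral_entropy"] == pytest.approx(np.log2(n))

    def test_all_zero_rejected(self):
        spec = feat.Spectrum(np.zeros(8, dtype=complex), np.arange(8.0), 8, 16)
        with pytest.raises(InputError):
            feat.frequency_features(spec)


# ---------------------------------------------------------------------------
# STFT
# ---------------------------------------------------------------------------


class TestSTFT:
    def test_zero_signal_zero_grid(self):
        grid = feat.stft(np.zeros(4000), fs=500)
        assert np.allclose(grid.magnitudes, 0)

    def test_stationary_tone_peaks_in_every_frame(self):
        t = np.arange(4000) / 500
        grid = feat.stft(np.sin(2 * np.pi * 10 * t), fs=500)
        peak_bins = grid.frequencies[np.argmax(grid.magnitudes, axis=1)]
        df = grid.frequencies[1] - grid.frequencies[0]
        assert np.all(np.abs(peak_bins - 10.0) <= df)

    @given(
        n=st.integers(64, 4000),
        window=st.integers(8, 512),
        hop=st.integers(1, 256),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_frame_count_formula(self, n, window, hop):
        if window > n:
            return
        grid = feat.stft(np.zeros(n), window=window, hop=hop, fs=500)
        assert grid.magnitudes.shape[0] == (n - window) // hop + 1

    def test_timefreq_tone_and_single_frame(self):
        t = np.arange(2000) / 500
        x = np.sin(2 * np.pi * 10 * t)
        grid = feat.stft(x, fs=500)
        out = feat.timefreq_features(grid)
        df = grid.frequencies[1] - grid.frequencies[0]
        assert abs(out["mean_frequency"] - 10.0) <= df
        single = feat.stft(x[:500], window=500, hop=500, fs=500)
        sout = feat.timefreq_features(single)
        p = single.magnitudes[0] ** 2
        p = p / p.sum()
        assert sout["mean_frequency"] == pytest.approx(float(single.frequencies @ p))

    def test_uniform_frames_entropy_log2_bins(self):
        grid = feat.STFTGrid(
            magnitudes=np.ones((3, 16)),
            times=np.arange(3.0),
            frequencies=np.arange(16.0),
            window=16, hop=8, fs=32,
        )
        assert feat.timefreq_features(grid)["mean_spectral_entropy"] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# ZCR / compare / fusion
# ---------------------------------------------------------------------------


class TestZCR:
    @pytest.mark.parametrize(
        "x,count",
        [
            ([1, 1, 1, 1], 0),
            ([1, -1, 1, -1], 3),
            ([1, 0, -1], 1),  # zero sample bridging opposite signs counts once
            ([1, 0, 1], 0),
        ],
    )
    def test_counting_convention(self, x, count):
        assert feat.zcr(x)["count"] == count

    def test_sine_integer_periods_exact(self):
        fs, f, m = 500, 10, 7
        n = int(fs * m / f) + 1  # include t = m/f so all 2m crossings are spanned
        x = np.sin(2 * np.pi * f * np.arange(n) / fs + 0.1)
        assert feat.zcr(x)["count"] == 2 * m


class TestCompare:
    def test_identical_and_constant_offset(self, rng):
        a = rng.normal(size=100)
        assert feat.compare_signals(a, a) == {"mse": 0.0, "rmse": 0.0}
        out = feat.compare_signals(a, a - 0.3)
        assert out["mse"] == pytest.approx(0.09) and out["rmse"] == pytest.approx(0.3)

    def test_loop_oracle(self, rng):
        a, b = rng.normal(size=64), rng.normal(size=64)
        mse = sum((ai - bi) ** 2 for ai, bi in zip(a, b)) / 64
        assert feat.compare_signals(a, b)["mse"] == pytest.approx(mse, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            feat.compare_signals(np.zeros(3), np.zeros(4))


class TestFusion:
    def _parts(self):
        return dict(
            time={k: float(i) for i, k in enumerate(feat.TIME_KEYS)},
            freq={k: 10.0 + i for i, k in enumerate(feat.FREQ_KEYS)},
            timefreq={k: 20.0 + i for i, k in enumerate(feat.TIMEFREQ_KEYS)},
            hrv={k: 30.0 + i for i, k in enumerate(feat.HRV_KEYS)},
            zcr={"rate_per_sample": 0.5},
            mode_summary=np.arange(12.0),
        )

    def test_length_additivity(self):
        fused = feat.fuse_features(**self._parts())
        assert fused.size == 5 + 5 + 2 + 5 + 1 + 12 == 30

    def test_round_trip_resplit(self):
        parts = self._parts()
        fused = feat.fuse_features(**parts)
        assert np.array_equal(fused[:5], [0, 1, 2, 3, 4])
        assert np.array_equal(fused[5:10], [10, 11, 12, 13, 14])
        assert np.array_equal(fused[10:12], [20, 21])
        assert np.array_equal(fused[12:17], [30, 31, 32, 33, 34])
        assert fused[17] == 0.5
        assert np.array_equal(fused[18:], np.arange(12.0))

    def test_missing_domain_named(self):
        parts = self._parts()
        parts["hrv"] = None
        with pytest.raises(InputError, match="hrv"):
            feat.fuse_features(**parts)

    def test_bundle_layout_matches_fused(self, clean_ecg):
        from ecgcrypt.decompose import VMDSettings, vmd
        from ecgcrypt.pipeline import PipelineConfig, extract_features
        from ecgcrypt.decompose import reconstruct

        clean = preprocess(clean_ecg)
        ms = vmd(clean, VMDSettings(K=3))
        bundle = extract_features(clean, reconstruct(ms), ms, PipelineConfig())
        assert len(bundle.layout()) == bundle.fused.size == 5 + 5 + 2 + 5 + 1 + (2 * 3 + 2)
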