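import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristpd.features import (
    DEFAULT_BANDS,
    BandDefinition,
    WindowingConfig,
    band_power,
    jerk,
    n_windows,
    segment_features,
    windowed_features,
)
from wristpd.io import TriaxialSignal, TrialRecord, segments_from_labels
from wristpd.preprocess import NormSignal

RATE = 50.0
BANDS = {b.name: b for b in DEFAULT_BANDS}


def norm_signal(a, rate=RATE):
    a = np.asarray(a, dtype=float)
    return NormSignal(np.arange(len(a)) / rate, a, rate)


def sine_norm(freq, duration_s, amp=1.0, rate=RATE):
    t = np.arange(int(duration_s * rate)) / rate
    return norm_signal(amp * np.sin(2 * np.pi * freq * t), rate)


def periodogram_band_power(a, rate, f_lo, f_hi):
    """Independent oracle: direct periodogram integration."""
    from scipy.signal import periodogram

    f, p = periodogram(a, fs=rate)
    df = f[1] - f[0]
    return np.sum(p[(f >= f_lo) & (f < f_hi)]) * df


class TestSegmentFeatures:
    def test_constant_segment(self):
        feats = segment_features(norm_signal(np.full(200, 3.7)))
        for name in ("mean", "median", "p25", "p75", "max", "min"):
            assert feats[name] == pytest.approx(3.7)
        assert feats["std"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(feats["skewness"])

    def test_5hz_sine_band_powers(self):
        feats = segment_features(sine_norm(5.0, 30))
        assert feats["power_tremor46"] == pytest.approx(0.5, rel=0.05)
        total = feats["power_full"]
        assert feats["power_gait"] < 0.01 * total

    def test_white_noise_full_band(self):
        rng = np.random.default_rng(8)
        sigma = 1.3
        feats = segment_features(norm_signal(rng.normal(0, sigma, 1500)))
        # flat spectrum: the 0-20 Hz band holds 20/25 of the variance
        assert feats["power_full"] == pytest.approx(sigma**2 * 20 / 25, rel=0.10)

    def test_short_segment_time_only(self):
        feats = segment_features(norm_signal(np.arange(50)))  # 1 s at 50 Hz
        assert np.isfinite(feats["std"])
        assert np.isnan(feats["power_full"])

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            segment_features(norm_signal([]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_order_statistics_invariants(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, rng.uniform(0.1, 5), int(rng.integers(10, 400)))
        f = segment_features(norm_signal(a))
        assert f["p25"] <= f["median"] <= f["p75"]
        assert f["min"] <= f["mean"] <= f["max"]

    def test_scaling_monotonicity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 1000)
        f1 = segment_features(norm_signal(a))
        k = 3.5
        f2 = segment_features(norm_signal(k * a))
        assert f2["std"] == pytest.approx(k * f1["std"], rel=1e-9)
        for band in BANDS:
            assert f2[f"power_{band}"] == pytest.approx(
                k**2 * f1[f"power_{band}"], rel=1e-9)


class TestBandPower:
    def test_zero_signal(self):
        for band in DEFAULT_BANDS:
            assert band_power(norm_signal(np.zeros(500)), band) == 0.0

    def test_disjoint_bands_sum_to_union(self):
        rng = np.random.default_rng(2)
        norm = norm_signal(rng.normal(0, 1, 1500))
        parts = [BandDefinition("a", 0, 3), BandDefinition("b", 3, 8),
                 BandDefinition("c", 8, 20)]
        total = band_power(norm, BandDefinition("u", 0, 20))
        assert sum(band_power(norm, b) for b in parts) == pytest.approx(total, rel=0.01)

    def test_parseval_full_band(self):
        # long record: Welch's averaging noise (~1/sqrt(K * n_bins)) must sit
        # well inside the 2% band being asserted
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 12000)
        a -= a.mean()
        full = band_power(norm_signal(a), BandDefinition("all", 0, 25.1))
        assert full == pytest.approx(np.var(a), rel=0.02)

    def test_2hz_sine_lands_in_gait_band(self):
        norm = sine_norm(2.0, 30, amp=1.4)
        gait = band_power(norm, BANDS["gait"])
        oracle = periodogram_band_power(norm.a, RATE, 1, 3)
        assert gait == pytest.approx(1.4**2 / 2, rel=0.05)
        assert gait == pytest.approx(oracle, rel=0.05)
        assert band_power(norm, BANDS["tremor46"]) < 0.01 * band_power(norm, BANDS["full"])

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power(norm_signal(np.zeros(500)), BandDefinition("x", 30, 40))

    def test_matches_periodogram_oracle_on_5hz_sine(self):
        norm = sine_norm(5.0, 30)
        welch = band_power(norm, BANDS["tremor46"])
        oracle = periodogram_band_power(norm.a, RATE, 4, 6)
        assert welch == pytest.approx(oracle, rel=0.05)


class TestWindows:
    @pytest.mark.parametrize("length,expected", [(256, 3), (127, 0), (128, 1),
                                                 (191, 1), (192, 2)])
    def test_window_count(self, length, expected):
        assert n_windows(length, WindowingConfig()) == expected

    def test_default_is_256_seconds_at_50hz(self):
        cfg = WindowingConfig()
        assert cfg.window_samples / RATE == pytest.approx(2.56)
        assert cfg.step == 64

    def test_count_formula_property(self):
        cfg = WindowingConfig()
        for L in [128, 200, 500, 1000]:
            k = n_windows(L, cfg)
            assert k == (L - cfg.window_samples) // cfg.step + 1
            # last window fits, one more would not
            assert (k - 1) * cfg.step + cfg.window_samples <= L
            assert k * cfg.step + cfg.window_samples > L


class TestJerk:
    def test_linear_ramp(self):
        x = 0.2 * np.arange(100)
        np.testing.assert_allclose(jerk(x, RATE), 0.2 * RATE)

    def test_constant(self):
        assert np.all(jerk(np.full(50, 7.0), RATE) == 0)

    def test_sine_gain(self):
        f = 2.0
        t = np.arange(1000) / RATE
        j = jerk(3.0 * np.sin(2 * np.pi * f * t), RATE)
        assert np.max(np.abs(j)) == pytest.approx(3.0 * 2 * np.pi * f, rel=0.05)

    def test_too_short(self):
        with pytest.raises(ValueError):
            jerk(np.array([1.0]), RATE)


class TestWindowedFeatures:
    def _trial(self, labels, rng):
        n = len(labels)
        t = np.arange(n) / RATE
        sig = TriaxialSignal(t, rng.normal(0, 1, n), rng.normal(0, 1, n),
                             9.81 + rng.normal(0, 1, n), RATE)
        return TrialRecord("s", "supervised", 1, sig,
                           segments_from_labels(np.asarray(labels)),
                           {"3.17": 2, "3.6": 3})

    def test_row_count_matches_window_accounting(self):
        rng = np.random.default_rng(0)
        labels = [1] * 256 + [2] * 127 + [6] * 400
        table = windowed_features(self._trial(labels, rng))
        counts = table.groupby("label_code").size().to_dict()
        assert counts.get(1, 0) == 3
        assert 2 not in counts  # 127 samples: no window fits
        assert counts.get(6, 0) == n_windows(400, WindowingConfig())

    def test_rows_carry_paired_score(self):
        rng = np.random.default_rng(1)
        table = windowed_features(self._trial([1] * 256 + [6] * 256, rng))
        rest = table[table.label_code == 1]
        assert (rest.score_item == "3.17").all()
        assert (rest.score == 2).all()
        pronosup = table[table.label_code == 6]
        assert (pronosup.score == 3).all()

    def test_window_larger_than_every_segment_warns_empty(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning):
            table = windowed_features(self._trial([1] * 100, rng))
        assert table.empty

    def test_empty_registry_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            windowed_features(self._trial([1] * 256, rng), time_registry={})
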