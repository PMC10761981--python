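import numpy as np
import pandas as pd
import pytest

from sblfp.datamodel import BehavioralEvent, make_bout_table
from sblfp.power import (
    TimeFrequencyPower,
    band_power_series,
    bout_band_power,
    compare_event_categories,
    delta_band_power,
    event_zscore,
    period_mean,
    preprocess,
    spectrogram,
)
from sblfp.simulate import SimulationConfig, simulate_session
from tests.conftest import fast_config


class TestPreprocess:
    def test_decimation_length(self):
        x = np.random.default_rng(0).standard_normal(40_000)
        y = preprocess(x, 20_000.0, 5_000.0)
        assert len(y) == 10_000

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros(100), 1000.0, 5000.0)

    def test_lowpass_attenuation(self):
        fs = 5000.0
        t = np.arange(int(10 * fs)) / fs
        passed = preprocess(np.sin(2 * np.pi * 100 * t), fs, fs)
        stopped = preprocess(np.sin(2 * np.pi * 400 * t), fs, fs)
        ratio = np.sqrt(np.mean(stopped**2) / np.mean(passed**2))
        assert 20 * np.log10(ratio) < -20

    def test_dc_preserved(self):
        y = preprocess(np.full(10_000, 3.0), 5000.0, 5000.0)
        assert np.allclose(y[100:-100], 3.0, atol=1e-6)


class TestSpectrogram:
    def test_tone_localization(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        tf = spectrogram(np.sin(2 * np.pi * 8 * t), fs)
        peak = tf.freqs[np.argmax(tf.power.mean(axis=1))]
        assert peak == pytest.approx(8.0, abs=0.5)
        theta = band_power_series(tf, "theta").mean()
        gamma = band_power_series(tf, "gamma").mean()
        assert theta > 100 * gamma

    def test_grid_spacing(self):
        tf = spectrogram(np.random.default_rng(0).standard_normal(5000), 500.0)
        assert tf.df == pytest.approx(0.5)
        assert np.diff(tf.times)[0] == pytest.approx(0.5)

    def test_parseval_white_noise(self):
        x = np.random.default_rng(1).standard_normal(60_000)
        tf = spectrogram(x, 500.0)
        integ = tf.power.mean(axis=1).sum() * tf.df
        assert integ == pytest.approx(x.var(), rel=0.05)

    def test_amplitude_step_quadruples_power(self):
        fs = 500.0
        rng = np.random.default_rng(2)
        x = np.sin(2 * np.pi * 8 * np.arange(int(120 * fs)) / fs)
        x[int(60 * fs):] *= 2
        tf = spectrogram(x, fs)
        s = band_power_series(tf, "theta")
        before = s[(s.index > 10) & (s.index < 50)].mean()
        after = s[(s.index > 70) & (s.index < 110)].mean()
        assert after / before == pytest.approx(4.0, rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            spectrogram(np.zeros(100), 500.0)


class TestBandPower:
    def test_flat_psd_band_power(self):
        freqs = np.arange(0, 101, 0.5)
        times = np.arange(0.25, 10, 0.5)
        tf = TimeFrequencyPower(np.full((len(freqs), len(times)), 3.0), freqs, times, 2.0, 0.5)
        s = band_power_series(tf, "theta")
        assert (s == 3.0).all()

    def test_masked_bins_excluded_matches_brute_force(self):
        rng = np.random.default_rng(3)
        freqs = np.arange(0, 101, 0.5)
        times = np.arange(0.25, 60, 0.5)
        power = rng.random((len(freqs), len(times)))
        tf = TimeFrequencyPower(power, freqs, times, 2.0, 0.5)
        s = band_power_series(tf, "theta")
        got = period_mean(s, (0.0, 60.0), mask_intervals=[(10.0, 20.0)])
        keep = (times < 10.0) | (times >= 20.0)
        assert got == pytest.approx(s.to_numpy()[keep].mean())

    def test_delta_recovers_injected_theta_gain(self):
        cfg = fast_config(encounter_gain={"theta": 1.5, "gamma": 1.0},
                          baseline_s=120.0, encounter_s=120.0)
        sess, _, _ = simulate_session(cfg, "M01", "SP", 1, seed=11, regions=["PrL"])
        s = delta_band_power(sess, "PrL", "theta")
        assert s.mean_encounter_power / s.mean_baseline_power == pytest.approx(2.25, rel=0.1)
        g = delta_band_power(sess, "PrL", "gamma")
        assert g.delta == pytest.approx(0.0, abs=0.15 * g.mean_baseline_power)

    def test_null_delta_near_zero(self):
        cfg = fast_config(encounter_gain={"theta": 1.0, "gamma": 1.0},
                          baseline_s=120.0, encounter_s=120.0)
        sess, _, _ = simulate_session(cfg, "M01", "SP", 1, seed=12, regions=["PrL"])
        s = delta_band_power(sess, "PrL", "theta")
        assert abs(s.delta) < 0.1 * s.mean_baseline_power


class TestBoutBandPower:
    def _toy_tf(self):
        """Piecewise-constant theta power: bouts at {4, 6, 8}, baseline 2."""
        freqs = np.arange(0, 101, 0.5)
        times = np.arange(0.25, 120, 0.5)
        power = np.full((len(freqs), len(times)), 2.0)
        for (lo, hi), v in zip([(70, 80), (85, 95), (100, 110)], [4.0, 6.0, 8.0]):
            power[:, (times >= lo) & (times < hi)] = v
        return TimeFrequencyPower(power, freqs, times, 2.0, 0.5)

    def test_hand_built_three_bout_toy(self):
        from sblfp.datamodel import RecordingSession

        sess = RecordingSession(
            "M01", "SP", 1, 500.0, np.zeros((1, 60_000), dtype=np.float32), ["PrL"],
            (0.0, 60.0), (60.0, 120.0), {"left": "social", "right": "object"},
            60.0, 120.0,
        )
        bouts = make_bout_table(
            [("s", "empty", "l", 10.0, 40.0)]
            + [("s", "social", "l", a, b) for a, b in [(70, 80), (85, 95), (100, 110)]]
        )
        out = bout_band_power(sess, bouts, "PrL", "theta", tf=self._toy_tf())
        # equal durations: duration-weighted mean = mean(4,6,8) - 2 = 4
        assert out["social"] == pytest.approx(4.0)

    def test_missing_stimulus_yields_nan(self, tiny_session):
        sess, bouts = tiny_session
        only_empty = bouts[bouts["stimulus"] == "empty"]
        with pytest.warns(UserWarning, match="omitted"):
            out = bout_band_power(sess, only_empty, sess.region_labels[0], "theta")
        assert all(np.isnan(v) for v in out.values())


class TestEventZscore:
    def _tf_with_step(self, t_step=60.0, gain=4.0):
        rng = np.random.default_rng(5)
        freqs = np.arange(0, 101, 0.5)
        times = np.arange(0.25, 120, 0.5)
        power = rng.random((len(freqs), len(times))) + 1.0
        power[:, times >= t_step] *= gain
        return TimeFrequencyPower(power, freqs, times, 2.0, 0.5)

    def test_constant_power_zero_z(self):
        freqs = np.arange(0, 101, 0.5)
        times = np.arange(0.25, 60, 0.5)
        tf = TimeFrequencyPower(np.full((len(freqs), len(times)), 2.0), freqs, times, 2.0, 0.5)
        ev = [BehavioralEvent("bout_start", 30.0, "social")]
        z = event_zscore(tf, ev, "theta")
        assert z.n_events == 0  # zero pre-event SD -> dropped

    def test_step_gives_positive_post_z(self):
        tf = self._tf_with_step()
        ev = [BehavioralEvent("bout_start", 60.0, "social")]
        z = event_zscore(tf, ev, "theta")
        assert z.n_events == 1
        pre = z.z[z.lags < 0]
        post = z.z[z.lags > 0]
        assert abs(pre.mean()) < 1.0 and post.mean() > 3.0

    def test_mean_matches_brute_force_averaging(self):
        """Averaging order: z per event first, then mean across events."""
        rng = np.random.default_rng(6)
        freqs = np.arange(0, 101, 0.5)
        times = np.arange(0.25, 300, 0.5)
        power = rng.random((len(freqs), len(times))) + 0.5
        tf = TimeFrequencyPower(power, freqs, times, 2.0, 0.5)
        ev_times = np.arange(20.0, 280.0, 10.0)
        events = [BehavioralEvent("bout_start", t, "social") for t in ev_times]
        z = event_zscore(tf, events, "theta")
        # brute-force oracle
        s = band_power_series(tf, "theta").to_numpy()
        traces = []
        for t in ev_times:
            k = int(np.searchsorted(times, t))
            seg = s[k - 10:k + 10]
            pre = seg[:10]
            traces.append((seg - pre.mean()) / pre.std(ddof=1))
        np.testing.assert_allclose(z.z, np.mean(traces, axis=0), rtol=1e-10)
        assert z.n_events == len(ev_times)

    def test_rescaling_invariance(self):
        tf = self._tf_with_step()
        ev = [BehavioralEvent("bout_start", 60.0, "social")]
        z1 = event_zscore(tf, ev, "theta")
        tf_scaled = TimeFrequencyPower(tf.power * 7.3, tf.freqs, tf.times, 2.0, 0.5)
        z2 = event_zscore(tf_scaled, ev, "theta")
        np.testing.assert_allclose(z1.z, z2.z, rtol=1e-10)


class TestCompareCategories:
    def test_constructed_offset_detected(self):
        rng = np.random.default_rng(7)
        lags = np.arange(-4.75, 5.0, 0.5)
        from sblfp.power import EventAlignedZ

        za = [EventAlignedZ("bout_start", "a", lags,
                            rng.standard_normal(len(lags)) + np.where(lags >= 0, 1.5, 0),
                            5) for _ in range(10)]
        zb = [EventAlignedZ("bout_start", "b", lags, rng.standard_normal(len(lags)), 5)
              for _ in range(10)]
        res = compare_event_categories(za, zb, paired=True)
        assert res.p < 0.01

    def test_identical_categories_zero_difference(self):
        rng = np.random.default_rng(8)
        lags = np.arange(-4.75, 5.0, 0.5)
        from sblfp.power import EventAlignedZ

        za = [EventAlignedZ("bout_start", "a", lags, rng.standard_normal(len(lags)), 5)
              for _ in range(6)]
        res = compare_event_categories(za, za, paired=True)
        assert res.p == pytest.approx(1.0)

    def test_insufficient_sessions_error(self):
        from sblfp.power import EventAlignedZ

        lags = np.arange(-4.75, 5.0, 0.5)
        z = [EventAlignedZ("bout_start", "a", lags, np.zeros(len(lags)), 1)]
        with pytest.raises(ValueError):
            compare_event_categories(z, z)
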