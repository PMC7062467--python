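import numpy as np
import pytest

from fictloc.core_signals import Epoch, TimeSeries
from fictloc.ventral_root import (
    BurstDetectionParams,
    BurstTable,
    burst_metrics,
    detect_bursts,
    epoch_compare,
    rectify_integrate,
    timecourse_normalize,
)


def square_burst_raw(rate=1000.0, total_s=60.0, on_s=1.0, off_s=3.0, gain=5.0,
                     baseline=0.2, seed=7):
    """Deterministic square-envelope burst train: noise carrier x envelope."""
    rng = np.random.default_rng(seed)
    n = int(total_s * rate)
    t = np.arange(n) / rate
    period = on_s + off_s
    env = baseline + gain * (np.mod(t, period) < on_s)
    return TimeSeries(env * rng.normal(size=n), sampling_rate_hz=rate)


class TestRectifyIntegrate:
    def test_step_response_closed_form(self, make_ts):
        # delayed unit step at 1 kHz, tau = 50 ms
        rate, tau = 1000.0, 0.05
        x = np.zeros(500)
        x[100:] = 1.0
        y = rectify_integrate(make_ts(x, rate=rate), tau_s=tau)
        # the ZOH update holds the input over (t[i-1], t[i]], so the step
        # effectively starts at the last zero sample (index 99)
        i = 99 + int(round(tau * rate))  # tau after the step onset
        assert y.values[i] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-3)

    def test_full_step_curve(self, make_ts):
        rate, tau = 1000.0, 0.05
        x = np.zeros(1000)
        x[100:] = 1.0
        y = rectify_integrate(make_ts(x, rate=rate), tau_s=tau)
        t = (np.arange(1000) - 99) / rate  # step onset at the last zero sample
        expected = np.where(t > 0, 1.0 - np.exp(-np.maximum(t, 0) / tau), 0.0)
        # exact discretization matches the continuous response sample for sample
        np.testing.assert_allclose(y.values, expected, atol=1e-3)

    def test_zero_input_zero_output(self, make_ts):
        y = rectify_integrate(make_ts(np.zeros(100)))
        assert np.all(y.values == 0.0)

    def test_rectified_sine_steady_state_mean(self, make_ts):
        rate = 10000.0
        t = np.arange(int(rate)) / rate
        x = np.sin(2 * np.pi * 100 * t)
        y = rectify_integrate(make_ts(x, rate=rate), tau_s=0.05)
        steady = y.values[int(0.5 * rate):]
        assert np.mean(steady) == pytest.approx(2.0 / np.pi, rel=0.01)

    def test_tau_below_sample_interval_errors(self, make_ts):
        with pytest.raises(ValueError, match="sample interval"):
            rectify_integrate(make_ts(np.ones(10), rate=10.0), tau_s=0.01)


class TestDetectBursts:
    def test_square_train_counts_and_durations(self):
        raw = square_burst_raw()
        y = rectify_integrate(raw)
        bursts = detect_bursts(y)
        assert len(bursts) == 15
        intervals = np.diff(bursts.onset_s)
        np.testing.assert_allclose(intervals, 4.0, atol=0.05)
        np.testing.assert_allclose(bursts.duration_s, 1.0, atol=0.1)

    def test_noise_only_is_empty(self, rng):
        raw = TimeSeries(rng.normal(size=60000), sampling_rate_hz=1000.0)
        y = rectify_integrate(raw)
        bursts = detect_bursts(y, BurstDetectionParams(threshold_k=5.0))
        assert len(bursts) == 0

    def test_close_events_merge(self, make_ts):
        # synthetic integrated-like trace: two boxes 50 ms apart
        y = np.zeros(5000)
        y[1000:1400] = 1.0
        y[1450:1850] = 1.0
        bursts = detect_bursts(
            make_ts(y + 1e-3 * np.sin(np.arange(5000))),
            BurstDetectionParams(merge_gap_s=0.1, min_duration_s=0.3, refine_frac=0.0),
        )
        assert len(bursts) == 1

    def test_flat_trace_warns_empty(self, make_ts):
        with pytest.warns(UserWarning, match="flat"):
            bursts = detect_bursts(make_ts(np.zeros(1000)))
        assert len(bursts) == 0

    def test_gain_invariance(self):
        raw = square_burst_raw(seed=11)
        y1 = rectify_integrate(raw)
        y2 = rectify_integrate(raw.with_values(raw.values * 7.5))
        b1, b2 = detect_bursts(y1), detect_bursts(y2)
        np.testing.assert_allclose(b1.onset_s, b2.onset_s)
        np.testing.assert_allclose(b1.duration_s, b2.duration_s)
        m1 = burst_metrics(b1, raw)
        m2 = burst_metrics(b2, raw.with_values(raw.values * 7.5))
        np.testing.assert_allclose(
            m2["per_burst_amplitude"], 7.5 * m1["per_burst_amplitude"], rtol=1e-9
        )

    @pytest.mark.parametrize("snr", [5.0, 10.0, 20.0])
    def test_recovery_across_snr(self, snr):
        from fictloc.synthetic_data import ScenarioConfig, gen_ventral_root

        cfg = ScenarioConfig(seed=int(snr), duration_s=300.0)
        cfg.vr.burst_gain = snr * cfg.vr.baseline_gain
        raw, truth = gen_ventral_root(cfg)
        bursts = detect_bursts(rectify_integrate(raw))
        tb = truth["bursts"]
        true_freq = (len(tb) - 1) / (tb.onset_s[-1] - tb.onset_s[0])
        m = burst_metrics(bursts, raw)
        assert m["frequency_hz"] == pytest.approx(true_freq, rel=0.05)
        assert m["mean_duration_s"] == pytest.approx(np.mean(tb.duration_s), rel=0.05)


class TestBurstTable:
    def test_invariants(self):
        with pytest.raises(ValueError):
            BurstTable(onset_s=[0.0, 1.0], offset_s=[0.5, 0.5])
        with pytest.raises(ValueError):
            BurstTable(onset_s=[1.0, 0.0], offset_s=[1.5, 0.5])

    def test_frame_round_trip(self):
        b = BurstTable(onset_s=[0.0, 4.0], offset_s=[2.0, 6.0], amplitude=[1.0, 2.0])
        back = BurstTable.from_frame(b.to_frame())
        np.testing.assert_array_equal(back.onset_s, b.onset_s)
        np.testing.assert_array_equal(back.amplitude, b.amplitude)


class TestBurstMetrics:
    def test_amplitude_exact_on_clean_signal(self, make_ts):
        rate = 1000.0
        x = np.zeros(10000)
        x[1000:2000] = 3.0
        x[5000:6000] = -3.0  # rectification
        bursts = BurstTable(onset_s=[1.0, 5.0], offset_s=[2.0, 6.0])
        m = burst_metrics(bursts, make_ts(x, rate=rate))
        np.testing.assert_allclose(m["per_burst_amplitude"], [3.0, 3.0])

    def test_frequency_from_onsets(self, make_ts):
        bursts = BurstTable(onset_s=[0.0, 4.0, 8.0], offset_s=[2.0, 6.0, 10.0])
        m = burst_metrics(bursts, make_ts(np.zeros(12000) + 0.0, rate=1000.0))
        assert m["frequency_hz"] == pytest.approx(0.25)
        assert m["frequency_defined"]

    def test_single_burst_frequency_flagged(self, make_ts):
        bursts = BurstTable(onset_s=[1.0], offset_s=[2.0])
        m = burst_metrics(bursts, make_ts(np.ones(5000), rate=1000.0))
        assert not m["frequency_defined"]
        assert np.isnan(m["frequency_hz"])
        assert np.isfinite(m["mean_duration_s"])


class TestTimecourse:
    def test_constant_metric_everywhere_100(self):
        times = np.arange(0.0, 1200.0, 4.0)
        values = np.full(times.size, 7.0)
        tc = timecourse_normalize(times, values, Epoch("pre", 0.0, 600.0))
        assert np.nanmax(np.abs(tc.metric_pct - 100.0)) < 1e-9

    def test_doubling_after_pre_is_200(self):
        times = np.arange(0.0, 1200.0, 4.0)
        values = np.where(times < 600.0, 5.0, 10.0)
        tc = timecourse_normalize(times, values, Epoch("pre", 0.0, 600.0))
        post = tc.metric_pct[tc.bin_start_s >= 600.0]
        np.testing.assert_allclose(post, 200.0)

    def test_empty_bin_is_missing(self):
        times = np.array([1.0, 2.0, 100.0])  # nothing in [30, 60)
        values = np.ones(3)
        tc = timecourse_normalize(times, values, Epoch("pre", 0.0, 30.0))
        assert np.isnan(tc.metric_pct[1])

    def test_zero_pre_mean_errors(self):
        times = np.arange(0.0, 700.0, 4.0)
        with pytest.raises(ValueError, match="zero"):
            timecourse_normalize(times, np.zeros(times.size), Epoch("pre", 0.0, 600.0))

    def test_no_pre_bursts_errors(self):
        with pytest.raises(ValueError, match="no bursts"):
            timecourse_normalize(np.array([700.0]), np.array([1.0]), Epoch("pre", 0.0, 600.0))


class TestEpochCompare:
    def test_identical_epochs_ratio_100(self):
        times = np.arange(0.0, 1200.0, 4.0)
        values = np.full(times.size, 3.0)
        epochs = [Epoch("control", 0.0, 600.0), Epoch("drug", 600.0, 1200.0)]
        df = epoch_compare(times, values, epochs)
        means = df.set_index("epoch")["mean"]
        assert means["drug"] / means["control"] == pytest.approx(1.0)

    def test_short_epoch_named_in_error(self):
        with pytest.raises(ValueError, match="drug"):
            epoch_compare(
                np.array([0.0]), np.array([1.0]),
                [Epoch("control", 0.0, 600.0), Epoch("drug", 600.0, 700.0)],
            )

    def test_window_is_final_portion(self):
        times = np.arange(0.0, 600.0, 1.0)
        values = np.where(times < 450.0, 0.0, 8.0)  # jump inside final window
        df = epoch_compare(times, values, [Epoch("only", 0.0, 600.0)], window_s=150.0)
        assert df["mean"].iloc[0] == pytest.approx(8.0)
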