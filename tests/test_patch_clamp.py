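import warnings

import numpy as np
import pytest

from fictloc.core_signals import Epoch, TimeSeries
from fictloc.patch_clamp import (
    Sweep,
    _has_block,
    depolarizing_block,
    detect_spikes,
    extract_spike_features,
    half_width,
    holding_current_change,
    input_resistance,
    interspike_ahp,
    mAHP_amplitude,
    max_firing,
    ramp_threshold,
    rheobase,
    spike_onset,
    spontaneous_rate,
)

RATE = 10000.0


def v_ts(values, rate=RATE, start=0.0):
    return TimeSeries(np.asarray(values, dtype=float), sampling_rate_hz=rate,
                      start_time_s=start, units="mV")


def triangle_spike(n=2000, i0=800, rise_n=5, fall_n=15, rest=-60.0, amp=60.0, ahp=8.0):
    """Piecewise-linear spike with analytically known half-width."""
    v = np.full(n, rest)
    pk = i0 + rise_n
    tr = pk + fall_n
    v[i0 : pk + 1] = rest + amp * np.arange(rise_n + 1) / rise_n
    v[pk : tr + 1] = (rest + amp) - (amp + ahp) * np.arange(fall_n + 1) / fall_n
    v[tr + 1 :] = rest - ahp + (ahp) * (1 - np.exp(-np.arange(n - tr - 1) / 200.0))
    hw_ms = 1e3 / RATE * (rise_n / 2 + fall_n * (amp / 2) / (amp + ahp))
    return v, pk, hw_ms


class TestDetectSpikes:
    def test_five_injected_spikes(self):
        v = np.full(20000, -60.0)
        peaks = [2000, 6000, 10000, 14000, 18000]
        for p in peaks:
            v[p - 5 : p + 6] = np.concatenate(
                [np.linspace(-60, 20, 6), np.linspace(20, -60, 6)[1:]]
            )
        ev = detect_spikes(v_ts(v))
        assert len(ev) == 5
        np.testing.assert_allclose(ev.times_s, np.array(peaks) / RATE, atol=1.5 / RATE)

    def test_subthreshold_empty(self, rng):
        ev = detect_spikes(v_ts(-60.0 + rng.normal(0, 2, 5000)))
        assert len(ev) == 0

    def test_refractory_merges_close_peaks(self):
        v = np.full(1000, -60.0)
        v[500] = 10.0
        v[504] = 12.0  # 0.4 ms later
        ev = detect_spikes(v_ts(v))
        assert len(ev) == 1


class TestSpikeOnset:
    def test_linear_rise_onset(self):
        v = np.full(2000, -60.0)
        t0 = 1000
        # 20 mV/ms rise = 2 mV/sample at 10 kHz
        ramp = -60.0 + 2.0 * np.arange(40)
        v[t0 : t0 + 40] = ramp
        v[t0 + 40 :] = ramp[-1]
        onset = spike_onset(v_ts(v), peak_s=(t0 + 39) / RATE)
        assert onset is not None
        assert onset[0] == pytest.approx(t0 / RATE, abs=1.5 / RATE)

    def test_gaussian_spike_matches_analytic_root(self):
        # V(t) = A exp(-(t-tp)^2 / 2 sigma^2) + rest; dV/dt = 10 mV/ms has a
        # closed-form first crossing on the rising flank
        amp, sigma, rest = 80.0, 0.0005, -60.0
        tp = 0.1
        t = np.arange(int(0.2 * RATE)) / RATE
        v = rest + amp * np.exp(-((t - tp) ** 2) / (2 * sigma**2))
        onset = spike_onset(v_ts(v), peak_s=tp)
        assert onset is not None
        # analytic: solve A * (tp-t)/sigma^2 * exp(-(tp-t)^2/2sigma^2) = 10 mV/ms
        crit = 10.0 * 1e3  # mV/s
        ts_grid = np.linspace(tp - 6 * sigma, tp, 200000)
        dvdt = amp * (tp - ts_grid) / sigma**2 * np.exp(-((tp - ts_grid) ** 2) / (2 * sigma**2))
        t_analytic = ts_grid[np.argmax(dvdt >= crit)]
        assert onset[0] == pytest.approx(t_analytic, abs=2.0 / RATE)

    def test_slow_rise_flagged(self):
        v = np.full(2000, -60.0)
        # 5 mV/ms: never meets the criterion
        v[1000:1200] = -60.0 + 0.5 * np.arange(200)
        assert spike_onset(v_ts(v), peak_s=1199 / RATE, search_window_s=0.02) is None


class TestHalfWidth:
    def test_triangular_construction(self):
        v, pk, hw_true = triangle_spike()
        onset = spike_onset(v_ts(v), pk / RATE)
        hw = half_width(v_ts(v), onset, (pk / RATE, v[pk]))
        assert hw == pytest.approx(hw_true, abs=0.05)

    def test_gaussian_fwhm(self):
        amp, sigma, rest = 80.0, 0.0004, -60.0
        tp = 0.05
        t = np.arange(int(0.1 * RATE)) / RATE
        v = rest + amp * np.exp(-((t - tp) ** 2) / (2 * sigma**2))
        fs = extract_spike_features(v_ts(v))
        assert len(fs.half_width_ms) == 1
        # onset voltage is slightly above rest, so the measured width sits just
        # under the full FWHM = 2.355 sigma; one-sample tolerance
        assert fs.half_width_ms[0] == pytest.approx(2.355 * sigma * 1e3, abs=1e3 / RATE)

    def test_offset_and_time_shift_invariance(self):
        v, pk, _ = triangle_spike()
        ts0 = v_ts(v)
        onset0 = spike_onset(ts0, pk / RATE)
        hw0 = half_width(ts0, onset0, (pk / RATE, v[pk]))
        ts1 = v_ts(v + 17.0, start=3.0)
        onset1 = spike_onset(ts1, 3.0 + pk / RATE)
        hw1 = half_width(ts1, onset1, (3.0 + pk / RATE, v[pk] + 17.0))
        assert hw1 == pytest.approx(hw0, abs=1e-9)

    def test_truncated_sweep_flagged(self):
        v, pk, _ = triangle_spike()
        short = v[: pk + 2]  # cut before the falling crossing
        onset = spike_onset(v_ts(short), pk / RATE)
        assert half_width(v_ts(short), onset, (pk / RATE, short[pk])) is None


def brief_pulse_sweep(trough_depth=5.0, rest=-60.0, noise=0.0, rng=None, rate=RATE):
    n = int(0.5 * rate)
    cmd = np.zeros(n)
    i0 = int(0.1 * rate)
    cmd[i0 : i0 + int(0.01 * rate)] = 500.0
    v = np.full(n, rest)
    pk = i0 + 30
    v[pk - 5 : pk + 1] = np.linspace(rest, 10.0, 6)
    fall = np.linspace(10.0, rest - 1.0, 21)
    v[pk : pk + 21] = fall
    # slow trough at +40 ms, exactly trough_depth below rest
    tt = np.arange(n - pk - 21) / rate
    alpha = (tt + 0.0021) / 0.04 * np.exp(1 - (tt + 0.0021) / 0.04)
    v[pk + 21 :] = rest - trough_depth * np.minimum(alpha, 1.0)
    if noise and rng is not None:
        v = v + rng.normal(0, noise, n)
    return Sweep(
        command=TimeSeries(cmd, rate, units="pA"),
        response=TimeSeries(v, rate, units="mV"),
        protocol_tag="brief_pulse",
    )


class TestMAHP:
    def test_identical_sweeps_exact(self):
        sweeps = [brief_pulse_sweep(trough_depth=5.0) for _ in range(15)]
        assert mAHP_amplitude(sweeps) == pytest.approx(5.0, abs=0.01)

    def test_estimator_sd_under_noise(self):
        """Monte-Carlo: with additive noise the estimator SD stays below the
        sigma*sqrt(2)/sqrt(15) bound for two independent noisy terms."""
        rng = np.random.default_rng(5)
        sigma = 1.0
        estimates = [
            mAHP_amplitude([brief_pulse_sweep(5.0, noise=sigma, rng=rng) for _ in range(15)])
            for _ in range(200)
        ]
        sd = np.std(estimates)
        assert sd <= sigma * np.sqrt(2) / np.sqrt(15) * 1.2
        # extreme-value bias of min-over-window grows with noise; bounded here
        assert abs(np.mean(estimates) - 5.0) < 1.0

    def test_no_dip_warns(self):
        sweeps = [brief_pulse_sweep(trough_depth=-0.5) for _ in range(15)]
        with pytest.warns(UserWarning, match="dip"):
            amp = mAHP_amplitude(sweeps)
        assert amp <= 0

    def test_multi_spike_sweeps_excluded(self):
        good = [brief_pulse_sweep(5.0) for _ in range(15)]
        bad = brief_pulse_sweep(5.0)
        bad.response.values[2000:2010] = 20.0  # second spike
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            amp = mAHP_amplitude(good + [bad])
        assert amp == pytest.approx(5.0, abs=0.01)


def train_sweep(n_spikes=8, isi_n=800, trough=8.0, rest=-60.0, rate=RATE):
    n = int(1.5 * rate)
    cmd = np.zeros(n)
    i_step0, i_step1 = int(0.2 * rate), int(1.2 * rate)
    cmd[i_step0:i_step1] = 300.0
    v = np.full(n, rest)
    base = -45.0
    v[i_step0:i_step1] = base
    for k in range(n_spikes):
        i0 = i_step0 + 300 + k * isi_n
        pk = i0 + 5
        v[i0 : pk + 1] = np.linspace(base, 15.0, 6)
        v[pk : pk + 16] = np.linspace(15.0, base - trough, 16)
        nxt = min(i_step0 + 300 + (k + 1) * isi_n, i_step1)
        seg = np.arange(nxt - pk - 16)
        v[pk + 16 : nxt] = base - trough * np.exp(-seg / 100.0)
    return Sweep(
        command=TimeSeries(cmd, rate, units="pA"),
        response=TimeSeries(v, rate, units="mV"),
        protocol_tag="step",
    )


class TestInterspikeAHP:
    def test_constant_trough_exact(self):
        sw = train_sweep(trough=8.0)
        assert interspike_ahp(sw) == pytest.approx(8.0, abs=0.01)

    def test_few_spikes_warns_and_uses_available(self):
        sw = train_sweep(n_spikes=4)
        with pytest.warns(UserWarning, match="intervals"):
            amp = interspike_ahp(sw, k_last=5)
        assert amp == pytest.approx(8.0, abs=0.01)

    def test_single_spike_errors(self):
        sw = train_sweep(n_spikes=1)
        with pytest.raises(ValueError):
            interspike_ahp(sw)

    @pytest.mark.parametrize("depth", [4.0, 8.0, 12.0])
    def test_depth_recovery_from_generator(self, depth):
        from fictloc.synthetic_data import ScenarioConfig, gen_patch_sweeps

        cfg = ScenarioConfig(seed=int(depth))
        cfg.cell.spike.interspike_ahp_mV = depth
        sweeps, truth = gen_patch_sweeps(cfg, "step")
        rates = []
        for sw in sweeps:
            ev = detect_spikes(sw.response)
            t = ev.times_s
            rates.append((t.size - 1) / (t[-1] - t[0]) if t.size >= 2 else -np.inf)
        best = sweeps[int(np.argmax(rates))]
        assert interspike_ahp(best) == pytest.approx(depth, abs=0.5)


class TestRheobase:
    def test_first_firing_step(self):
        assert rheobase([(10, 0), (60, 0), (110, 3), (160, 8)]) == (110.0, False)

    def test_first_step_fires(self):
        assert rheobase([(10, 2), (60, 5)]) == (10.0, False)

    def test_censored(self):
        current, censored = rheobase([(10, 0), (60, 0)])
        assert current is None and censored


class TestDepolarizingBlock:
    def test_burst_then_silence_is_block(self):
        t = np.array([0.25, 0.31, 0.37, 0.43, 0.49])
        assert _has_block(t, step_end_s=1.2)

    def test_90ms_pause_is_not_block(self):
        t = np.array([0.25, 0.31, 0.37, 0.46, 0.52, 0.58, 0.64, 0.70, 0.76, 0.82,
                      0.88, 0.94, 1.00, 1.06, 1.12, 1.18])
        assert not _has_block(t, step_end_s=1.2)

    def test_slow_regular_firing_never_establishes(self):
        t = np.arange(0.25, 1.15, 0.15)  # ISI 150 ms
        assert not _has_block(t, step_end_s=1.2)

    def test_generator_block_exact(self):
        from fictloc.synthetic_data import ScenarioConfig, gen_patch_sweeps

        cfg = ScenarioConfig(seed=3)
        sweeps, truth = gen_patch_sweeps(cfg, "step")
        current, censored = depolarizing_block(sweeps)
        assert not censored
        assert current == truth["block_pA"]

    def test_never_blocking_censored(self):
        from fictloc.synthetic_data import ScenarioConfig, gen_patch_sweeps

        cfg = ScenarioConfig(seed=3)
        cfg.cell.fI.block_pA = 1e9  # never blocks
        cfg.cell.fI.max_current_pA = 860.0
        sweeps, _ = gen_patch_sweeps(cfg, "step")
        current, censored = depolarizing_block(sweeps)
        assert censored and current is None


class TestMaxFiring:
    def test_max_of_rates(self):
        results = [
            (110.0, np.array([0.3, 0.5, 0.7])),          # 5 Hz
            (160.0, np.array(np.arange(0.25, 1.2, 0.05))),  # 20 Hz
            (210.0, np.array(np.arange(0.25, 1.2, 0.0833))),
        ]
        rate, at = max_firing(results)
        assert rate == pytest.approx(20.0)
        assert at == 160.0

    def test_tie_goes_to_lower_current(self):
        t = np.arange(0.25, 1.2, 0.1)
        rate, at = max_firing([(210.0, t), (160.0, t)])
        assert at == 160.0

    def test_no_multi_spike_step_errors(self):
        with pytest.raises(ValueError):
            max_firing([(110.0, np.array([0.5]))])


class TestInputResistance:
    @staticmethod
    def _vc_sweep(level, r_mohm=100.0, hold=-60.0, noise=0.0, rng=None, rate=1000.0):
        n = int(0.6 * rate)
        cmd = np.full(n, hold)
        cmd[int(0.1 * rate):] = level
        i = (cmd - (-60.0)) / r_mohm * 1000.0
        if noise and rng is not None:
            i = i + rng.normal(0, noise, n)
        return Sweep(
            command=TimeSeries(cmd, rate, units="mV"),
            response=TimeSeries(i, rate, units="pA"),
            protocol_tag="vc_steps",
        )

    def test_ideal_ohmic_exact(self):
        sweeps = [self._vc_sweep(v) for v in (-75.0, -72.5, -70.0, -67.5)]
        assert input_resistance(sweeps) == pytest.approx(100.0, abs=1e-6)

    def test_noise_within_5pct(self, rng):
        sweeps = [
            self._vc_sweep(v, noise=2.0, rng=rng)
            for v in np.arange(-75.0, -52.4, 2.5)
        ]
        assert input_resistance(sweeps) == pytest.approx(100.0, rel=0.05)

    def test_two_levels_errors(self):
        sweeps = [self._vc_sweep(v) for v in (-75.0, -72.5)]
        with pytest.raises(ValueError):
            input_resistance(sweeps)

    def test_order_invariance(self):
        levels = [-75.0, -70.0, -65.0, -55.0]
        a = input_resistance([self._vc_sweep(v) for v in levels])
        b = input_resistance([self._vc_sweep(v) for v in levels[::-1]])
        assert a == pytest.approx(b)

    def test_nonmonotone_warns(self):
        sweeps = [self._vc_sweep(v) for v in (-75.0, -70.0, -65.0)]
        sweeps[1].response.values[:] = 150.0  # saturated middle level
        with pytest.warns(UserWarning, match="r²"):
            input_resistance(sweeps)


class TestHoldingCurrent:
    def test_plateau_shift(self, make_ts):
        rate = 100.0
        i = np.full(int(180 * rate), -50.0)
        i[int(60 * rate):] = -152.0
        ts = TimeSeries(i, rate, units="pA")
        assert holding_current_change(ts, 60.0, "inward") == pytest.approx(-102.0)

    def test_no_effect_near_zero(self, rng):
        rate = 100.0
        ts = TimeSeries(-50.0 + rng.normal(0, 2, int(180 * rate)), rate, units="pA")
        assert abs(holding_current_change(ts, 60.0, "auto")) < 2.0

    def test_injected_delta_recovered(self):
        from fictloc.synthetic_data import gen_holding_current_trace

        ts, truth = gen_holding_current_trace(-37.0, rng=np.random.default_rng(2))
        delta = holding_current_change(ts, truth["drug_onset_s"], "inward")
        assert delta == pytest.approx(-37.0, abs=3.0)

    def test_onset_outside_span_errors(self, make_ts):
        ts = TimeSeries(np.zeros(100), 10.0, units="pA")
        with pytest.raises(ValueError):
            holding_current_change(ts, 100.0)


class TestRampThreshold:
    def test_generator_threshold_recovered(self):
        from fictloc.synthetic_data import ScenarioConfig, gen_patch_sweeps

        cfg = ScenarioConfig(seed=8)
        cfg.cell.threshold_mV = -45.0
        sweeps, truth = gen_patch_sweeps(cfg, "ramp")
        assert ramp_threshold(sweeps[0]) == pytest.approx(-45.0, abs=1.0)

    def test_first_spike_used(self):
        from fictloc.synthetic_data import ScenarioConfig, gen_patch_sweeps

        cfg = ScenarioConfig(seed=9)
        sweeps, truth = gen_patch_sweeps(cfg, "ramp")
        ev = detect_spikes(sweeps[0].response)
        assert len(ev) >= 2  # the measure must come from the first one
        onset = spike_onset(sweeps[0].response, float(ev.times_s[0]))
        assert ramp_threshold(sweeps[0]) == pytest.approx(onset[1])

    def test_subthreshold_ramp_errors(self):
        from fictloc.synthetic_data import ScenarioConfig, gen_patch_sweeps

        cfg = ScenarioConfig(seed=10)
        sweeps, _ = gen_patch_sweeps(cfg, "ramp", i_max_pA=50.0)
        with pytest.raises(ValueError):
            ramp_threshold(sweeps[0])


class TestSpontaneousRate:
    def test_count_over_duration(self):
        v = np.full(int(6 * RATE), -60.0)
        for k in range(12):
            p = int((0.25 + 0.47 * k) * RATE)
            v[p - 5 : p + 6] = np.concatenate(
                [np.linspace(-60, 10, 6), np.linspace(10, -60, 6)[1:]]
            )
        assert spontaneous_rate(v_ts(v), Epoch("w", 0.0, 6.0)) == pytest.approx(2.0)

    def test_no_spikes_zero(self):
        v = np.full(1000, -60.0)
        assert spontaneous_rate(v_ts(v), Epoch("w", 0.0, 0.1)) == 0.0

    def test_dc_offset_invariance(self):
        v = np.full(int(6 * RATE), -60.0)
        for k in range(6):
            p = int((0.5 + 0.9 * k) * RATE)
            v[p - 5 : p + 6] = np.concatenate(
                [np.linspace(-60, 10, 6), np.linspace(10, -60, 6)[1:]]
            )
        r0 = spontaneous_rate(v_ts(v), Epoch("w", 0.0, 6.0))
        r1 = spontaneous_rate(v_ts(v + 15.0), Epoch("w", 0.0, 6.0))
        assert r0 == r1
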