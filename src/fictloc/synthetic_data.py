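"""Seeded generators emulating the three recording modalities.

Every generator is a pure function of its config and seed and returns the
emitted traces together with a ground-truth record, so each analysis stage
has a parameter-recovery test and the full pipeline runs with no external
data.

Defaults mirror the recorded preparations: ~0.23 Hz ventral-root bursts of
~2 s, 5 Hz fluorescence frames, and 10 kHz current-clamp sweeps driven by
1 s square steps from 10 pA in 50 pA increments.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .calcium import RoiTrace
from .core_signals import Epoch, TimeSeries
from .patch_clamp import Sweep
from .ventral_root import BurstTable

__all__ = [
    "VRConfig",
    "EpochEffect",
    "CaConfig",
    "SpikeShape",
    "FIConfig",
    "CellConfig",
    "ScenarioConfig",
    "gen_ventral_root",
    "gen_calcium_cells",
    "gen_patch_sweeps",
    "gen_holding_current_trace",
    "gen_full_scenario",
]


@dataclass
class VRConfig:
    burst_rate_hz: float = 0.23
    burst_duration_s: float = 2.0
    carrier_noise_sd: float = 1.0
    burst_gain: float = 10.0
    baseline_gain: float = 1.0
    sample_rate_hz: float = 1000.0
    jitter_shape: float = 10.0  # Gamma shape of inter-onset intervals
    min_gap_s: float = 1.0  # floor on the inter-burst gap so bursts stay separable
    edge_smooth_s: float = 0.05


@dataclass
class EpochEffect:
    """An epoch together with the multipliers it applies to the generator."""

    name: str
    start_s: float
    end_s: float
    amplitude_multiplier: float = 1.0
    rate_multiplier: float = 1.0
    duration_multiplier: float = 1.0

    def to_epoch(self) -> Epoch:
        return Epoch(self.name, self.start_s, self.end_s)


@dataclass
class CaConfig:
    n_cells: int = 20
    coupled_fraction: float = 0.65
    kappa: float = 3.0
    transients_per_cycle_prob: float = 0.35
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.5
    amplitude_dff_pct_lo: float = 30.0
    amplitude_dff_pct_hi: float = 100.0
    noise_sd_pct: float = 5.0
    bleach_tau_s: float | None = None
    frame_rate_hz: float = 5.0
    f0: float = 100.0
    region: str = "L1-3"


@dataclass
class SpikeShape:
    amplitude_mV: float = 60.0
    half_width_ms: float = 1.0
    mahp_mV: float = 5.0
    interspike_ahp_mV: float = 8.0
    rise_slope_mV_per_ms: float = 150.0
    mahp_time_to_peak_s: float = 0.04
    recovery_tau_s: float = 0.01


@dataclass
class FIConfig:
    gain_hz_per_pA: float = 0.06
    rheobase_pA: float = 110.0
    block_pA: float = 510.0
    step_start_pA: float = 10.0
    step_increment_pA: float = 50.0
    step_duration_s: float = 1.0
    steps_beyond_block: int = 2
    max_current_pA: float | None = None  # overrides the grid end when set


@dataclass
class CellConfig:
    rest_mV: float = -60.0
    threshold_mV: float = -45.0
    R_MOhm: float = 80.0
    spike: SpikeShape = field(default_factory=SpikeShape)
    fI: FIConfig = field(default_factory=FIConfig)
    noise_sd_mV: float = 0.2
    sample_rate_hz: float = 10000.0


@dataclass
class ScenarioConfig:
    seed: int = 0
    duration_s: float = 600.0
    vr: VRConfig = field(default_factory=VRConfig)
    epochs: list[EpochEffect] = field(default_factory=list)
    ca: CaConfig = field(default_factory=CaConfig)
    cell: CellConfig = field(default_factory=CellConfig)

    def resolved_epochs(self) -> list[EpochEffect]:
        if self.epochs:
            return self.epochs
        return [EpochEffect("control", 0.0, self.duration_s)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        vr = VRConfig(**d.pop("vr", {}))
        epochs = [EpochEffect(**e) for e in d.pop("epochs", [])]
        ca = CaConfig(**d.pop("ca", {}))
        cell_d = dict(d.pop("cell", {}))
        spike = SpikeShape(**cell_d.pop("spike", {}))
        fi = FIConfig(**cell_d.pop("fI", {}))
        cell = CellConfig(spike=spike, fI=fi, **cell_d)
        return cls(vr=vr, epochs=epochs, ca=ca, cell=cell, **d)


# ---------------------------------------------------------------------------
# ventral root


def _multipliers_at(epochs: list[EpochEffect], t: float) -> tuple[float, float, float]:
    for e in epochs:
        if e.start_s <= t < e.end_s:
            return e.amplitude_multiplier, e.rate_multiplier, e.duration_multiplier
    return 1.0, 1.0, 1.0


def gen_ventral_root(cfg: ScenarioConfig, rng: np.random.Generator | None = None):
    """Generate a raw ventral-root trace with known bursts.

    The raw signal is zero-mean Gaussian noise multiplied by an envelope of
    ``baseline_gain + gain * smoothed square burst train``; inter-onset
    intervals are Gamma(shape=jitter_shape) so the rate has realistic but
    controllable variance.  Epoch multipliers scale the burst gain, rate and
    duration.  Returns ``(TimeSeries raw, ground truth dict)``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    vr = cfg.vr
    epochs = cfg.resolved_epochs()
    rate_fs = vr.sample_rate_hz
    n = int(round(cfg.duration_s * rate_fs))

    onsets, offsets, gains = [], [], []
    t = float(rng.gamma(vr.jitter_shape, (1.0 / vr.burst_rate_hz) / vr.jitter_shape)) * 0.5
    while t < cfg.duration_s:
        amp_m, rate_m, dur_m = _multipliers_at(epochs, t)
        dur = vr.burst_duration_s * dur_m
        if t + dur < cfg.duration_s:
            onsets.append(t)
            offsets.append(t + dur)
            gains.append(vr.burst_gain * amp_m)
        mean_isi = 1.0 / (vr.burst_rate_hz * rate_m)
        isi = float(rng.gamma(vr.jitter_shape, mean_isi / vr.jitter_shape))
        t += max(isi, dur + vr.min_gap_s)

    env = np.full(n, vr.baseline_gain)
    for on, off, g in zip(onsets, offsets, gains):
        i0, i1 = int(round(on * rate_fs)), int(round(off * rate_fs))
        env[i0:i1] += g
    if vr.edge_smooth_s > 0:
        env = gaussian_filter1d(env, vr.edge_smooth_s * rate_fs)

    raw = env * rng.normal(0.0, vr.carrier_noise_sd, n)
    ts = TimeSeries(raw, sampling_rate_hz=rate_fs, units="a.u.", channel_id="vr")
    truth = {
        "bursts": BurstTable(
            onset_s=np.array(onsets), offset_s=np.array(offsets), amplitude=np.array(gains)
        ),
        "epochs": epochs,
    }
    return ts, truth


# ---------------------------------------------------------------------------
# calcium


def _ca_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Rise/decay kernel normalized to unit peak."""
    k = (1.0 - np.exp(-np.maximum(t, 0.0) / rise_s)) * np.exp(-np.maximum(t, 0.0) / decay_s)
    t_pk = rise_s * math.log((decay_s + rise_s) / rise_s)
    peak = (1.0 - math.exp(-t_pk / rise_s)) * math.exp(-t_pk / decay_s)
    out = k / peak
    out[t < 0] = 0.0
    return out


def gen_calcium_cells(
    cfg: ScenarioConfig,
    truth_bursts: BurstTable,
    rng: np.random.Generator | None = None,
):
    """Generate per-ROI fluorescence traces phase-locked to the burst train.

    Coupled cells emit at most one transient per locomotor cycle (with
    probability ``transients_per_cycle_prob``) at a von Mises phase around
    the cell's preferred phase; uncoupled cells emit a rate-matched Poisson
    stream with uniform timing.  Events are convolved with a rise/decay
    kernel, scaled to ΔF/F amplitude, optionally bleached, and sampled with
    additive Gaussian noise at the frame rate.
    """
    if len(truth_bursts) < 2:
        raise ValueError("need at least 2 true bursts")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ca = cfg.ca
    on = truth_bursts.onset_s
    n_cycles = on.size - 1
    duration = cfg.duration_s
    n_frames = int(round(duration * ca.frame_rate_hz))
    t_frames = np.arange(n_frames) / ca.frame_rate_hz

    n_coupled = int(round(ca.n_cells * ca.coupled_fraction))
    traces, cell_truth = [], []
    for i in range(ca.n_cells):
        coupled = i < n_coupled
        mu = float(rng.uniform(0.0, 2.0 * np.pi))
        if coupled:
            fire = rng.random(n_cycles) < ca.transients_per_cycle_prob
            cyc = np.flatnonzero(fire)
            phases = np.mod(rng.vonmises(mu, ca.kappa, cyc.size), 2.0 * np.pi)
            times = on[cyc] + phases / (2.0 * np.pi) * (on[cyc + 1] - on[cyc])
        else:
            n_ev = rng.poisson(ca.transients_per_cycle_prob * n_cycles)
            times = np.sort(rng.uniform(on[0], on[-1], n_ev))
            phases = np.full(times.size, np.nan)
        order = np.argsort(times)
        times = times[order]
        amps = rng.uniform(ca.amplitude_dff_pct_lo, ca.amplitude_dff_pct_hi, times.size)

        dff = np.zeros(n_frames)
        for t_e, a_e in zip(times, amps):
            dff += a_e * _ca_kernel(t_frames - t_e, ca.kernel_rise_s, ca.kernel_decay_s)
        f = ca.f0 * (1.0 + dff / 100.0)
        if ca.bleach_tau_s:
            f = f * np.exp(-t_frames / ca.bleach_tau_s)
        f = f + rng.normal(0.0, ca.noise_sd_pct / 100.0 * ca.f0, n_frames)
        f = np.maximum(f, 1e-6)
        roi_id = f"roi{i:03d}"
        traces.append(
            RoiTrace(
                roi_id=roi_id,
                trace=TimeSeries(
                    f, sampling_rate_hz=ca.frame_rate_hz, units="a.u.", channel_id=roi_id
                ),
                region=ca.region,
            )
        )
        cell_truth.append(
            {
                "roi_id": roi_id,
                "coupled": coupled,
                "preferred_phase_rad": mu if coupled else np.nan,
                "event_times_s": times,
                "event_phases_rad": phases if coupled else np.full(times.size, np.nan),
                "event_amplitudes_pct": amps,
            }
        )
    return traces, {"cells": cell_truth, "bursts": truth_bursts}


# ---------------------------------------------------------------------------
# patch clamp


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _spike_segments(shape: SpikeShape, dt: float) -> tuple[float, float]:
    """Rise and fall durations (s), snapped to the sample grid so that the
    rendered half-width is an exact function of the parameters."""
    a = shape.amplitude_mV
    h = shape.half_width_ms * 1e-3
    t_r = max(dt, _snap(a / shape.rise_slope_mV_per_ms * 1e-3, dt))
    ahp = shape.interspike_ahp_mV
    t_f = (h - t_r / 2.0) * 2.0 * (a + ahp) / a
    t_f = max(dt, _snap(t_f, dt))
    return t_r, t_f


def true_half_width_ms(shape: SpikeShape, dt: float) -> float:
    """Half-width actually rendered for train spikes, given grid snapping."""
    t_r, t_f = _spike_segments(shape, dt)
    a, ahp = shape.amplitude_mV, shape.interspike_ahp_mV
    return 1e3 * (t_r / 2.0 + t_f * (a / 2.0) / (a + ahp))


def _alpha_fn(t: float, t_m: float) -> float:
    return (t / t_m) * math.exp(1.0 - t / t_m) if t > 0 else 0.0


def _single_spike_fall(shape: SpikeShape, dt: float) -> tuple[float, float, float]:
    """Rise/fall durations and fall depth for the single-spike (mAHP)
    renderer, solved self-consistently so the rendered half-width is an
    exact function of the parameters."""
    a = shape.amplitude_mV
    h = shape.half_width_ms * 1e-3
    t_r = max(dt, _snap(a / shape.rise_slope_mV_per_ms * 1e-3, dt))
    t_m = _snap(shape.mahp_time_to_peak_s, dt)
    depth = a
    t_f = max(dt, _snap((h - t_r / 2.0) * 2.0, dt))
    for _ in range(4):
        t_f = max(dt, _snap((h - t_r / 2.0) * 2.0 * depth / a, dt))
        depth = a + shape.mahp_mV * _alpha_fn(t_f, t_m)
    return t_r, t_f, depth


def single_spike_half_width_ms(shape: SpikeShape, dt: float) -> float:
    """Half-width actually rendered for brief-pulse single spikes."""
    t_r, t_f, depth = _single_spike_fall(shape, dt)
    return 1e3 * (t_r / 2.0 + t_f * (shape.amplitude_mV / 2.0) / depth)


def _render_spike_train(
    v: np.ndarray,
    rate: float,
    spike_onset_idx: list[int],
    base_of: np.ndarray,
    shape: SpikeShape,
) -> list[int]:
    """Render piecewise-linear spikes with exponential AHP recovery into
    ``v`` (in place), starting each spike at ``v``'s current value at its
    onset index.  Returns the peak indices."""
    dt = 1.0 / rate
    t_r, t_f = _spike_segments(shape, dt)
    n_r, n_f = int(round(t_r / dt)), int(round(t_f / dt))
    tau_rec = shape.recovery_tau_s
    peaks = []
    n = v.size
    for k, i0 in enumerate(spike_onset_idx):
        v_on = v[i0]
        i_pk = i0 + n_r
        i_tr = i_pk + n_f
        if i_tr >= n:
            break
        v_pk = v_on + shape.amplitude_mV
        v_trough = v_on - shape.interspike_ahp_mV
        v[i0 : i_pk + 1] = v_on + (v_pk - v_on) * np.arange(n_r + 1) / n_r
        v[i_pk : i_tr + 1] = v_pk + (v_trough - v_pk) * np.arange(n_f + 1) / n_f
        # exponential recovery toward the local baseline until the next spike
        i_next = spike_onset_idx[k + 1] if k + 1 < len(spike_onset_idx) else n
        i_end = min(n, i_next)
        if i_end > i_tr + 1:
            tt = np.arange(i_end - i_tr - 1) * dt
            target = base_of[i_tr + 1 : i_end]
            v[i_tr + 1 : i_end] = target + (v_trough - target[0]) * np.exp(-tt / tau_rec)
        peaks.append(i_pk)
    return peaks


def _render_single_spike_mahp(
    v: np.ndarray, rate: float, i0: int, rest: float, shape: SpikeShape
) -> int:
    """Render one spike followed by an alpha-function mAHP whose trough depth
    is exactly ``shape.mahp_mV`` below rest.  Returns the peak index."""
    dt = 1.0 / rate
    t_r, t_f, _depth = _single_spike_fall(shape, dt)
    n_r, n_f = int(round(t_r / dt)), int(round(t_f / dt))
    i_pk = i0 + n_r
    t_m = _snap(shape.mahp_time_to_peak_s, dt)
    v_on = v[i0]
    v_pk = v_on + shape.amplitude_mV

    def alpha(ts):
        x = np.maximum(ts, 0.0) / t_m
        return x * np.exp(1.0 - x)

    i_fall_end = i_pk + n_f
    t_fall_end = (i_fall_end - i_pk) * dt
    v_fall_end = rest - shape.mahp_mV * float(alpha(np.array([t_fall_end]))[0])
    v[i0 : i_pk + 1] = v_on + (v_pk - v_on) * np.arange(n_r + 1) / n_r
    v[i_pk : i_fall_end + 1] = v_pk + (v_fall_end - v_pk) * np.arange(n_f + 1) / n_f
    n = v.size
    tt = (np.arange(i_fall_end + 1, n) - i_pk) * dt
    v[i_fall_end + 1 :] = rest - shape.mahp_mV * alpha(tt)
    return i_pk


def _make_sweep(command, response, rate, tag) -> Sweep:
    return Sweep(
        command=TimeSeries(command, sampling_rate_hz=rate, units="pA" if tag != "vc_steps" else "mV"),
        response=TimeSeries(response, sampling_rate_hz=rate, units="mV" if tag != "vc_steps" else "pA"),
        protocol_tag=tag,
    )


def _gen_step_family(cell: CellConfig, rng: np.random.Generator):
    fi = cell.fI
    rate = cell.sample_rate_hz
    dt = 1.0 / rate
    pre_s, post_s = 0.2, 0.3
    dur = fi.step_duration_s
    n = int(round((pre_s + dur + post_s) * rate))
    i_step0 = int(round(pre_s * rate))
    i_step1 = int(round((pre_s + dur) * rate))
    end_margin_s = 0.05

    if fi.max_current_pA is not None:
        max_current = fi.max_current_pA
    else:
        max_current = fi.block_pA + fi.steps_beyond_block * fi.step_increment_pA
    currents = np.arange(fi.step_start_pA, max_current + 1e-9, fi.step_increment_pA)

    sweeps, truth_rows = [], []
    for current in currents:
        cmd = np.zeros(n)
        cmd[i_step0:i_step1] = current
        base = np.full(n, cell.rest_mV)
        if current < fi.rheobase_pA:
            # subthreshold RC response
            tau_m = 0.02
            tt = np.arange(i_step1 - i_step0) * dt
            dv = current * cell.R_MOhm / 1000.0
            base[i_step0:i_step1] += dv * (1.0 - np.exp(-tt / tau_m))
            tt2 = np.arange(n - i_step1) * dt
            base[i_step1:] += dv * np.exp(-tt2 / tau_m) * (1.0 - np.exp(-dur / tau_m))
            spike_idx: list[int] = []
        else:
            base[i_step0:i_step1] = cell.threshold_mV
            if current >= fi.block_pA:
                # brief burst (ISIs < 100 ms, enough to establish repetitive
                # firing) then depolarizing block for the rest of the step
                isi = 0.09
                t_first = pre_s + 0.03
                spike_idx = [int(round((t_first + j * isi) * rate)) for j in range(3)]
            else:
                f = fi.gain_hz_per_pA * (current - fi.rheobase_pA)
                if f * dur < 1.0:
                    spike_idx = [int(round((pre_s + dur / 2.0) * rate))]
                else:
                    isi = _snap(1.0 / f, dt)
                    k = int(np.floor((dur - 0.03 - end_margin_s) / isi)) + 1
                    t_last = pre_s + dur - end_margin_s
                    spike_idx = [
                        int(round((t_last - j * isi) * rate)) for j in range(k - 1, -1, -1)
                    ]
        v = base.copy()
        peaks = _render_spike_train(v, rate, spike_idx, base, cell.spike)
        v = v + rng.normal(0.0, cell.noise_sd_mV, n)
        sweeps.append(_make_sweep(cmd, v, rate, "step"))
        truth_rows.append(
            {
                "current_pA": float(current),
                "spike_times_s": np.array(peaks) / rate,
                "n_spikes": len(peaks),
                "blocked": bool(current >= fi.block_pA),
            }
        )

    firing = [r["current_pA"] for r in truth_rows if r["n_spikes"] >= 1]
    blocked = [r["current_pA"] for r in truth_rows if r["blocked"]]
    truth = {
        "steps": truth_rows,
        "rheobase_pA": min(firing) if firing else None,
        "block_pA": min(blocked) if blocked else None,
        "half_width_ms": true_half_width_ms(cell.spike, dt),
        "interspike_ahp_mV": cell.spike.interspike_ahp_mV,
    }
    rates = [
        (r["n_spikes"] - 1) / (r["spike_times_s"][-1] - r["spike_times_s"][0])
        for r in truth_rows
        if r["n_spikes"] >= 2
    ]
    curr = [r["current_pA"] for r in truth_rows if r["n_spikes"] >= 2]
    if rates:
        j = int(np.argmax(rates))
        truth["max_firing_hz"] = float(rates[j])
        truth["max_firing_at_pA"] = float(curr[j])
    return sweeps, truth


def _gen_brief_pulse_family(cell: CellConfig, rng: np.random.Generator, n_sweeps: int = 15):
    rate = cell.sample_rate_hz
    pre_s, pulse_s, total_s = 0.1, 0.01, 0.5
    n = int(round(total_s * rate))
    i_p0 = int(round(pre_s * rate))
    i_p1 = int(round((pre_s + pulse_s) * rate))
    sweeps = []
    for _ in range(n_sweeps):
        cmd = np.zeros(n)
        cmd[i_p0:i_p1] = 800.0  # supramaximal
        v = np.full(n, cell.rest_mV)
        i_spk = i_p0 + int(round(0.002 * rate))
        _render_single_spike_mahp(v, rate, i_spk, cell.rest_mV, cell.spike)
        v = v + rng.normal(0.0, cell.noise_sd_mV, n)
        sweeps.append(_make_sweep(cmd, v, rate, "brief_pulse"))
    return sweeps, {
        "mahp_mV": cell.spike.mahp_mV,
        "half_width_ms": single_spike_half_width_ms(cell.spike, 1.0 / rate),
    }


def _gen_ramp(cell: CellConfig, rng: np.random.Generator, i_max_pA: float = 800.0):
    rate = cell.sample_rate_hz
    dt = 1.0 / rate
    pre_s, ramp_s, post_s = 0.1, 1.0, 0.1
    n = int(round((pre_s + ramp_s + post_s) * rate))
    i_r0 = int(round(pre_s * rate))
    i_r1 = int(round((pre_s + ramp_s) * rate))
    cmd = np.zeros(n)
    cmd[i_r0:i_r1] = i_max_pA * np.arange(i_r1 - i_r0) / (i_r1 - i_r0)
    cmd[i_r1:] = 0.0
    base = cell.rest_mV + cmd * cell.R_MOhm / 1000.0
    base = np.minimum(base, cell.threshold_mV)
    cross = np.flatnonzero(base >= cell.threshold_mV)
    if cross.size == 0:
        v = base + rng.normal(0.0, cell.noise_sd_mV, n)
        return [_make_sweep(cmd, v, rate, "ramp")], {"threshold_mV": None}
    i_spk = int(cross[0])
    v = base.copy()
    # a short train after threshold; only the first spike is analyzed
    isi = int(round(0.08 * rate))
    idx = [i_spk + j * isi for j in range(3) if i_spk + j * isi < i_r1]
    _render_spike_train(v, rate, idx, base, cell.spike)
    v = v + rng.normal(0.0, cell.noise_sd_mV, n)
    return [_make_sweep(cmd, v, rate, "ramp")], {"threshold_mV": float(base[i_spk])}


def _gen_vc_steps(cell: CellConfig, rng: np.random.Generator, noise_sd_pA: float = 2.0):
    rate = cell.sample_rate_hz
    pre_s, step_s = 0.1, 0.5
    n = int(round((pre_s + step_s) * rate))
    i_s0 = int(round(pre_s * rate))
    hold = -60.0
    levels = np.arange(-75.0, -52.5 + 1e-9, 2.5)
    sweeps = []
    for level in levels:
        cmd = np.full(n, hold)
        cmd[i_s0:] = level
        i_resp = (cmd - cell.rest_mV) / cell.R_MOhm * 1000.0  # pA
        tt = np.arange(n - i_s0) / rate
        i_resp[i_s0:] += (hold - level) / cell.R_MOhm * 1000.0 * np.exp(-tt / 0.005)
        i_resp = i_resp + rng.normal(0.0, noise_sd_pA, n)
        sweeps.append(_make_sweep(cmd, i_resp, rate, "vc_steps"))
    return sweeps, {"R_MOhm": cell.R_MOhm}


def _gen_gapfree(cell: CellConfig, rng: np.random.Generator, rate_hz: float = 2.0,
                 duration_s: float = 10.0):
    rate = cell.sample_rate_hz
    n = int(round(duration_s * rate))
    base = np.full(n, cell.rest_mV)
    n_spk = rng.poisson(rate_hz * duration_s)
    t_spk = np.sort(rng.uniform(0.05, duration_s - 0.05, n_spk))
    # enforce a minimum separation so waveforms do not overlap
    keep = [0] if t_spk.size else []
    for i in range(1, t_spk.size):
        if t_spk[i] - t_spk[keep[-1]] > 0.05:
            keep.append(i)
    t_spk = t_spk[keep] if keep else t_spk
    idx = [int(round(t * rate)) for t in t_spk]
    v = base.copy()
    peaks = _render_spike_train(v, rate, idx, base, cell.spike)
    v = v + rng.normal(0.0, cell.noise_sd_mV, n)
    cmd = np.zeros(n)
    return [_make_sweep(cmd, v, rate, "gapfree")], {
        "spike_times_s": np.array(peaks) / rate,
        "rate_hz": len(peaks) / duration_s,
    }


def gen_patch_sweeps(
    cfg: ScenarioConfig,
    protocol: str,
    rng: np.random.Generator | None = None,
    **kwargs,
):
    """Generate a sweep family for one protocol.

    ``protocol`` is one of step | brief_pulse | ramp | vc_steps | gapfree.
    Returns ``(list[Sweep], ground truth dict)``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    cell = cfg.cell
    if protocol == "step":
        return _gen_step_family(cell, rng, **kwargs)
    if protocol == "brief_pulse":
        return _gen_brief_pulse_family(cell, rng, **kwargs)
    if protocol == "ramp":
        return _gen_ramp(cell, rng, **kwargs)
    if protocol == "vc_steps":
        return _gen_vc_steps(cell, rng, **kwargs)
    if protocol == "gapfree":
        return _gen_gapfree(cell, rng, **kwargs)
    raise ValueError(f"unknown protocol {protocol!r}")


def gen_holding_current_trace(
    delta_pA: float,
    drug_onset_s: float = 60.0,
    duration_s: float = 180.0,
    baseline_pA: float = -50.0,
    rise_tau_s: float = 10.0,
    noise_sd_pA: float = 4.0,
    sample_rate_hz: float = 100.0,
    rng: np.random.Generator | None = None,
):
    """Voltage-clamp holding-current trace with a drug-induced shift."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    i = np.full(n, baseline_pA)
    post = t >= drug_onset_s
    i[post] += delta_pA * (1.0 - np.exp(-(t[post] - drug_onset_s) / rise_tau_s))
    i = i + rng.normal(0.0, noise_sd_pA, n)
    return TimeSeries(i, sampling_rate_hz=sample_rate_hz, units="pA", channel_id="ihold"), {
        "delta_pA": delta_pA,
        "drug_onset_s": drug_onset_s,
    }


# ---------------------------------------------------------------------------
# full scenario


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    vr_raw: TimeSeries
    vr_truth: dict
    roi_traces: list
    ca_truth: dict
    patch: dict  # protocol -> (sweeps, truth)


def gen_full_scenario(cfg: ScenarioConfig, protocols: tuple[str, ...] = ("step", "brief_pulse", "ramp", "vc_steps")) -> ScenarioBundle:
    """One deterministic call producing all modalities plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    vr_raw, vr_truth = gen_ventral_root(cfg, rng)
    roi_traces, ca_truth = gen_calcium_cells(cfg, vr_truth["bursts"], rng)
    patch = {}
    for proto in protocols:
        patch[proto] = gen_patch_sweeps(cfg, proto, rng)
    return ScenarioBundle(
        config=cfg,
        vr_raw=vr_raw,
        vr_truth=vr_truth,
        roi_traces=roi_traces,
        ca_truth=ca_truth,
        patch=patch,
    )
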