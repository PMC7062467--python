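"""Intracellular feature extraction.

Passive properties, drug-induced holding currents, step-protocol
excitability (rheobase, depolarizing block, f-I, maximum firing) and
spike-waveform features (dV/dt onset, half-width, mAHP, inter-spike AHP).

Spike onsets use the dV/dt >= 10 mV/ms criterion computed by central
differences on the raw trace, with no smoothing, and half-width is the time
between the rising and falling crossings of the half-amplitude level
(linearly interpolated between samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core_signals import Epoch, EventSeries, TimeSeries

__all__ = [
    "Sweep",
    "SpikeFeatureSet",
    "ExcitabilitySummary",
    "PassiveProps",
    "detect_spikes",
    "spike_onset",
    "half_width",
    "extract_spike_features",
    "mAHP_amplitude",
    "interspike_ahp",
    "rheobase",
    "depolarizing_block",
    "max_firing",
    "input_resistance",
    "holding_current_change",
    "ramp_threshold",
    "spontaneous_rate",
]

DVDT_CRITERION_MV_PER_MS = 10.0
CENSORED = "censored_at_max"


@dataclass
class Sweep:
    """Paired command/response traces plus the protocol they belong to."""

    command: TimeSeries
    response: TimeSeries
    protocol_tag: str  # gapfree | step | brief_pulse | ramp | vc_steps

    def __post_init__(self) -> None:
        if self.command.sampling_rate_hz != self.response.sampling_rate_hz:
            raise ValueError("command and response must share a sampling rate")
        if len(self.command) != len(self.response):
            raise ValueError("command and response must share a span")


@dataclass
class SpikeFeatureSet:
    """Per-spike waveform features of one sweep."""

    peak_s: np.ndarray
    peak_mV: np.ndarray
    onset_s: np.ndarray
    onset_mV: np.ndarray
    half_width_ms: np.ndarray
    n_flagged: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_s": self.peak_s,
                "peak_mV": self.peak_mV,
                "onset_s": self.onset_s,
                "onset_mV": self.onset_mV,
                "half_width_ms": self.half_width_ms,
            }
        )


@dataclass
class ExcitabilitySummary:
    """Step-protocol outcomes for one cell.

    ``rheobase_pA`` / ``depol_block_pA`` are None when censored at the
    largest tested step (the cell never fired / never blocked).
    """

    rheobase_pA: float | None
    depol_block_pA: float | None
    max_firing_hz: float
    max_firing_at_pA: float
    fI_curve: pd.DataFrame = field(repr=False)
    rheobase_censored: bool = False
    block_censored: bool = False


@dataclass
class PassiveProps:
    input_resistance_MOhm: float
    holding_current_delta_pA: float | None = None
    resting_potential_mV: float | None = None

    def __post_init__(self) -> None:
        if not (self.input_resistance_MOhm > 0):
            raise ValueError("input resistance must be > 0")


# ---------------------------------------------------------------------------
# spike-level primitives


def detect_spikes(v: TimeSeries, peak_threshold_mV: float = -10.0) -> EventSeries:
    """Spike peaks: local maxima above threshold with >= 1 ms separation."""
    distance = max(1, int(round(1e-3 * v.sampling_rate_hz)))
    idx, _ = find_peaks(v.values, height=peak_threshold_mV, distance=distance)
    return EventSeries(times_s=v.start_time_s + idx / v.sampling_rate_hz)


def _dvdt_mv_per_ms(v: TimeSeries) -> np.ndarray:
    """dV/dt by central differences (forward/backward at the edges), mV/ms."""
    return np.gradient(v.values, 1e3 * v.dt)


def spike_onset(
    v: TimeSeries,
    peak_s: float,
    criterion_mv_per_ms: float = DVDT_CRITERION_MV_PER_MS,
    search_window_s: float = 0.02,
) -> tuple[float, float] | None:
    """Onset of a spike: walking backward from the peak, the earliest sample
    of the final contiguous run where dV/dt >= the criterion.

    Returns ``None`` when the criterion is never met within the search
    window (spike flagged, excluded from half-width statistics).
    """
    rate = v.sampling_rate_hz
    p = int(round((peak_s - v.start_time_s) * rate))
    p = min(max(p, 0), len(v) - 1)
    lo = max(0, p - int(round(search_window_s * rate)))
    dvdt = _dvdt_mv_per_ms(v)
    i = p
    # step back to enter the rising run
    while i > lo and dvdt[i] < criterion_mv_per_ms:
        i -= 1
    if dvdt[i] < criterion_mv_per_ms:
        return None
    while i > lo and dvdt[i - 1] >= criterion_mv_per_ms:
        i -= 1
    return v.start_time_s + i / rate, float(v.values[i])


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def half_width(
    v: TimeSeries,
    onset: tuple[float, float],
    peak: tuple[float, float],
    max_fall_search_s: float = 0.05,
) -> float | None:
    """Spike width (ms) at half of the onset-to-peak amplitude.

    Crossings are linearly interpolated; returns ``None`` when the falling
    crossing is absent (truncated sweep).
    """
    onset_s, onset_mv = onset
    peak_s, peak_mv = peak
    if not (onset_s < peak_s):
        raise ValueError("onset must precede peak")
    level = onset_mv + 0.5 * (peak_mv - onset_mv)
    rate = v.sampling_rate_hz
    t0 = v.start_time_s
    i_on = int(round((onset_s - t0) * rate))
    i_pk = int(round((peak_s - t0) * rate))
    y = v.values

    rise_t = None
    for i in range(i_on, i_pk):
        if y[i] < level <= y[i + 1]:
            rise_t = _interp_crossing(i / rate, (i + 1) / rate, y[i], y[i + 1], level)
            break
    if rise_t is None:
        rise_t = i_on / rate if y[i_on] >= level else None
    if rise_t is None:
        return None

    i_max = min(len(y) - 1, i_pk + int(round(max_fall_search_s * rate)))
    fall_t = None
    for i in range(i_pk, i_max):
        if y[i] >= level > y[i + 1]:
            fall_t = _interp_crossing(i / rate, (i + 1) / rate, y[i], y[i + 1], level)
            break
    if fall_t is None:
        return None
    return 1e3 * (fall_t - rise_t)


def extract_spike_features(
    v: TimeSeries, peak_threshold_mV: float = -10.0
) -> SpikeFeatureSet:
    """Detect spikes and measure onset/half-width for each.

    Spikes whose dV/dt onset criterion is never met, or whose falling
    half-amplitude crossing is absent, are flagged and dropped.
    """
    events = detect_spikes(v, peak_threshold_mV)
    rate = v.sampling_rate_hz
    rows = []
    n_flagged = 0
    for t_peak in events.times_s:
        i_pk = int(round((t_peak - v.start_time_s) * rate))
        pk_mv = float(v.values[i_pk])
        onset = spike_onset(v, t_peak)
        if onset is None:
            n_flagged += 1
            continue
        hw = half_width(v, onset, (t_peak, pk_mv))
        if hw is None:
            n_flagged += 1
            continue
        rows.append((t_peak, pk_mv, onset[0], onset[1], hw))
    if rows:
        arr = np.array(rows)
        return SpikeFeatureSet(
            peak_s=arr[:, 0],
            peak_mV=arr[:, 1],
            onset_s=arr[:, 2],
            onset_mV=arr[:, 3],
            half_width_ms=arr[:, 4],
            n_flagged=n_flagged,
        )
    empty = np.array([])
    return SpikeFeatureSet(empty, empty, empty, empty, empty, n_flagged=n_flagged)


# ---------------------------------------------------------------------------
# protocol-level measures


def _step_window(command: TimeSeries, min_delta: float = 1.0) -> tuple[int, int, float]:
    """Start/end indices and plateau amplitude of the command step
    (relative to the pre-step command level)."""
    c = command.values
    base = c[0]
    on = np.flatnonzero(np.abs(c - base) > min_delta)
    if on.size == 0:
        raise ValueError("command trace contains no step")
    i0, i1 = int(on[0]), int(on[-1]) + 1
    amp = float(np.median(c[i0:i1]) - base)
    return i0, i1, amp


def mAHP_amplitude(
    sweeps: list[Sweep],
    n_avg: int = 15,
    post_window_s: tuple[float, float] = (0.005, 0.2),
    pre_window_s: float = 0.05,
    peak_threshold_mV: float = -10.0,
) -> float:
    """mAHP after a single evoked spike, from averaged brief-pulse sweeps.

    Sweeps with zero or multiple spikes are excluded; the remainder are
    aligned on the spike peak and averaged, and the mAHP is the pre-pulse
    resting level minus the minimum in the post-spike window (positive for a
    hyperpolarization).
    """
    usable = []
    for sw in sweeps:
        ev = detect_spikes(sw.response, peak_threshold_mV)
        if len(ev) == 1:
            usable.append((sw, float(ev.times_s[0])))
    if len(usable) < 2:
        raise ValueError("need at least 2 usable single-spike sweeps")
    if len(usable) < n_avg:
        warnings.warn(
            f"only {len(usable)} usable sweeps (requested {n_avg}); averaging those",
            stacklevel=2,
        )
    usable = usable[:n_avg]

    rate = usable[0][0].response.sampling_rate_hz
    pre_n = int(round(pre_window_s * rate))
    post_lo = int(round(post_window_s[0] * rate))
    post_hi = int(round(post_window_s[1] * rate))

    segs, rests = [], []
    for sw, t_peak in usable:
        i_pk = int(round((t_peak - sw.response.start_time_s) * rate))
        i_pulse, _, _ = _step_window(sw.command)
        v = sw.response.values
        if i_pk + post_hi > v.size or i_pulse - pre_n < 0:
            continue
        rests.append(np.mean(v[i_pulse - pre_n : i_pulse]))
        segs.append(v[i_pk + post_lo : i_pk + post_hi])
    if not segs:
        raise ValueError("no sweep has complete pre/post windows")
    avg_post = np.mean(np.vstack(segs), axis=0)
    v_rest = float(np.mean(rests))
    trough = float(np.min(avg_post))
    amp = v_rest - trough
    if amp <= 0:
        warnings.warn("no post-spike dip below rest (mAHP <= 0)", stacklevel=2)
    return amp


def interspike_ahp(
    sweep: Sweep, k_last: int = 5, peak_threshold_mV: float = -10.0
) -> float:
    """Mean inter-spike AHP over the last ``k_last`` inter-spike intervals.

    AHP of an interval = onset voltage of the preceding spike minus the
    voltage trough between the two spikes (positive for a trough below
    onset).  With fewer than ``k_last + 1`` spikes all available intervals
    are used (with a warning); fewer than 2 spikes is an error.
    """
    v = sweep.response
    ev = detect_spikes(v, peak_threshold_mV)
    if len(ev) < 2:
        raise ValueError("need at least 2 spikes for inter-spike AHP")
    if len(ev) < k_last + 1:
        warnings.warn(
            f"only {len(ev)} spikes; using {len(ev) - 1} intervals instead of {k_last}",
            stacklevel=2,
        )
    peaks = ev.times_s[-(k_last + 1) :]
    rate = v.sampling_rate_hz
    amps = []
    for t_a, t_b in zip(peaks[:-1], peaks[1:]):
        onset = spike_onset(v, t_a)
        if onset is None:
            continue
        i_a = int(round((t_a - v.start_time_s) * rate))
        i_b = int(round((t_b - v.start_time_s) * rate))
        trough = float(np.min(v.values[i_a:i_b]))
        amps.append(onset[1] - trough)
    if not amps:
        raise ValueError("no interval had a measurable spike onset")
    return float(np.mean(amps))


def rheobase(step_results: list[tuple[float, int]]) -> tuple[float | None, bool]:
    """Smallest step current eliciting >= 1 spike.

    Returns ``(current_pA, censored)``; censored means no step fired.
    """
    ordered = sorted(step_results, key=lambda r: r[0])
    for current, count in ordered:
        if count >= 1:
            return float(current), False
    return None, True


def _has_block(spike_times: np.ndarray, step_end_s: float, silent_s: float = 0.1) -> bool:
    """True when >= 2 spikes with ISIs < ``silent_s`` are followed by a
    spike-free period >= ``silent_s`` before the step end."""
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return False
    run = 1  # spikes in the current fast run
    for i in range(1, t.size):
        isi = t[i] - t[i - 1]
        if isi < silent_s:
            run += 1
        else:
            if run >= 2 and isi >= silent_s:
                return True
            run = 1
    return run >= 2 and (step_end_s - t[-1]) >= silent_s


def depolarizing_block(
    step_sweeps: list[Sweep], peak_threshold_mV: float = -10.0
) -> tuple[float | None, bool]:
    """Lowest step current producing a depolarizing block.

    Block = a >= 100 ms silent period after repetitive firing (>= 2 spikes
    with inter-spike intervals < 100 ms) within the step.  Returns
    ``(current_pA, censored)``.
    """
    annotated = []
    for sw in step_sweeps:
        i0, i1, amp = _step_window(sw.command)
        annotated.append((amp, sw, i0, i1))
    for amp, sw, i0, i1 in sorted(annotated, key=lambda r: r[0]):
        ev = detect_spikes(sw.response, peak_threshold_mV)
        rate = sw.response.sampling_rate_hz
        t_step0 = sw.response.start_time_s + i0 / rate
        t_step1 = sw.response.start_time_s + i1 / rate
        in_step = ev.times_s[(ev.times_s >= t_step0) & (ev.times_s < t_step1)]
        if _has_block(in_step, t_step1):
            return float(amp), False
    return None, True


def max_firing(step_results: list[tuple[float, np.ndarray]]) -> tuple[float, float]:
    """Highest firing rate across steps and the current that elicited it.

    Rate per step = (n_spikes - 1) / (last - first spike time); ties go to
    the lower current.
    """
    best_rate, best_current = -np.inf, None
    for current, spike_times in sorted(step_results, key=lambda r: r[0]):
        t = np.asarray(spike_times, dtype=float)
        if t.size < 2:
            continue
        r = (t.size - 1) / (t[-1] - t[0])
        if r > best_rate:
            best_rate, best_current = r, float(current)
    if best_current is None:
        raise ValueError("no step elicited >= 2 spikes")
    return float(best_rate), best_current


def input_resistance(
    vc_sweeps: list[Sweep], steady_frac: float = 0.2, min_r2: float = 0.9
) -> float:
    """Input resistance (MΩ) from a voltage-clamp step family.

    Least-squares slope of steady-state V (mV) over steady-state I (pA)
    across levels; steady state is the last ``steady_frac`` of each step.
    A poor fit (r² < ``min_r2``) warns but still returns the slope.
    """
    if len(vc_sweeps) < 3:
        raise ValueError("need at least 3 voltage levels")
    vs, is_ = [], []
    for sw in vc_sweeps:
        try:
            i0, i1, _ = _step_window(sw.command, min_delta=0.5)
        except ValueError:
            # level equal to the holding potential: steady state = sweep tail
            i0, i1 = 0, len(sw.command)
        n_ss = max(1, int(round((i1 - i0) * steady_frac)))
        vs.append(float(np.mean(sw.command.values[i1 - n_ss : i1])))
        is_.append(float(np.mean(sw.response.values[i1 - n_ss : i1])))
    vs_arr, is_arr = np.array(vs), np.array(is_)
    slope, intercept = np.polyfit(is_arr, vs_arr, 1)
    pred = slope * is_arr + intercept
    ss_res = float(np.sum((vs_arr - pred) ** 2))
    ss_tot = float(np.sum((vs_arr - vs_arr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r2:
        warnings.warn(f"non-ohmic I-V relation (r² = {r2:.3f})", stacklevel=2)
    # mV per pA = GΩ; convert to MΩ
    return float(slope) * 1e3


def holding_current_change(
    i_trace: TimeSeries,
    drug_onset_s: float,
    direction: str = "auto",
    baseline_window_s: float = 30.0,
    smooth_s: float = 1.0,
) -> float:
    """Drug-induced change in holding current (pA).

    Baseline = median over the 30 s before drug onset; the post-onset trace
    is smoothed with a 1 s rolling median and the extremum deviation taken
    (most negative for 'inward', most positive for 'outward', largest
    magnitude for 'auto').  Sign convention: inward currents are negative.
    """
    if direction not in {"inward", "outward", "auto"}:
        raise ValueError("direction must be inward|outward|auto")
    if not (i_trace.start_time_s < drug_onset_s < i_trace.end_time_s):
        raise ValueError("drug onset lies outside the recording span")
    rate = i_trace.sampling_rate_hz
    i_on = int(round((drug_onset_s - i_trace.start_time_s) * rate))
    i_base0 = max(0, i_on - int(round(baseline_window_s * rate)))
    baseline = float(np.median(i_trace.values[i_base0:i_on]))
    win = max(1, int(round(smooth_s * rate)))
    post = (
        pd.Series(i_trace.values[i_on:])
        .rolling(win, min_periods=max(1, win // 2))
        .median()
        .to_numpy()
    )
    dev = post - baseline
    if direction == "inward":
        return float(np.nanmin(dev))
    if direction == "outward":
        return float(np.nanmax(dev))
    lo, hi = float(np.nanmin(dev)), float(np.nanmax(dev))
    return lo if abs(lo) >= abs(hi) else hi


def ramp_threshold(ramp_sweep: Sweep, peak_threshold_mV: float = -10.0) -> float:
    """Voltage threshold (mV): dV/dt-criterion onset of the first spike on a
    depolarizing current ramp."""
    ev = detect_spikes(ramp_sweep.response, peak_threshold_mV)
    if len(ev) == 0:
        raise ValueError("no spike on the ramp")
    onset = spike_onset(ramp_sweep.response, float(ev.times_s[0]))
    if onset is None:
        raise ValueError("first ramp spike has no dV/dt-criterion onset")
    return onset[1]


def spontaneous_rate(
    v: TimeSeries, window: Epoch, peak_threshold_mV: float = -10.0
) -> float:
    """Spike count over window duration (Hz) on a gap-free trace."""
    ev = detect_spikes(v, peak_threshold_mV)
    n = int(np.sum(window.contains(ev.times_s)))
    return n / window.duration_s
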