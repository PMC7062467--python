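"""Per-ROI fluorescence processing: baseline, ΔF/F, bleach correction and
Ca²⁺ transient detection.

The pipeline starts from per-ROI intensity traces (nominal 5 Hz); image-stack
processing is upstream and out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_signals import TimeSeries

__all__ = [
    "RoiTrace",
    "BaselineEstimate",
    "TransientTable",
    "estimate_baseline",
    "compute_dff",
    "correct_bleach",
    "detect_transients",
]

BASELINE_WINDOW_FRAMES = 10
BASELINE_SEARCH_S = 60.0


@dataclass
class RoiTrace:
    """One ROI's raw intensity trace plus its rostro-caudal region label."""

    roi_id: str
    trace: TimeSeries
    region: str = "other"  # 'L1-3' | 'L4-6' | 'other'

    def __post_init__(self) -> None:
        if np.any(self.trace.values < 0):
            raise ValueError(f"ROI {self.roi_id}: intensities must be >= 0")


@dataclass
class BaselineEstimate:
    f0: float
    window_start_s: float
    window_len_frames: int = BASELINE_WINDOW_FRAMES

    def __post_init__(self) -> None:
        if not (self.f0 > 0):
            raise ValueError("baseline f0 must be > 0")


@dataclass
class TransientTable:
    """Detected transients for one ROI."""

    roi_id: str
    onset_s: np.ndarray
    peak_s: np.ndarray
    amplitude_dff_pct: np.ndarray

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.peak_s = np.asarray(self.peak_s, dtype=float)
        self.amplitude_dff_pct = np.asarray(self.amplitude_dff_pct, dtype=float)
        if not (self.onset_s.shape == self.peak_s.shape == self.amplitude_dff_pct.shape):
            raise ValueError("transient columns must have equal length")
        if np.any(self.peak_s < self.onset_s):
            raise ValueError("each peak must not precede its onset")
        if self.onset_s.size > 1 and np.any(np.diff(self.onset_s) < 0):
            raise ValueError("onsets must be sorted")

    def __len__(self) -> int:
        return self.onset_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_id,
                "onset_s": self.onset_s,
                "peak_s": self.peak_s,
                "amplitude_dff_pct": self.amplitude_dff_pct,
            }
        )


def estimate_baseline(trace: TimeSeries) -> BaselineEstimate:
    """Baseline fluorescence f0: the minimum mean over all 10-consecutive-frame
    windows within the first minute (automated proxy for a manually chosen
    low-activity period)."""
    rate = trace.sampling_rate_hz
    if trace.duration_s < BASELINE_SEARCH_S:
        raise ValueError("recording must be at least 60 s for baseline estimation")
    n_first = int(round(BASELINE_SEARCH_S * rate))
    first = trace.values[:n_first]
    w = BASELINE_WINDOW_FRAMES
    if first.size < w:
        raise ValueError(f"fewer than {w} frames in the first minute")
    csum = np.concatenate(([0.0], np.cumsum(first)))
    window_means = (csum[w:] - csum[:-w]) / w
    k = int(np.argmin(window_means))
    f0 = float(window_means[k])
    if f0 <= 0:
        raise ValueError("baseline f0 must be positive")
    return BaselineEstimate(f0=f0, window_start_s=trace.start_time_s + k / rate)


def compute_dff(trace: TimeSeries, baseline: BaselineEstimate) -> TimeSeries:
    """ΔF/F in percent: ``100 * (f - f0) / f0``."""
    if not (baseline.f0 > 0):
        raise ValueError("baseline f0 must be > 0")
    return trace.with_values(100.0 * (trace.values - baseline.f0) / baseline.f0, units="%dF/F")


def _decay_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def correct_bleach(
    trace: TimeSeries,
    percentile: float = 10.0,
    envelope_window_s: float = 30.0,
    min_decay_per_min: float = 0.01,
) -> TimeSeries:
    """Divide out slow photobleaching.

    A rolling low-percentile envelope of the trace is fitted with a
    mono-exponential + offset; if the fitted decay exceeds
    ``min_decay_per_min`` (fraction per minute) the trace is divided by the
    fitted curve, rescaled so the first-minute level is unchanged.  On a
    non-convergent fit the input is returned unchanged with a warning.
    """
    if trace.duration_s < BASELINE_SEARCH_S:
        raise ValueError("recording must be at least 60 s for bleach correction")
    rate = trace.sampling_rate_hz
    t = np.arange(len(trace)) / rate
    win = max(3, int(round(envelope_window_s * rate)))
    env = (
        pd.Series(trace.values)
        .rolling(win, center=True, min_periods=max(3, win // 2))
        .quantile(percentile / 100.0)
        .to_numpy()
    )
    f_start = float(np.mean(env[: max(3, win)]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _decay_model,
                t,
                env,
                p0=(0.2 * f_start, trace.duration_s / 2.0, 0.8 * f_start),
                bounds=([0.0, 1.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError):
        warnings.warn("bleach fit did not converge; trace returned unchanged", stacklevel=2)
        return trace
    a, tau, c = popt
    fit0 = _decay_model(0.0, *popt)
    fit_end = _decay_model(trace.duration_s, *popt)
    if fit0 <= 0:
        warnings.warn("degenerate bleach fit; trace returned unchanged", stacklevel=2)
        return trace
    decay_per_min = (fit0 - _decay_model(60.0, *popt)) / fit0
    if decay_per_min < min_decay_per_min:
        return trace  # stable trace: no-op
    decay = _decay_model(t, *popt)
    # renormalize so the first-minute baseline level is preserved
    i60 = int(round(BASELINE_SEARCH_S * rate))
    ref = float(np.mean(decay[:i60]))
    corrected = trace.values / decay * ref
    return trace.with_values(corrected)


def detect_transients(
    dff: TimeSeries,
    threshold_pct: float = 20.0,
    min_separation_s: float = 1.0,
) -> TransientTable:
    """Detect Ca²⁺ transients on a ΔF/F (%) trace.

    Onset = upward threshold crossing sustained for at least 2 frames;
    peak = maximum before the trace falls back below ``threshold/2``;
    events with peaks closer than ``min_separation_s`` are merged keeping
    the larger peak.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be > 0")
    y = dff.values
    rate = dff.sampling_rate_hz
    t0 = dff.start_time_s

    above = y >= threshold_pct
    events: list[tuple[int, int, float]] = []  # (onset_idx, peak_idx, peak_val)
    i = 0
    n = y.size
    while i < n:
        if above[i] and (i == 0 or not above[i - 1]):
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= 2:  # sustained >= 2 frames
                # extend to re-crossing below threshold/2 for the peak search
                k = j
                while k < n and y[k] >= threshold_pct / 2.0:
                    k += 1
                seg = y[i:k]
                p = i + int(np.argmax(seg))
                events.append((i, p, float(y[p])))
                i = k
                continue
            i = j
        else:
            i += 1

    # merge events with peaks closer than min_separation_s, keep larger peak
    merged: list[tuple[int, int, float]] = []
    for ev in events:
        if merged and (ev[1] - merged[-1][1]) / rate < min_separation_s:
            if ev[2] > merged[-1][2]:
                merged[-1] = (merged[-1][0], ev[1], ev[2])
        else:
            merged.append(ev)

    onset_s = np.array([t0 + e[0] / rate for e in merged])
    peak_s = np.array([t0 + e[1] / rate for e in merged])
    amp = np.array([e[2] for e in merged])
    return TransientTable(
        roi_id=dff.channel_id, onset_s=onset_s, peak_s=peak_s, amplitude_dff_pct=amp
    )
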