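"""Stage orchestration: the three study-level analyses.

``run_vr_study`` pools ventral-root epoch comparisons across preparations,
``run_phase_study`` turns ROI traces into per-cell phase results and
regional coupled fractions, and ``run_patch_study`` extracts per-cell
excitability/waveform features and runs the paired comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calcium, patch_clamp, phase, stats, ventral_root
from .core_signals import Epoch, EventSeries, TimeSeries
from .patch_clamp import Sweep
from .ventral_root import BurstDetectionParams, BurstTable

__all__ = [
    "analyze_vr_prep",
    "run_vr_study",
    "analyze_roi",
    "run_phase_study",
    "extract_cell_features",
    "run_patch_study",
]

VR_METRICS = ("frequency", "duration", "amplitude")


def _per_burst_series(bursts: BurstTable, raw: TimeSeries, amplitude_mode: str = "mean"):
    """Per-burst metric series keyed by burst onset time.

    Instantaneous frequency (1/inter-onset interval) is assigned to the
    later onset of each interval.
    """
    m = ventral_root.burst_metrics(bursts, raw, amplitude_mode=amplitude_mode)
    series = {
        "duration": (bursts.onset_s, bursts.duration_s),
        "amplitude": (bursts.onset_s, m["per_burst_amplitude"]),
    }
    if len(bursts) >= 2:
        series["frequency"] = (bursts.onset_s[1:], 1.0 / np.diff(bursts.onset_s))
    else:
        series["frequency"] = (np.array([]), np.array([]))
    return series, m


def analyze_vr_prep(
    raw: TimeSeries,
    epochs: list[Epoch],
    params: BurstDetectionParams | None = None,
    pre_control: Epoch | None = None,
    bin_s: float = 30.0,
    window_s: float = 300.0,
    tau_s: float = 0.05,
) -> dict:
    """Full ventral-root chain for one preparation.

    Returns bursts, summary metrics, per-metric time courses (% of the
    pre-control period, default the first epoch) and per-epoch steady-state
    means over the final ``window_s`` of each epoch.
    """
    integrated = ventral_root.rectify_integrate(raw, tau_s=tau_s)
    bursts = ventral_root.detect_bursts(integrated, params)
    series, summary = _per_burst_series(bursts, raw)
    pre = pre_control or epochs[0]

    timecourses = {}
    epoch_means = {}
    for name in VR_METRICS:
        t, v = series[name]
        if t.size:
            timecourses[name] = ventral_root.timecourse_normalize(
                t, v, pre, bin_s=bin_s, metric_name=name
            )
            epoch_means[name] = ventral_root.epoch_compare(t, v, epochs, window_s=window_s)
    return {
        "bursts": bursts,
        "summary": summary,
        "timecourses": timecourses,
        "epoch_means": epoch_means,
    }


def run_vr_study(
    preps: list[dict],
    params: BurstDetectionParams | None = None,
    window_s: float = 300.0,
    control: str = "control",
    drug: str = "drug",
) -> dict:
    """Pool epoch comparisons across preparations.

    Each prep dict needs ``raw`` (TimeSeries) and ``epochs`` (list[Epoch]).
    Returns the per-prep epoch means (long table), percent drug effects
    relative to control per prep, and one normality-gated repeated-measures
    report per metric.
    """
    rows = []
    for i, prep in enumerate(preps):
        res = analyze_vr_prep(prep["raw"], prep["epochs"], params=params, window_s=window_s)
        for name, df in res["epoch_means"].items():
            for _, r in df.iterrows():
                rows.append(
                    {
                        "prep": prep.get("id", f"prep{i:02d}"),
                        "metric": name,
                        "condition": r["epoch"],
                        "value": r["mean"],
                    }
                )
    long = pd.DataFrame(rows)

    effects = []
    reports = {}
    for name in VR_METRICS:
        sub = long[long["metric"] == name]
        if sub.empty:
            continue
        wide = sub.pivot(index="prep", columns="condition", values="value")
        if control in wide and drug in wide:
            pct = 100.0 * (wide[drug] / wide[control] - 1.0)
            for prep_id, val in pct.items():
                effects.append({"prep": prep_id, "metric": name, "effect_pct": float(val)})
        reports[name] = stats.repeated_compare(
            sub.rename(columns={"prep": "unit_id"})[["unit_id", "condition", "value"]]
        )
    return {
        "per_prep": long,
        "effects": pd.DataFrame(effects),
        "stats": reports,
    }


# ---------------------------------------------------------------------------
# phase study


def analyze_roi(
    trace: TimeSeries,
    cycles: phase.LocomotorCycles,
    roi_id: str | None = None,
    region: str = "other",
    threshold_pct: float = 20.0,
    min_separation_s: float = 1.0,
    use_peaks: bool = False,
    alpha: float = 0.05,
    bleach_correct: bool = True,
) -> tuple[phase.CellPhaseResult, calcium.TransientTable]:
    """ΔF/F conversion, transient detection and phase summary for one ROI."""
    t = calcium.correct_bleach(trace) if bleach_correct else trace
    baseline = calcium.estimate_baseline(t)
    dff = calcium.compute_dff(t, baseline)
    transients = calcium.detect_transients(
        dff, threshold_pct=threshold_pct, min_separation_s=min_separation_s
    )
    times = transients.peak_s if use_peaks else transients.onset_s
    phases, _, n_excl = phase.assign_phase(EventSeries(times), cycles)
    result = phase.summarize_cell(
        roi_id or trace.channel_id, phases, alpha=alpha, region=region, n_excluded=n_excl
    )
    return result, transients


def run_phase_study(
    roi_traces: list,
    bursts: BurstTable,
    alpha: float = 0.05,
    threshold_pct: float = 20.0,
    min_separation_s: float = 1.0,
    use_peaks: bool = False,
    bleach_correct: bool = True,
) -> dict:
    """Per-cell phase results and regional coupled fractions.

    ``roi_traces`` is a list of :class:`fictloc.calcium.RoiTrace`.
    """
    cycles = phase.define_cycles(bursts)
    results, transient_tables = [], []
    for roi in roi_traces:
        res, tr = analyze_roi(
            roi.trace,
            cycles,
            roi_id=roi.roi_id,
            region=roi.region,
            threshold_pct=threshold_pct,
            min_separation_s=min_separation_s,
            use_peaks=use_peaks,
            alpha=alpha,
            bleach_correct=bleach_correct,
        )
        results.append(res)
        transient_tables.append(tr)
    fractions = phase.coupled_fraction(results, alpha=alpha)
    return {
        "cells": results,
        "cell_table": phase.results_to_frame(results),
        "fractions": fractions,
        "transients": transient_tables,
    }


# ---------------------------------------------------------------------------
# patch study


def step_family_results(step_sweeps: list[Sweep], peak_threshold_mV: float = -10.0):
    """Per-step (current, spike times within the step) from a sweep family."""
    out = []
    for sw in step_sweeps:
        i0, i1, amp = patch_clamp._step_window(sw.command)
        rate = sw.response.sampling_rate_hz
        t0 = sw.response.start_time_s + i0 / rate
        t1 = sw.response.start_time_s + i1 / rate
        ev = patch_clamp.detect_spikes(sw.response, peak_threshold_mV)
        t = ev.times_s[(ev.times_s >= t0) & (ev.times_s < t1)]
        out.append((amp, t))
    return sorted(out, key=lambda r: r[0])


def extract_cell_features(sweeps_by_protocol: dict[str, list[Sweep]]) -> dict:
    """All per-cell measures available from the supplied protocols.

    Censored rheobase/block are reported as NaN with a companion
    ``*_censored`` flag.
    """
    feats: dict[str, float | bool] = {}
    if "step" in sweeps_by_protocol:
        steps = sweeps_by_protocol["step"]
        results = step_family_results(steps)
        counts = [(c, t.size) for c, t in results]
        rheo, rheo_cens = patch_clamp.rheobase(counts)
        feats["rheobase_pA"] = np.nan if rheo_cens else rheo
        feats["rheobase_censored"] = rheo_cens
        block, block_cens = patch_clamp.depolarizing_block(steps)
        feats["depol_block_pA"] = np.nan if block_cens else block
        feats["block_censored"] = block_cens
        try:
            rate, at = patch_clamp.max_firing(results)
            feats["max_firing_hz"] = rate
            feats["max_firing_at_pA"] = at
        except ValueError:
            feats["max_firing_hz"] = np.nan
            feats["max_firing_at_pA"] = np.nan
        # inter-spike AHP on the step with the highest firing rate
        rates = []
        for (c, t), sw in zip(results, steps):
            rates.append((t.size - 1) / (t[-1] - t[0]) if t.size >= 2 else -np.inf)
        if np.isfinite(max(rates, default=-np.inf)):
            best = steps[int(np.argmax(rates))]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                feats["interspike_ahp_mV"] = patch_clamp.interspike_ahp(best)
    if "brief_pulse" in sweeps_by_protocol:
        pulses = sweeps_by_protocol["brief_pulse"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats["mahp_mV"] = patch_clamp.mAHP_amplitude(pulses)
        widths = []
        for sw in pulses:
            fs = patch_clamp.extract_spike_features(sw.response)
            if len(fs.half_width_ms):
                widths.append(fs.half_width_ms[0])
        if widths:
            feats["half_width_ms"] = float(np.mean(widths))
    if "ramp" in sweeps_by_protocol:
        feats["ramp_threshold_mV"] = patch_clamp.ramp_threshold(
            sweeps_by_protocol["ramp"][0]
        )
    if "vc_steps" in sweeps_by_protocol:
        feats["input_resistance_MOhm"] = patch_clamp.input_resistance(
            sweeps_by_protocol["vc_steps"]
        )
    return feats


PAIRED_FEATURES = (
    "rheobase_pA",
    "depol_block_pA",
    "max_firing_hz",
    "half_width_ms",
    "interspike_ahp_mV",
    "mahp_mV",
    "ramp_threshold_mV",
    "input_resistance_MOhm",
)


def run_patch_study(
    cells: list[dict],
    condition_names: tuple[str, str] = ("control", "drug"),
) -> dict:
    """Per-cell features in two conditions plus paired comparisons.

    Each cell dict maps condition name -> ``{protocol: [Sweep]}``.
    """
    a_name, b_name = condition_names
    rows = []
    for i, cell in enumerate(cells):
        for cond in condition_names:
            feats = extract_cell_features(cell[cond])
            feats["cell"] = cell.get("id", f"cell{i:02d}")
            feats["condition"] = cond
            rows.append(feats)
    table = pd.DataFrame(rows)

    reports = {}
    diffs = []
    for feat in PAIRED_FEATURES:
        if feat not in table.columns:
            continue
        wide = table.pivot(index="cell", columns="condition", values=feat).dropna()
        if len(wide) < 3:
            continue
        reports[feat] = stats.paired_compare(
            wide[b_name].to_numpy(), wide[a_name].to_numpy()
        )
        diffs.append(
            {
                "feature": feat,
                "mean_control": float(wide[a_name].mean()),
                "mean_drug": float(wide[b_name].mean()),
                "mean_diff": float((wide[b_name] - wide[a_name]).mean()),
                "p_value": reports[feat].p_value,
                "test": reports[feat].test_name,
            }
        )
    return {"features": table, "stats": reports, "differences": pd.DataFrame(diffs)}
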