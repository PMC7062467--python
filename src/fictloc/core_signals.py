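"""Shared data model and I/O for uniformly sampled traces, events and epochs.

Conventions used throughout the package:

* time is in seconds, samples are 0-based, windows are half-open ``[start, end)``;
* canonical units are ``mV`` (voltage), ``pA`` (current) and ``a.u.``
  (fluorescence, ventral root);
* CSV traces carry metadata in leading ``# key = value`` lines and HDF5 traces
  live in one group per channel with a ``values`` dataset and
  ``sampling_rate_hz`` / ``start_time_s`` / ``units`` attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "EventSeries",
    "Epoch",
    "read_timeseries",
    "write_timeseries",
    "slice_window",
    "write_table",
]


class SignalIOError(ValueError):
    """Raised for malformed trace files (missing metadata, non-finite samples)."""


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Sample ``i`` sits at ``start_time_s + i / sampling_rate_hz``.
    """

    values: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    units: str = "a.u."
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("TimeSeries requires a 1-D vector with at least one sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.flatnonzero(~np.isfinite(self.values))
            raise ValueError(f"non-finite samples at indices {bad[:10].tolist()}")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sampling_rate_hz

    @property
    def end_time_s(self) -> float:
        """End of the half-open span covered by the trace."""
        return self.start_time_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.values.size) / self.sampling_rate_hz

    def index_at(self, t_s: float) -> int:
        """Index of the first sample at or after ``t_s``."""
        return int(np.ceil((t_s - self.start_time_s) * self.sampling_rate_hz - 1e-9))

    def with_values(self, values: np.ndarray, units: str | None = None) -> "TimeSeries":
        return TimeSeries(
            values=np.asarray(values, dtype=float),
            sampling_rate_hz=self.sampling_rate_hz,
            start_time_s=self.start_time_s,
            units=self.units if units is None else units,
            channel_id=self.channel_id,
        )


@dataclass
class EventSeries:
    """Sorted point events (spike peaks, transient onsets, burst onsets)."""

    times_s: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("times_s must be a 1-D vector")
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) < 0):
            raise ValueError("event times must be non-decreasing")
        if self.labels is not None and len(self.labels) != self.times_s.size:
            raise ValueError("labels length must match times")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class Epoch:
    """A named, half-open experimental period such as control/drug/washout."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s):
            raise ValueError(f"epoch {self.name!r}: end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float | np.ndarray):
        return (np.asarray(t) >= self.start_s) & (np.asarray(t) < self.end_s)


def check_epochs_disjoint(epochs: Sequence[Epoch]) -> None:
    ordered = sorted(epochs, key=lambda e: e.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s:
            raise ValueError(f"epochs {a.name!r} and {b.name!r} overlap")


# ---------------------------------------------------------------------------
# I/O


def _read_csv_timeseries(path: Path, channel: str | None) -> TimeSeries:
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=n_meta, float_precision="round_trip")
    if "sampling_rate_hz" not in meta:
        raise SignalIOError(f"{path}: no 'sampling_rate_hz' declared in metadata header")
    col = "value" if "value" in df.columns else df.columns[-1]
    raw = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(raw)):
        bad = np.flatnonzero(~np.isfinite(raw))
        raise SignalIOError(
            f"{path}: non-finite values in column {col!r} at data rows {bad[:10].tolist()}"
        )
    return TimeSeries(
        values=raw,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        start_time_s=float(meta.get("start_time_s", 0.0)),
        units=meta.get("units", "a.u."),
        channel_id=channel or meta.get("channel_id", ""),
    )


def _read_hdf5_timeseries(path: Path, channel: str | None) -> TimeSeries:
    with h5py.File(path, "r") as f:
        if channel is None:
            channels = [k for k in f.keys() if isinstance(f[k], h5py.Group)]
            if len(channels) != 1:
                raise SignalIOError(
                    f"{path}: channel must be given (found {channels})"
                )
            channel = channels[0]
        if channel not in f:
            raise SignalIOError(f"{path}: no channel group {channel!r}")
        grp = f[channel]
        if "sampling_rate_hz" not in grp.attrs:
            raise SignalIOError(f"{path}:{channel}: missing sampling_rate_hz attribute")
        values = np.asarray(grp["values"][...], dtype=float)
        if not np.all(np.isfinite(values)):
            bad = np.flatnonzero(~np.isfinite(values))
            raise SignalIOError(
                f"{path}:{channel}: non-finite samples at indices {bad[:10].tolist()}"
            )
        return TimeSeries(
            values=values,
            sampling_rate_hz=float(grp.attrs["sampling_rate_hz"]),
            start_time_s=float(grp.attrs.get("start_time_s", 0.0)),
            units=str(grp.attrs.get("units", "a.u.")),
            channel_id=channel,
        )


def read_timeseries(path, format: str | None = None, channel: str | None = None) -> TimeSeries:
    """Read a trace from CSV or HDF5.

    ``format`` defaults to the file suffix (``.csv`` vs ``.h5``/``.hdf5``).
    A missing declared sampling rate or any non-finite sample is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv")
    if fmt == "csv":
        return _read_csv_timeseries(path, channel)
    if fmt == "hdf5":
        return _read_hdf5_timeseries(path, channel)
    raise ValueError(f"unknown format {fmt!r}")


def write_timeseries(ts: TimeSeries, path, format: str | None = None) -> None:
    """Write a trace; inverse of :func:`read_timeseries`."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv")
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# sampling_rate_hz = {ts.sampling_rate_hz!r}\n")
            fh.write(f"# start_time_s = {ts.start_time_s!r}\n")
            fh.write(f"# units = {ts.units}\n")
            if ts.channel_id:
                fh.write(f"# channel_id = {ts.channel_id}\n")
            fh.write("value\n")
            fh.writelines(f"{float(v)!r}\n" for v in ts.values)
    elif fmt == "hdf5":
        with h5py.File(path, "a") as f:
            name = ts.channel_id or "trace"
            if name in f:
                del f[name]
            grp = f.create_group(name)
            grp.create_dataset("values", data=ts.values, track_times=False)
            grp.attrs["sampling_rate_hz"] = ts.sampling_rate_hz
            grp.attrs["start_time_s"] = ts.start_time_s
            grp.attrs["units"] = ts.units
    else:
        raise ValueError(f"unknown format {fmt!r}")


def slice_window(ts: TimeSeries, start_s: float, end_s: float) -> TimeSeries:
    """Return the samples with times in ``[start_s, end_s)``.

    Raises if the window does not overlap the recording span.
    """
    if not (end_s > start_s):
        raise ValueError("end_s must exceed start_s")
    i0 = max(0, ts.index_at(start_s))
    i1 = min(len(ts), ts.index_at(end_s))
    if i1 <= i0:
        raise ValueError(
            f"window [{start_s}, {end_s}) has no overlap with trace span "
            f"[{ts.start_time_s}, {ts.end_time_s})"
        )
    return TimeSeries(
        values=ts.values[i0:i1].copy(),
        sampling_rate_hz=ts.sampling_rate_hz,
        start_time_s=ts.start_time_s + i0 / ts.sampling_rate_hz,
        units=ts.units,
        channel_id=ts.channel_id,
    )


def write_table(rows, path) -> None:
    """Write any tabular result to CSV with a stable column order.

    Accepts a DataFrame or an iterable of mappings; floats round-trip
    losslessly (``repr`` precision).
    """
    if rows is None:
        raise ValueError("rows must not be None")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False)
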