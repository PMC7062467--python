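"""Locomotor-cycle phase mapping and circular statistics.

Transient times are mapped onto the cycle defined by successive burst onsets
(phase 0 at onset), summarized per cell by the circular mean and resultant
length, and tested for uniformity with the Rayleigh test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_signals import EventSeries
from .ventral_root import BurstTable

__all__ = [
    "LocomotorCycles",
    "CellPhaseResult",
    "define_cycles",
    "assign_phase",
    "circular_mean",
    "rayleigh_test",
    "summarize_cell",
    "coupled_fraction",
]

MIN_RAYLEIGH_N = 4


@dataclass
class LocomotorCycles:
    """Cycle boundaries: cycle i is ``[onset[i], onset[i+1])``."""

    onset_s: np.ndarray

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        if self.onset_s.size < 2:
            raise ValueError("need at least 2 burst onsets to define cycles")
        if np.any(np.diff(self.onset_s) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return self.onset_s.size - 1


@dataclass
class CellPhaseResult:
    """Per-cell circular summary and Rayleigh outcome."""

    roi_id: str
    n: int
    mean_direction_rad: float
    vector_length_r: float
    rayleigh_z: float
    p_value: float
    coupled: bool
    region: str = "other"
    underpowered: bool = False
    n_excluded: int = 0


def define_cycles(bursts: BurstTable) -> LocomotorCycles:
    """Locomotor cycles from detected burst onsets (phase 0 at each onset)."""
    if len(bursts) < 2:
        raise ValueError("need at least 2 bursts to define locomotor cycles")
    return LocomotorCycles(onset_s=bursts.onset_s.copy())


def assign_phase(events: EventSeries, cycles: LocomotorCycles) -> tuple[np.ndarray, np.ndarray, int]:
    """Map event times to phases in [0, 2π) within their own cycle.

    Returns ``(phases_rad, cycle_index, n_excluded)``; events before the
    first or at/after the last onset are excluded (counted, not fatal).
    """
    t = np.asarray(events.times_s, dtype=float)
    on = cycles.onset_s
    idx = np.searchsorted(on, t, side="right") - 1
    valid = (idx >= 0) & (idx < on.size - 1)
    n_excluded = int((~valid).sum())
    idx_v = idx[valid]
    t_v = t[valid]
    width = on[idx_v + 1] - on[idx_v]
    phases = 2.0 * np.pi * (t_v - on[idx_v]) / width
    phases = np.mod(phases, 2.0 * np.pi)
    return phases, idx_v, n_excluded


def circular_mean(phases: np.ndarray) -> tuple[float, float]:
    """Mean direction (in [0, 2π)) and resultant length r of a circular sample.

    For r = 0 the direction is undefined and NaN is returned.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    z = np.exp(1j * phases).mean()
    r = float(np.abs(z))
    if r < 1e-12:
        return float("nan"), 0.0
    direction = float(np.mod(np.angle(z), 2.0 * np.pi))
    return direction, r


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh uniformity test: ``Z = n * r**2`` with the series p-value

    ``p = exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``

    clipped to (0, 1].  For n < 4 the test is underpowered and p is set to 1.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < MIN_RAYLEIGH_N:
        return 0.0, 1.0
    _, r = circular_mean(phases)
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return float(z), p


def summarize_cell(
    roi_id: str,
    phases: np.ndarray,
    alpha: float = 0.05,
    region: str = "other",
    n_excluded: int = 0,
) -> CellPhaseResult:
    """Pool one cell's phases and apply the Rayleigh test."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        return CellPhaseResult(
            roi_id=roi_id,
            n=0,
            mean_direction_rad=float("nan"),
            vector_length_r=float("nan"),
            rayleigh_z=float("nan"),
            p_value=1.0,
            coupled=False,
            region=region,
            underpowered=True,
            n_excluded=n_excluded,
        )
    direction, r = circular_mean(phases)
    z, p = rayleigh_test(phases)
    return CellPhaseResult(
        roi_id=roi_id,
        n=n,
        mean_direction_rad=direction,
        vector_length_r=r,
        rayleigh_z=z,
        p_value=p,
        coupled=p < alpha,
        region=region,
        underpowered=n < MIN_RAYLEIGH_N,
        n_excluded=n_excluded,
    )


def coupled_fraction(
    results: list[CellPhaseResult],
    alpha: float = 0.05,
    group_by_region: bool = True,
) -> pd.DataFrame:
    """Fraction of cells with Rayleigh p < alpha, per region.

    No multiplicity correction is applied.  Regions with no cells are
    absent from the table (missing, not zero).
    """
    rows = []
    if group_by_region:
        regions = sorted({res.region for res in results})
        groups = [(reg, [r for r in results if r.region == reg]) for reg in regions]
    else:
        groups = [("all", list(results))]
    for name, grp in groups:
        if not grp:
            continue
        n_coupled = sum(1 for r in grp if r.p_value < alpha)
        rows.append(
            {
                "region": name,
                "n_cells": len(grp),
                "n_coupled": n_coupled,
                "fraction_coupled": n_coupled / len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n_cells", "n_coupled", "fraction_coupled"])


def results_to_frame(results: list[CellPhaseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in results],
            "region": [r.region for r in results],
            "n": [r.n for r in results],
            "mean_direction_rad": [r.mean_direction_rad for r in results],
            "r": [r.vector_length_r for r in results],
            "Z": [r.rayleigh_z for r in results],
            "p": [r.p_value for r in results],
            "coupled": [r.coupled for r in results],
            "n_excluded": [r.n_excluded for r in results],
        }
    )
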