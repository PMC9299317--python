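"""Single-cell fluorescence traces and peak dF/F0 extraction.

Calcium-indicator time courses enter as F/F0 samples under a step protocol:
cells are perfused at a low baseline [Ca2+]o, then switched to a test
concentration.  The response measure is the peak fractional increase
(F - F0)/F0 within a window after the solution change; per-coverslip means of
~20 cells form one dose-response point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, NormalizationError
from .hill import DoseResponsePoint

__all__ = [
    "StepProtocol",
    "FluorescenceTrace",
    "PeakMeasurement",
    "extract_peak",
    "aggregate_coverslip",
    "write_trace_csv",
    "read_trace_csv",
]

#: Default post-switch window (s) within which the peak is sought; responses
#: peak well inside the first minute after the solution change.
DEFAULT_PEAK_WINDOW_S = 55.0

#: Window (s) before the switch over which F0 normalization is checked.
BASELINE_WINDOW_S = 10.0

#: Relative tolerance on the pre-switch mean of F/F0 (must be ~1).
BASELINE_TOL = 0.05


@dataclass(frozen=True)
class StepProtocol:
    """One [Ca2+]o step: baseline -> test concentration and back."""

    baseline_conc: float  # mM
    test_conc: float  # mM
    t_switch_on: float  # s
    t_switch_off: float  # s
    sample_interval: float  # s

    def __post_init__(self) -> None:
        if not (self.t_switch_on < self.t_switch_off):
            raise DomainError("t_switch_on must precede t_switch_off")
        if not (self.sample_interval > 0):
            raise DomainError("sample_interval must be > 0")
        if self.baseline_conc <= 0 or self.test_conc <= 0:
            raise DomainError("concentrations must be > 0 mM")


@dataclass(frozen=True)
class FluorescenceTrace:
    """F/F0 time series for one cell under a defined step protocol."""

    cell_id: str
    times: np.ndarray  # s, strictly increasing
    f_over_f0: np.ndarray  # dimensionless, > 0
    protocol: StepProtocol

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f_over_f0, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "f_over_f0", f)
        if t.shape != f.shape or t.ndim != 1:
            raise DomainError("times and f_over_f0 must be 1-D of equal length")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(f <= 0):
            raise DomainError("f_over_f0 must be positive everywhere")

    def baseline_mean(self) -> float:
        """Mean F/F0 over the last BASELINE_WINDOW_S s before the switch."""
        t_on = self.protocol.t_switch_on
        mask = (self.times < t_on) & (self.times >= t_on - BASELINE_WINDOW_S)
        if not mask.any():
            mask = self.times < t_on
        if not mask.any():
            raise NormalizationError(
                f"trace {self.cell_id}: no pre-switch samples to check F0"
            )
        return float(self.f_over_f0[mask].mean())


@dataclass(frozen=True)
class PeakMeasurement:
    """Peak dF/F0 of one cell; ``clamped`` records a negative raw peak."""

    value: float
    clamped: bool = False

    def __float__(self) -> float:
        return self.value


def extract_peak(
    trace: FluorescenceTrace, window_s: float = DEFAULT_PEAK_WINDOW_S
) -> PeakMeasurement:
    """Peak (F - F0)/F0 within the post-switch window.

    The window spans ``(t_switch_on, min(t_switch_on + window_s,
    t_switch_off)]``; pre-switch samples are excluded by contract.  A negative
    raw peak (noise on a sub-threshold response, or indicator bleaching) is
    clamped to 0 and flagged, keeping the response measure in the Hill
    equation's non-negative range.

    Raises
    ------
    NormalizationError
        If the pre-switch baseline mean deviates from 1 by more than 5%.
    DomainError
        If no samples fall inside the window.
    """
    if window_s <= 0:
        raise DomainError("window_s must be > 0")
    base = trace.baseline_mean()
    if abs(base - 1.0) > BASELINE_TOL:
        raise NormalizationError(
            f"trace {trace.cell_id}: pre-switch mean F/F0 = {base:.3f} "
            f"violates normalization (tolerance {BASELINE_TOL:.0%})"
        )
    t_on = trace.protocol.t_switch_on
    t_end = min(t_on + window_s, trace.protocol.t_switch_off)
    mask = (trace.times > t_on) & (trace.times <= t_end)
    if not mask.any():
        raise DomainError(
            f"trace {trace.cell_id}: no samples in peak window "
            f"({t_on:g}, {t_end:g}] s"
        )
    raw = float(trace.f_over_f0[mask].max() - 1.0)
    if raw < 0.0:
        return PeakMeasurement(0.0, clamped=True)
    return PeakMeasurement(raw, clamped=False)


def aggregate_coverslip(
    peaks: Sequence[PeakMeasurement | float], conc: float
) -> DoseResponsePoint:
    """Collapse per-cell peaks of one coverslip into a dose-response point.

    Returns mean, SEM (sample SD / sqrt(n); 0 for a single cell) and cell
    count at the given test concentration.  Permutation invariant.
    """
    vals = np.array([float(p) for p in peaks], dtype=float)
    if vals.size == 0:
        raise DomainError("aggregate_coverslip requires at least one peak")
    n = vals.size
    sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return DoseResponsePoint(conc, float(vals.mean()), sem, int(n))


def write_trace_csv(
    traces: Iterable[FluorescenceTrace], path: str | Path, **extra_cols
) -> None:
    """Long-format trace CSV: ``cell_id, time_s, f_over_f0`` (+ extras)."""
    frames = []
    for tr in traces:
        df = pd.DataFrame(
            {"cell_id": tr.cell_id, "time_s": tr.times, "f_over_f0": tr.f_over_f0}
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for k, v in extra_cols.items():
        out[k] = v
    out.to_csv(path, index=False)


def read_trace_csv(
    path: str | Path, protocol: StepProtocol
) -> list[FluorescenceTrace]:
    """Read a long-format trace CSV; the protocol arrives as sidecar config."""
    df = pd.read_csv(path)
    required = {"cell_id", "time_s", "f_over_f0"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"trace CSV missing columns {sorted(missing)}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            FluorescenceTrace(
                str(cid),
                grp["time_s"].to_numpy(float),
                grp["f_over_f0"].to_numpy(float),
                protocol,
            )
        )
    return out
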