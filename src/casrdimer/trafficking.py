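"""Membrane-expression quantification from fluorescence line profiles.

Cell-surface expression of a tagged receptor is read from a 1-D intensity
profile drawn across the cell: membrane-localized receptor produces sharp
peaks where the line crosses the plasma membrane, retained receptor a
cytoplasmic plateau.  The profile's baseline-subtracted peak is the
membrane-expression measure; per-condition means relative to a full-dose WT
control are compared against the random-association model's predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dimer import ConstructMix, membrane_tag_fraction
from .errors import DomainError

__all__ = [
    "LineProfile",
    "MembraneExpression",
    "FractionEstimate",
    "TraffickingComparison",
    "profile_peak",
    "membrane_fraction",
    "summarize_expression",
    "compare_to_model",
]

MIN_PROFILE_SAMPLES = 16

#: Fraction of samples at each profile end treated as off-cell background.
BASELINE_EDGE_FRACTION = 0.10


@dataclass(frozen=True)
class LineProfile:
    """Fluorescence intensities sampled along a line across one cell."""

    cell_id: str
    positions: np.ndarray  # um, strictly increasing
    intensities: np.ndarray  # a.u., >= 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise DomainError("positions and intensities must match in shape")
        if pos.size < MIN_PROFILE_SAMPLES:
            raise DomainError(
                f"profile needs >= {MIN_PROFILE_SAMPLES} samples, got {pos.size}"
            )
        if np.any(np.diff(pos) <= 0):
            raise DomainError("positions must be strictly increasing")
        if np.any(inten < 0):
            raise DomainError("intensities must be >= 0")


def profile_peak(profile: LineProfile) -> float:
    """Baseline-subtracted peak intensity of a line profile (a.u.).

    The off-cell baseline is the mean of the outermost 10% of samples at each
    end of the line; the peak is the profile maximum above that baseline,
    clamped at 0.  Invariant to reversing the profile direction.
    """
    n = profile.intensities.size
    k = max(1, int(round(BASELINE_EDGE_FRACTION * n)))
    baseline = float(
        np.concatenate([profile.intensities[:k], profile.intensities[-k:]]).mean()
    )
    return max(0.0, float(profile.intensities.max() - baseline))


@dataclass(frozen=True)
class MembraneExpression:
    """Per-condition summary of membrane peak fluorescence."""

    condition_label: str
    mean_peak: float  # a.u.
    sem: float  # a.u.
    n_cells: int
    n_coverslips: int
    relative_to_control: float = float("nan")
    relative_sem: float | None = None

    def __post_init__(self) -> None:
        if self.n_coverslips < 1:
            raise DomainError("n_coverslips must be >= 1")
        if not math.isnan(self.relative_to_control) and self.relative_to_control < 0:
            raise DomainError("relative_to_control must be >= 0")


@dataclass(frozen=True)
class FractionEstimate:
    """A membrane fraction with its delta-method standard error."""

    value: float
    sem: float

    def __float__(self) -> float:
        return self.value


def summarize_expression(
    condition_label: str,
    peaks_by_coverslip: Sequence[Sequence[float]],
) -> MembraneExpression:
    """Aggregate per-cell profile peaks into a condition summary.

    The coverslip is the replicate unit: cell peaks are averaged within each
    coverslip, and the reported mean/SEM are across coverslip means.
    """
    means = []
    n_cells = 0
    for peaks in peaks_by_coverslip:
        arr = np.asarray(list(peaks), dtype=float)
        if arr.size == 0:
            raise DomainError("each coverslip needs at least one cell peak")
        means.append(float(arr.mean()))
        n_cells += arr.size
    m = np.asarray(means)
    sem = float(np.std(m, ddof=1) / math.sqrt(m.size)) if m.size > 1 else 0.0
    return MembraneExpression(
        condition_label, float(m.mean()), sem, int(n_cells), int(m.size)
    )


def membrane_fraction(
    sample: MembraneExpression, control: MembraneExpression
) -> FractionEstimate:
    """Membrane expression of ``sample`` relative to ``control``.

    SEM via the first-order (delta-method) ratio formula
    ``f * sqrt((sem_s/mean_s)^2 + (sem_c/mean_c)^2)``; for a zero sample mean
    the SEM reduces to ``sem_s / mean_c``.  Scale-invariant: multiplying all
    intensities by a constant leaves the fraction unchanged.
    """
    if control.mean_peak <= 0:
        raise DomainError("control mean peak must be > 0")
    f = sample.mean_peak / control.mean_peak
    if sample.mean_peak > 0:
        rel = math.hypot(
            sample.sem / sample.mean_peak, control.sem / control.mean_peak
        )
        sem = f * rel
    else:
        sem = sample.sem / control.mean_peak
    return FractionEstimate(f, sem)


def with_fraction(
    sample: MembraneExpression, control: MembraneExpression
) -> MembraneExpression:
    """Copy of ``sample`` with the relative-to-control fields filled in."""
    est = membrane_fraction(sample, control)
    return MembraneExpression(
        sample.condition_label,
        sample.mean_peak,
        sample.sem,
        sample.n_cells,
        sample.n_coverslips,
        relative_to_control=est.value,
        relative_sem=est.sem,
    )


@dataclass(frozen=True)
class TraffickingComparison:
    """Observed membrane fraction against the random-association prediction."""

    condition_label: str
    observed_fraction: float
    observed_sem: float | None
    predicted_fraction: float
    deviation: float
    consistent: bool

    def to_dict(self) -> dict:
        return {
            "condition": self.condition_label,
            "observed_fraction": self.observed_fraction,
            "observed_sem": self.observed_sem,
            "predicted_fraction": self.predicted_fraction,
            "deviation": self.deviation,
            "consistent_within_2_sem": self.consistent,
        }


def compare_to_model(
    observed: MembraneExpression,
    mix: ConstructMix,
    control_mix: ConstructMix,
    tag: str = "EGFP",
) -> TraffickingComparison:
    """Compare a measured membrane fraction with the dimer-model prediction.

    ``observed.relative_to_control`` must be populated (see
    :func:`with_fraction`).  Consistency means the observed fraction lies
    within 2 propagated SEMs of the prediction; with no SEM available the
    flag is based on a 2-percentage-point margin.  A measurable fraction
    where the model predicts zero (mutant alone) is flagged inconsistent --
    the residual signal is optical background from out-of-focus cytoplasmic
    fluorescence, not membrane trafficking.
    """
    f_obs = observed.relative_to_control
    if math.isnan(f_obs):
        raise DomainError(
            "observed.relative_to_control is not set; compute it with "
            "with_fraction() against the control condition"
        )
    predicted = membrane_tag_fraction(mix, tag, control_mix)
    deviation = abs(f_obs - predicted)
    margin = (
        2.0 * observed.relative_sem
        if observed.relative_sem is not None
        else 0.02
    )
    return TraffickingComparison(
        condition_label=observed.condition_label,
        observed_fraction=f_obs,
        observed_sem=observed.relative_sem,
        predicted_fraction=predicted,
        deviation=deviation,
        consistent=deviation <= margin,
    )


# ---------------------------------------------------------------------------
# CSV dialects


def write_profile_csv(
    profiles: Iterable[LineProfile], path: str | Path, **extra_cols
) -> None:
    """Line-profile CSV: ``cell_id, position_um, intensity`` (+ extras)."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": p.cell_id,
                "position_um": p.positions,
                "intensity": p.intensities,
            }
        )
        for p in profiles
    ]
    out = pd.concat(frames, ignore_index=True)
    for k, v in extra_cols.items():
        out[k] = v
    out.to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> list[LineProfile]:
    df = pd.read_csv(path)
    required = {"cell_id", "position_um", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"profile CSV missing columns {sorted(missing)}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("position_um")
        out.append(
            LineProfile(
                str(cid),
                grp["position_um"].to_numpy(float),
                grp["intensity"].to_numpy(float),
            )
        )
    return out


def write_expression_csv(
    rows: Sequence[MembraneExpression],
    path: str | Path,
    predictions: Mapping[str, float] | None = None,
) -> None:
    """Expression summary CSV in the pipeline's standard shape."""
    predictions = predictions or {}
    pd.DataFrame(
        [
            {
                "condition": e.condition_label,
                "mean_peak": e.mean_peak,
                "sem": e.sem,
                "n_cells": e.n_cells,
                "n_coverslips": e.n_coverslips,
                "relative_to_control": e.relative_to_control,
                "predicted_fraction": predictions.get(e.condition_label),
            }
            for e in rows
        ]
    ).to_csv(path, index=False)
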