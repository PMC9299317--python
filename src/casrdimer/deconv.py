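"""Curve-subtraction deconvolution of mixed receptor populations.

A cell population co-expressing WT and mutant receptor signals through a
mixture of dimer species.  Because the mutant homodimer is silent and the
membrane composition is known from the random-association model, component
concentration-response relationships can be isolated by pointwise
subtraction of dose-response tables acquired on the same concentration grid:

* untransfected background is removed by subtracting the untransfected
  table from a transfected one;
* the heterodimer component is the equimolar-mix table minus the table of a
  WT-only transfection at the mix's WT dose share (the quarter-dose
  reference), since the mix's WT homodimers are exactly as many as in that
  reference.

The subtracted points are refit with the Hill equation, and scaled-curve
comparisons check the linear-expression prediction (e.g. a full-dose WT
curve scaled by 0.25 should match the quarter-dose fit).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlignmentError, DegenerateFitError
from .hill import (
    DoseResponsePoint,
    DoseResponseTable,
    HillFit,
    HillParams,
    eval_hill,
    fit_hill,
    fit_report,
    scale_hill_curve,
)

__all__ = [
    "SubtractionResult",
    "ScaledComparison",
    "subtract_background",
    "isolate_heterodimer",
    "compare_scaled",
]

#: Relative tolerance for declaring two concentration grids identical.
GRID_RTOL = 1e-6


def _check_grids(a: DoseResponseTable, b: DoseResponseTable) -> np.ndarray:
    """Validate strictly-increasing identical grids; return the common grid."""
    for t in (a, b):
        if not t.is_strict_grid:
            raise AlignmentError(
                f"table {t.label!r} has replicate concentrations; aggregate "
                "coverslips before subtraction"
            )
    ca, cb = a.conc, b.conc
    if len(ca) != len(cb) or not np.allclose(ca, cb, rtol=GRID_RTOL, atol=0.0):
        raise AlignmentError(
            f"concentration grids of {a.label!r} and {b.label!r} differ; "
            "no silent interpolation is performed"
        )
    return ca


def subtract_background(
    transfected: DoseResponseTable, untransfected: DoseResponseTable
) -> DoseResponseTable:
    """Pointwise difference removing the endogenous (untransfected) response.

    SEMs combine in quadrature; cell counts are kept from the transfected
    table.  Grids must match within 1e-6 relative (no interpolation).
    """
    grid = _check_grids(transfected, untransfected)
    pts = []
    for c, pt, pu in zip(grid, transfected.points, untransfected.points):
        pts.append(
            DoseResponsePoint(
                float(c),
                pt.response - pu.response,
                math.hypot(pt.sem, pu.sem),
                pt.n_cells,
            )
        )
    return DoseResponseTable(f"{transfected.label}-bg", tuple(pts))


@dataclass
class SubtractionResult:
    """Isolated component table, its Hill fit, and the scaled reference."""

    component_label: str
    points: DoseResponseTable
    fit: HillFit | None
    reference_fit: HillParams | None
    scale_factor: float
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        ref = self.reference_fit
        return {
            "component_label": self.component_label,
            "points": [
                {
                    "conc_mM": p.conc,
                    "response": p.response,
                    "sem": p.sem,
                    "n_cells": p.n_cells,
                }
                for p in self.points.points
            ],
            "fit": None if self.fit is None else fit_report(self.fit),
            "reference_fit": None
            if ref is None
            else {"f_max": ref.f_max, "ec50_mM": ref.ec50, "hill_n": ref.hill_n},
            "scale_factor": self.scale_factor,
            "degenerate": self.degenerate,
            "warnings": list(self.warnings),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def isolate_heterodimer(
    mix_table: DoseResponseTable,
    homodimer_ref_table: DoseResponseTable,
    full_wt_fit: HillParams | None = None,
    scale_factor: float = 0.5,
    neg_tol_sems: float = 1.0,
) -> SubtractionResult:
    """Isolate the heterodimer concentration-response by subtraction.

    ``homodimer_ref_table`` must come from a WT-only transfection at the WT
    dose share of the mix (for an equimolar mix, the quarter-dose WT
    condition: the mix assembles p^2 = 1/4 as many WT homodimers as a
    full-dose WT transfection).  The difference is attributed to heterodimers
    and refit with the Hill equation.

    Parameters
    ----------
    full_wt_fit:
        Optional full-dose WT parameters; when given they are scaled by
        ``scale_factor`` (the heterodimer membrane fraction from the dimer
        model, 0.5 for an equimolar mix) and stored as the equal-efficacy
        reference curve.
    neg_tol_sems:
        Differences more negative than this many combined SEMs count toward
        the model-inconsistency warning, raised when more than two
        concentrations are affected.
    """
    if not (0.0 < scale_factor <= 1.0):
        raise AlignmentError("scale_factor must lie in (0, 1]")
    diff = subtract_background(mix_table, homodimer_ref_table)
    diff = DoseResponseTable(f"{mix_table.label}-het", diff.points)

    warnings: list[str] = []
    neg = [
        p for p in diff.points
        if p.response < -neg_tol_sems * max(p.sem, 1e-12)
    ]
    if len(neg) > 2:
        warnings.append(
            f"{len(neg)} concentrations show differences below "
            f"-{neg_tol_sems:g} combined SEM; mixture model may be "
            "inconsistent with the data"
        )

    fit: HillFit | None = None
    degenerate = False
    try:
        fit = fit_hill(diff)
    except DegenerateFitError:
        degenerate = True
        warnings.append("difference table is flat; no heterodimer signal")

    reference = (
        None if full_wt_fit is None else scale_hill_curve(full_wt_fit, scale_factor)
    )
    return SubtractionResult(
        component_label=diff.label,
        points=diff,
        fit=fit,
        reference_fit=reference,
        scale_factor=scale_factor,
        degenerate=degenerate,
        warnings=warnings,
    )


@dataclass(frozen=True)
class ScaledComparison:
    """Discrepancy between a scaled full-dose curve and a target fit."""

    max_abs_diff: float
    rms_diff: float
    ec50_ratio: float  # target / full
    scale: float

    def to_dict(self) -> dict:
        return {
            "max_abs_diff": self.max_abs_diff,
            "rms_diff": self.rms_diff,
            "ec50_ratio": self.ec50_ratio,
            "scale": self.scale,
        }


def compare_scaled(
    full_fit: HillParams,
    target_fit: HillParams,
    scale: float,
    grid=None,
) -> ScaledComparison:
    """Compare ``scale * full curve`` against a target fit on a grid.

    Used both for the linear-expression check (full-dose WT scaled by 0.25
    vs the quarter-dose fit: curves nearly indistinguishable) and for the
    efficacy/affinity comparison of the heterodimer (full WT scaled by 0.5:
    similar maximum, right-shifted EC50).
    """
    if not (0.0 < scale <= 1.0):
        raise AlignmentError("scale must lie in (0, 1]")
    from .hill import DEFAULT_GRID

    g = np.asarray(DEFAULT_GRID if grid is None else grid, dtype=float)
    if g.size == 0:
        raise AlignmentError("comparison grid must be non-empty")
    scaled = scale_hill_curve(full_fit, scale)
    d = eval_hill(scaled, g) - eval_hill(target_fit, g)
    return ScaledComparison(
        max_abs_diff=float(np.max(np.abs(d))),
        rms_diff=float(np.sqrt(np.mean(d * d))),
        ec50_ratio=target_fit.ec50 / full_fit.ec50,
        scale=scale,
    )
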