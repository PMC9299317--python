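"""Hill concentration-effect model: evaluation, fitting and curve scaling.

The single quantitative transduction model used throughout this package is the
Hill equation

    (F - F0)/F0 = F_max / (1 + (EC50 / [Ca2+]o)^n)

with ``F_max`` the maximal fractional fluorescence increase (efficacy
surrogate), ``EC50`` the extracellular calcium concentration (mM) producing a
half-maximal response (affinity surrogate) and ``n`` the Hill coefficient
(steepness/cooperativity).  Fitting is unweighted nonlinear least squares on
per-coverslip mean peak responses, with standard errors taken from the
Gauss-Newton approximation to the curvature of the objective at the optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    ConvergenceError,
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
)

__all__ = [
    "HillParams",
    "DoseResponsePoint",
    "DoseResponseTable",
    "HillFit",
    "eval_hill",
    "fit_hill",
    "scale_hill_curve",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "fit_report",
]

#: Default test-concentration grid, mM.  The experimental design spans
#: 0.5-50 mM extracellular calcium; eight roughly log-spaced steps cover the
#: sigmoid for every receptor combination studied.
DEFAULT_GRID: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 5.0, 10.0, 20.0, 50.0)

# Responses whose total range falls below this (dimensionless dF/F0) carry no
# usable concentration dependence; attempting a sigmoid fit on them only
# returns noise-chasing parameters with enormous standard errors.
DEGENERATE_RANGE_TOL = 0.02

_BOUNDS_LO = (1e-9, 1e-9, 1e-9)
_BOUNDS_HI = (10.0, 1e3, 10.0)


@dataclass(frozen=True)
class HillParams:
    """Parameter triple of the Hill equation, with optional standard errors.

    Parameters
    ----------
    f_max:
        Maximal (F-F0)/F0, dimensionless, >= 0.
    ec50:
        Half-maximally activating [Ca2+]o, mM, > 0.
    hill_n:
        Hill coefficient, dimensionless, > 0.
    se_f_max, se_ec50, se_hill_n:
        Standard errors of the estimates.  Either all three are given or none.
    """

    f_max: float
    ec50: float
    hill_n: float
    se_f_max: float | None = None
    se_ec50: float | None = None
    se_hill_n: float | None = None

    def __post_init__(self) -> None:
        if not (self.f_max >= 0):
            raise DomainError(f"f_max must be >= 0, got {self.f_max}")
        if not (self.ec50 > 0):
            raise DomainError(f"ec50 must be > 0, got {self.ec50}")
        if not (self.hill_n > 0):
            raise DomainError(f"hill_n must be > 0, got {self.hill_n}")
        ses = (self.se_f_max, self.se_ec50, self.se_hill_n)
        if any(s is not None for s in ses):
            if any(s is None for s in ses):
                raise DomainError(
                    "either all three standard errors are present or none"
                )
            if any(s < 0 for s in ses):  # type: ignore[operator]
                raise DomainError("standard errors must be >= 0")

    @property
    def has_se(self) -> bool:
        return self.se_f_max is not None

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_max, self.ec50, self.hill_n)

    def unit_efficacy(self) -> "HillParams":
        """Same curve shape rescaled to F_max = 1 (standard errors dropped)."""
        return HillParams(1.0, self.ec50, self.hill_n)


@dataclass(frozen=True)
class DoseResponsePoint:
    """Mean peak (F-F0)/F0 of one coverslip at one test [Ca2+]o."""

    conc: float  # mM
    response: float  # dimensionless mean peak dF/F0
    sem: float = 0.0
    n_cells: int = 1

    def __post_init__(self) -> None:
        if not (self.conc > 0):
            raise DomainError(f"conc must be > 0, got {self.conc}")
        if self.n_cells < 1:
            raise DomainError("n_cells must be >= 1")
        if self.sem < 0:
            raise DomainError("sem must be >= 0")


@dataclass(frozen=True)
class DoseResponseTable:
    """Ordered per-coverslip dose-response points for one condition.

    Points are stored sorted by concentration.  Replicate coverslips at the
    same concentration are allowed (the replication design uses three
    coverslips per concentration); operations that require a strictly
    increasing grid (the subtraction procedures) call :meth:`aggregate` first
    or validate via :attr:`is_strict_grid`.
    """

    label: str
    points: tuple[DoseResponsePoint, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise DomainError("DoseResponseTable requires at least one point")
        ordered = tuple(sorted(self.points, key=lambda p: p.conc))
        object.__setattr__(self, "points", ordered)

    @property
    def conc(self) -> np.ndarray:
        return np.array([p.conc for p in self.points], dtype=float)

    @property
    def response(self) -> np.ndarray:
        return np.array([p.response for p in self.points], dtype=float)

    @property
    def sem(self) -> np.ndarray:
        return np.array([p.sem for p in self.points], dtype=float)

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([p.n_cells for p in self.points], dtype=int)

    @property
    def n_distinct_conc(self) -> int:
        return len(np.unique(self.conc))

    @property
    def is_strict_grid(self) -> bool:
        return bool(np.all(np.diff(self.conc) > 0))

    def aggregate(self) -> "DoseResponseTable":
        """Average replicate coverslips, yielding a strictly increasing grid.

        The mean of coverslip means is taken per concentration; the SEM is the
        between-coverslip SEM (SD of coverslip means / sqrt(replicates)) when
        more than one replicate exists, else the single coverslip's SEM.
        """
        out: list[DoseResponsePoint] = []
        for c in np.unique(self.conc):
            pts = [p for p in self.points if p.conc == c]
            vals = np.array([p.response for p in pts])
            n_cells = int(sum(p.n_cells for p in pts))
            if len(pts) > 1:
                sem = float(np.std(vals, ddof=1) / math.sqrt(len(pts)))
            else:
                sem = pts[0].sem
            out.append(
                DoseResponsePoint(float(c), float(vals.mean()), sem, n_cells)
            )
        return DoseResponseTable(self.label, tuple(out))


def eval_hill(params: HillParams, conc):
    """Evaluate the Hill response at one or many concentrations (mM).

    Strictly increasing in ``conc``, bounded by ``[0, f_max)``; exactly
    ``f_max / 2`` at ``conc == ec50``.

    Raises
    ------
    DomainError
        If any concentration is non-positive.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c <= 0):
        raise DomainError("concentration must be > 0 mM")
    out = params.f_max / (1.0 + (params.ec50 / c) ** params.hill_n)
    if np.isscalar(conc) or c.ndim == 0:
        return float(out)
    return out


def scale_hill_curve(params: HillParams, factor: float) -> HillParams:
    """Scale the curve's efficacy: ``f_max`` (and its SE) times ``factor``.

    ``ec50`` and ``hill_n`` are unchanged -- this is the linear-expression
    operation used to overlay a full-dose curve on a fractional-dose dataset.
    """
    if not (factor > 0):
        raise DomainError(f"scale factor must be > 0, got {factor}")
    se = None if params.se_f_max is None else params.se_f_max * factor
    return replace(params, f_max=params.f_max * factor, se_f_max=se)


@dataclass(frozen=True)
class HillFit:
    """Result of :func:`fit_hill`: estimates plus fit diagnostics."""

    label: str
    params: HillParams
    rss: float
    n_points: int
    converged: bool
    weighted: bool = False

    @property
    def f_max(self) -> float:
        return self.params.f_max

    @property
    def ec50(self) -> float:
        return self.params.ec50

    @property
    def hill_n(self) -> float:
        return self.params.hill_n


def _initial_guess(conc: np.ndarray, resp: np.ndarray) -> np.ndarray:
    """Heuristic start: f_max from the top, EC50 from half-max crossing, n=2."""
    f0 = float(resp.max())
    half = f0 / 2.0
    # first crossing of the half-max level, linearly interpolated in conc
    ec = None
    for i in range(len(resp) - 1):
        lo, hi = resp[i], resp[i + 1]
        if (lo - half) * (hi - half) <= 0 and lo != hi:
            w = (half - lo) / (hi - lo)
            ec = conc[i] + w * (conc[i + 1] - conc[i])
            break
    if ec is None or ec <= 0:
        ec = float(np.median(conc))
    return np.array([max(f0, 1e-3), float(ec), 2.0])


def fit_hill(
    table: DoseResponseTable,
    weights: str = "none",
    degenerate_tol: float = DEGENERATE_RANGE_TOL,
) -> HillFit:
    """Fit the Hill equation to a dose-response table by least squares.

    Parameters
    ----------
    table:
        Per-coverslip (or aggregated) dose-response points; at least four
        distinct concentrations are required.
    weights:
        ``"none"`` (default; unweighted, matching fitting on per-coverslip
        means) or ``"inverse_sem2"`` for 1/sem^2 weighting (points with zero
        SEM receive the smallest positive SEM in the table).
    degenerate_tol:
        Response range below which the table is declared concentration-
        independent and a :class:`DegenerateFitError` is raised.

    Returns
    -------
    HillFit
        Estimates with Gauss-Newton standard errors, residual sum of squares,
        and a convergence flag.  Non-convergence after deterministic
        multi-start restarts is flagged, never silent.

    Raises
    ------
    InsufficientDataError, DegenerateFitError, DomainError
    """
    if weights not in ("none", "inverse_sem2"):
        raise DomainError(f"unknown weights policy {weights!r}")
    conc = table.conc
    resp = table.response
    if table.n_distinct_conc < 4:
        raise InsufficientDataError(
            f"{table.label!r}: need >= 4 distinct concentrations, "
            f"got {table.n_distinct_conc}"
        )
    if float(np.ptp(resp)) < degenerate_tol or float(resp.max()) <= 0:
        raise DegenerateFitError(
            f"{table.label!r}: responses are flat (range "
            f"{float(np.ptp(resp)):.4g} < {degenerate_tol}); no concentration "
            "dependence to fit"
        )

    if weights == "inverse_sem2":
        sem = table.sem.copy()
        positive = sem[sem > 0]
        fill = positive.min() if positive.size else 1.0
        sem[sem <= 0] = fill
        w = 1.0 / sem
    else:
        w = np.ones_like(resp)

    def residuals(theta: np.ndarray) -> np.ndarray:
        f, e, n = theta
        return w * (f / (1.0 + (e / conc) ** n) - resp)

    x0 = _initial_guess(conc, resp)
    # deterministic multi-start: the heuristic start plus three perturbations
    starts = [
        x0,
        x0 * np.array([1.0, 0.5, 0.75]),
        x0 * np.array([1.2, 2.0, 1.5]),
        np.array([max(resp.max(), 1e-3), float(np.median(conc)), 1.0]),
    ]
    best = None
    for s in starts:
        s = np.clip(s, _BOUNDS_LO, _BOUNDS_HI)
        try:
            sol = least_squares(
                residuals, s, bounds=(_BOUNDS_LO, _BOUNDS_HI), xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=5000,
            )
        except Exception:  # numerical failure from a bad start
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    converged = best is not None
    if not converged:
        # flagged result: report the heuristic start with infinite RSS rather
        # than failing silently; callers decide whether to tolerate it
        params = HillParams(*np.clip(x0, _BOUNDS_LO, _BOUNDS_HI))
        return HillFit(table.label, params, float("inf"), len(resp), False,
                       weighted=(weights != "none"))

    theta = best.x
    m, k = len(resp), 3
    rss = float(np.sum((eval_hill(HillParams(*theta), conc) - resp) ** 2))
    # Gauss-Newton covariance: s^2 * (J'J)^-1 with s^2 from weighted residuals
    J = best.jac
    dof = max(m - k, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    params = HillParams(
        float(theta[0]), float(theta[1]), float(theta[2]),
        float(se[0]), float(se[1]), float(se[2]),
    )
    return HillFit(table.label, params, rss, m, True,
                   weighted=(weights != "none"))


def fit_hill_or_raise(table: DoseResponseTable, **kw) -> HillFit:
    """Like :func:`fit_hill` but promotes a non-converged flag to an error."""
    fit = fit_hill(table, **kw)
    if not fit.converged:
        raise ConvergenceError(f"fit for {table.label!r} did not converge")
    return fit


# ---------------------------------------------------------------------------
# CSV / JSON dialects


def write_dose_response_csv(
    tables: Iterable[DoseResponseTable], path: str | Path
) -> None:
    """Write tables as long CSV: ``label, conc_mM, response, sem, n_cells``."""
    rows = [
        {
            "label": t.label,
            "conc_mM": p.conc,
            "response": p.response,
            "sem": p.sem,
            "n_cells": p.n_cells,
        }
        for t in tables
        for p in t.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dose_response_csv(path: str | Path) -> dict[str, DoseResponseTable]:
    """Read the long CSV dialect back into per-condition tables."""
    df = pd.read_csv(path)
    required = {"label", "conc_mM", "response", "sem", "n_cells"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"dose-response CSV missing columns {sorted(missing)}")
    out: dict[str, DoseResponseTable] = {}
    for label, grp in df.groupby("label", sort=False):
        pts = tuple(
            DoseResponsePoint(
                float(r.conc_mM), float(r.response), float(r.sem), int(r.n_cells)
            )
            for r in grp.itertuples()
        )
        out[str(label)] = DoseResponseTable(str(label), pts)
    return out


def fit_report(fit: HillFit) -> dict:
    """JSON-ready fit report in the package's standard shape."""
    p = fit.params
    return {
        "label": fit.label,
        "f_max": p.f_max,
        "se_f_max": p.se_f_max,
        "ec50_mM": p.ec50,
        "se_ec50": p.se_ec50,
        "hill_n": p.hill_n,
        "se_hill_n": p.se_hill_n,
        "rss": fit.rss,
        "n_points": fit.n_points,
        "converged": fit.converged,
    }


def write_fit_reports(fits: Sequence[HillFit], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([fit_report(f) for f in fits], indent=2) + "\n"
    )
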