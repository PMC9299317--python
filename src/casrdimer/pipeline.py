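"""End-to-end workflow: simulate -> process -> fit -> deconvolve -> compare.

The default configuration reproduces the full study design on synthetic
data: six transfection conditions on the standard concentration grid, raw
Hill fits per condition, background subtraction against the untransfected
condition, heterodimer isolation by curve subtraction, scaled-curve
equivalence checks, a trafficking experiment with line profiles, and a
machine-readable report with the headline ratios (heterodimer/WT EC50 and
mixture/WT maximal response).
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .deconv import compare_scaled, isolate_heterodimer, subtract_background
from .dimer import ConstructMix
from .errors import CasrDimerError, ConfigError, ConvergenceError
from .hill import (
    DEFAULT_GRID,
    HillFit,
    fit_hill,
    fit_report,
    write_dose_response_csv,
)
from .synth import GeneratorConfig, generate_experiment, generate_line_profiles
from .trafficking import (
    compare_to_model,
    profile_peak,
    summarize_expression,
    with_fraction,
    write_expression_csv,
)

__all__ = ["default_config", "load_config", "run_pipeline", "summarize_headline"]

SCHEMA_VERSION = 1

_VALID_TAGS = ("EGFP", "myc", "none")


def default_config() -> dict:
    """Packaged all-synthetic configuration covering every pipeline stage."""
    return {
        "seed": 0,
        "grid": list(DEFAULT_GRID),
        "generator": {
            "noise_sd": 0.03,
            "cell_cv": 0.15,
            "cells_per_coverslip": 20,
            "coverslips_per_conc": 3,
            "wt_component": "wt_full_corrected",
            "het_component": "heterodimer",
        },
        "conditions": [
            {"label": "wt_full", "wt_dose_pM": 250.0, "mut_dose_pM": 0.0,
             "wt_tag": "EGFP", "mut_tag": "none"},
            {"label": "wt_myc_full", "wt_dose_pM": 250.0, "mut_dose_pM": 0.0,
             "wt_tag": "myc", "mut_tag": "none"},
            {"label": "wt_mut_mix", "wt_dose_pM": 125.0, "mut_dose_pM": 125.0,
             "wt_tag": "EGFP", "mut_tag": "myc"},
            {"label": "mut_full", "wt_dose_pM": 0.0, "mut_dose_pM": 250.0,
             "wt_tag": "none", "mut_tag": "EGFP"},
            {"label": "wt_quarter", "wt_dose_pM": 62.5, "mut_dose_pM": 0.0,
             "wt_tag": "EGFP", "mut_tag": "none"},
            {"label": "untransfected", "wt_dose_pM": 0.0, "mut_dose_pM": 250.0,
             "wt_tag": "none", "mut_tag": "none"},
        ],
        "deconvolution": {
            "mix": "wt_mut_mix",
            "reference": "wt_quarter",
            "wt_full": "wt_full",
            "background": "untransfected",
            "het_membrane_fraction": 0.5,
            "quarter_scale": 0.25,
        },
        "trafficking": {
            "control": {"label": "traffic_control", "wt_dose_pM": 250.0,
                        "mut_dose_pM": 0.0, "wt_tag": "EGFP", "mut_tag": "none"},
            "conditions": [
                {"label": "traffic_wt_egfp_mut_myc", "wt_dose_pM": 125.0,
                 "mut_dose_pM": 125.0, "wt_tag": "EGFP", "mut_tag": "myc"},
                {"label": "traffic_mut_egfp_wt_myc", "wt_dose_pM": 125.0,
                 "mut_dose_pM": 125.0, "wt_tag": "myc", "mut_tag": "EGFP"},
                {"label": "traffic_mut_alone", "wt_dose_pM": 0.0,
                 "mut_dose_pM": 250.0, "wt_tag": "none", "mut_tag": "EGFP"},
            ],
        },
    }


def _require(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ConfigError(field, msg)


def _mix_from_entry(entry: Mapping[str, Any], field: str) -> ConstructMix:
    for key in ("label", "wt_dose_pM", "mut_dose_pM"):
        _require(key in entry, f"{field}.{key}", "missing required key")
    wt_tag = entry.get("wt_tag", "none")
    mut_tag = entry.get("mut_tag", "none")
    _require(wt_tag in _VALID_TAGS, f"{field}.wt_tag", f"must be one of {_VALID_TAGS}")
    _require(mut_tag in _VALID_TAGS, f"{field}.mut_tag", f"must be one of {_VALID_TAGS}")
    try:
        return ConstructMix(
            float(entry["wt_dose_pM"]), float(entry["mut_dose_pM"]),
            wt_tag, mut_tag, label=str(entry["label"]),
        )
    except CasrDimerError as exc:
        raise ConfigError(field, str(exc)) from exc


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: Any) -> dict:
    _require(isinstance(cfg, dict), "<root>", "config must be a mapping")
    merged = default_config()
    for key, val in cfg.items():
        if key in ("generator", "deconvolution", "trafficking") and isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    grid = merged.get("grid")
    _require(isinstance(grid, (list, tuple)) and len(grid) > 0, "grid",
             "must be a non-empty list of concentrations (mM)")
    _require(all(float(c) > 0 for c in grid), "grid", "concentrations must be > 0")
    _require(isinstance(merged.get("seed"), int), "seed", "must be an integer")
    conds = merged.get("conditions")
    _require(isinstance(conds, list) and conds, "conditions", "must be a non-empty list")
    labels = [c.get("label") for c in conds]
    _require(len(set(labels)) == len(labels), "conditions", "labels must be unique")
    for i, entry in enumerate(conds):
        _mix_from_entry(entry, f"conditions[{i}]")
    dec = merged["deconvolution"]
    for key in ("mix", "reference", "wt_full", "background"):
        _require(dec.get(key) in labels, f"deconvolution.{key}",
                 f"must name one of the condition labels {labels}")
    tr = merged["trafficking"]
    _mix_from_entry(tr["control"], "trafficking.control")
    for i, entry in enumerate(tr["conditions"]):
        _mix_from_entry(entry, f"trafficking.conditions[{i}]")
    gen = merged["generator"]
    _require(isinstance(gen, dict), "generator", "must be a mapping")
    return merged


def _stage(log: list[dict], name: str, t0: float, **info) -> None:
    log.append({"stage": name, "wall_s": round(time.perf_counter() - t0, 3), **info})


def run_pipeline(
    config: str | Path | Mapping[str, Any] | None = None,
    out_dir: str | Path = "results/pipeline",
    seed: int | None = None,
    allow_flags: bool = False,
) -> dict:
    """Run the full synthetic study and write all outputs under ``out_dir``.

    Returns the report dict (also written as ``report.json``).  Raises
    :class:`ConvergenceError` on any flagged non-converged fit unless
    ``allow_flags`` is set.
    """
    if config is None:
        cfg = default_config()
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(dict(config))
    if seed is not None:
        cfg["seed"] = int(seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_cfg = GeneratorConfig(seed=cfg["seed"], **cfg["generator"])
    grid = [float(c) for c in cfg["grid"]]
    log: list[dict] = []

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    conditions = {
        e["label"]: _mix_from_entry(e, "conditions") for e in cfg["conditions"]
    }
    sim = generate_experiment(conditions, grid, gen_cfg)
    write_dose_response_csv(sim.tables.values(), out / "dose_response.csv")
    sim.peaks.to_csv(out / "peaks.csv", index=False)
    _stage(log, "simulate", t0, conditions=len(conditions), grid=len(grid),
           seed=cfg["seed"])

    # --- fit each condition -------------------------------------------------
    t0 = time.perf_counter()
    fits: dict[str, HillFit] = {}
    for label, table in sim.tables.items():
        try:
            fits[label] = fit_hill(table)
        except CasrDimerError as exc:
            raise type(exc)(f"fit stage, condition {label!r}: {exc}") from exc
    flagged = [l for l, f in fits.items() if not f.converged]
    if flagged and not allow_flags:
        raise ConvergenceError(
            f"fit stage: non-converged fits for {flagged}; rerun with "
            "allow_flags to tolerate"
        )
    (out / "fits.json").write_text(
        json.dumps({l: fit_report(f) for l, f in fits.items()}, indent=2) + "\n"
    )
    _stage(log, "fit", t0, n_fits=len(fits), flagged=flagged)

    # --- background subtraction and deconvolution ---------------------------
    t0 = time.perf_counter()
    dec = cfg["deconvolution"]
    agg = {label: t.aggregate() for label, t in sim.tables.items()}
    bg = agg[dec["background"]]
    wt_bgsub = subtract_background(agg[dec["wt_full"]], bg)
    quarter_bgsub = subtract_background(agg[dec["reference"]], bg)
    mix_bgsub = subtract_background(agg[dec["mix"]], bg)
    wt_corrected = fit_hill(wt_bgsub)
    quarter_corrected = fit_hill(quarter_bgsub)
    mix_corrected = fit_hill(mix_bgsub)
    linearity = compare_scaled(
        wt_corrected.params, quarter_corrected.params,
        float(dec["quarter_scale"]), grid,
    )
    het = isolate_heterodimer(
        agg[dec["mix"]], agg[dec["reference"]],
        full_wt_fit=wt_corrected.params,
        scale_factor=float(dec["het_membrane_fraction"]),
    )
    het.write_json(out / "heterodimer.json")
    het_vs_wt = (
        None
        if het.fit is None
        else compare_scaled(
            wt_corrected.params, het.fit.params,
            float(dec["het_membrane_fraction"]), grid,
        )
    )
    _stage(log, "deconvolve", t0, degenerate=het.degenerate,
           warnings=het.warnings)

    # --- trafficking --------------------------------------------------------
    t0 = time.perf_counter()
    tr = cfg["trafficking"]
    control_mix = _mix_from_entry(tr["control"], "trafficking.control")
    ctrl_profiles = generate_line_profiles(control_mix, gen_cfg)
    ctrl_expr = summarize_expression(
        control_mix.key,
        [[profile_peak(p) for p in cov] for cov in ctrl_profiles],
    )
    ctrl_expr = with_fraction(ctrl_expr, ctrl_expr)
    expressions = [ctrl_expr]
    comparisons = []
    predictions = {ctrl_expr.condition_label: 1.0}
    for entry in tr["conditions"]:
        mix = _mix_from_entry(entry, "trafficking.conditions")
        tag = "EGFP" if "EGFP" in (mix.wt_tag, mix.mut_tag) else mix.wt_tag
        profiles = generate_line_profiles(mix, gen_cfg, tag=tag)
        expr = summarize_expression(
            mix.key, [[profile_peak(p) for p in cov] for cov in profiles]
        )
        expr = with_fraction(expr, ctrl_expr)
        expressions.append(expr)
        if tag in (mix.wt_tag, mix.mut_tag) and tag != "none":
            comp = compare_to_model(expr, mix, control_mix, tag=tag)
            comparisons.append(comp.to_dict())
            predictions[expr.condition_label] = comp.predicted_fraction
    write_expression_csv(expressions, out / "expression.csv", predictions)
    _stage(log, "traffic", t0, conditions=len(expressions))

    # --- report -------------------------------------------------------------
    report = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": cfg["seed"],
        "config": cfg,
        "fits": {l: fit_report(f) for l, f in fits.items()},
        "corrected_fits": {
            "wt_full_corrected": fit_report(wt_corrected),
            "wt_quarter_corrected": fit_report(quarter_corrected),
            "mix_corrected": fit_report(mix_corrected),
        },
        "linearity_check": linearity.to_dict(),
        "heterodimer": het.to_dict(),
        "heterodimer_vs_scaled_wt": None
        if het_vs_wt is None
        else het_vs_wt.to_dict(),
        "trafficking": {
            "expressions": [
                {
                    "condition": e.condition_label,
                    "mean_peak": e.mean_peak,
                    "sem": e.sem,
                    "n_cells": e.n_cells,
                    "n_coverslips": e.n_coverslips,
                    "relative_to_control": e.relative_to_control,
                    "relative_sem": e.relative_sem,
                }
                for e in expressions
            ],
            "model_comparisons": comparisons,
        },
        "log": log,
    }
    report["headline"] = summarize_headline(report)
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def summarize_headline(report: Mapping[str, Any]) -> dict:
    """Headline ratios: heterodimer/WT EC50 and mixture/WT maximal response.

    Requires the corrected WT fit and the isolated-heterodimer fit in the
    report.  The EC50 ratio quantifies the affinity loss of the heterodimer;
    the maximal-response ratio of the background-corrected mixture against
    background-corrected full-dose WT reflects the membrane fraction lost to
    retained mutant homodimers (0.75 for an equimolar mix under full rescue).
    """
    try:
        wt = report["corrected_fits"]["wt_full_corrected"]
        mix_fit = report["corrected_fits"]["mix_corrected"]
        het = report["heterodimer"]["fit"]
    except (KeyError, TypeError) as exc:
        raise CasrDimerError(f"report is missing required fits: {exc}") from exc
    if het is None:
        raise CasrDimerError("heterodimer fit is degenerate; no headline ratio")
    return {
        "ec50_ratio_het_over_wt": het["ec50_mM"] / wt["ec50_mM"],
        "max_response_ratio_mix_over_wt": mix_fit["f_max"] / wt["f_max"],
        "wt_ec50_mM": wt["ec50_mM"],
        "het_ec50_mM": het["ec50_mM"],
        "het_f_max": het["f_max"],
    }
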