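#!/usr/bin/env python
"""Quantify membrane expression from line profiles and test the model.

Reads the per-coverslip profile CSVs written by 01_simulate.py, measures
each cell's baseline-subtracted peak, aggregates by coverslip, computes
fractions relative to the full-dose WT-EGFP control, and compares each
condition against the random-association prediction.
"""

from pathlib import Path

from casrdimer import compare_to_model, membrane_fraction, profile_peak
from casrdimer.pipeline import _mix_from_entry, default_config
from casrdimer.trafficking import (
    read_profile_csv,
    summarize_expression,
    with_fraction,
    write_expression_csv,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def condition_expression(label: str) -> "object":
    covs = sorted((OUT / "profiles").glob(f"{label}_cov*.csv"))
    peaks = [[profile_peak(p) for p in read_profile_csv(path)] for path in covs]
    return summarize_expression(label, peaks)


def main() -> None:
    cfg = default_config()
    tr = cfg["trafficking"]
    control_mix = _mix_from_entry(tr["control"], "control")
    ctrl = condition_expression(tr["control"]["label"])
    ctrl = with_fraction(ctrl, ctrl)
    rows, predictions = [ctrl], {ctrl.condition_label: 1.0}
    print(f"{'condition':>28}  observed  predicted")
    for entry in tr["conditions"]:
        mix = _mix_from_entry(entry, "conditions")
        expr = with_fraction(condition_expression(entry["label"]), ctrl)
        rows.append(expr)
        tag = "EGFP" if "EGFP" in (mix.wt_tag, mix.mut_tag) else mix.wt_tag
        comp = compare_to_model(expr, mix, control_mix, tag=tag)
        predictions[expr.condition_label] = comp.predicted_fraction
        note = "" if comp.consistent else (
            "  (deviates >2 SEM: cytoplasmic/out-of-focus signal adds to the"
            " edge reading)"
        )
        print(f"{entry['label']:>28}  {100 * comp.observed_fraction:6.1f}%  "
              f"{100 * comp.predicted_fraction:6.1f}%{note}")
    write_expression_csv(rows, OUT / "expression.csv", predictions)
    print(f"-> {OUT / 'expression.csv'}")


if __name__ == "__main__":
    main()
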