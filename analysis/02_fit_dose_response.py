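#!/usr/bin/env python
"""Fit the Hill equation to every simulated condition.

Reads results/dose_response.csv (written by 01_simulate.py), fits each
condition's per-coverslip points, and writes the fit table.  The wild-type
conditions should recover their generating presets; the mutant-only and
untransfected conditions carry only the small endogenous background.
"""

import json
from pathlib import Path

from casrdimer import fit_hill
from casrdimer.hill import fit_report, read_dose_response_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tables = read_dose_response_csv(OUT / "dose_response.csv")
    reports = {}
    for label, table in tables.items():
        fit = fit_hill(table)
        reports[label] = fit_report(fit)
        p = fit.params
        print(f"{label:>18}: F_max={p.f_max:5.3f}±{p.se_f_max:.3f}  "
              f"EC50={p.ec50:6.3f}±{p.se_ec50:.3f} mM  "
              f"n={p.hill_n:5.3f}±{p.se_hill_n:.3f}  "
              f"(rss={fit.rss:.4f}, converged={fit.converged})")
    (OUT / "fits.json").write_text(json.dumps(reports, indent=2) + "\n")
    print(f"-> {OUT / 'fits.json'}")


if __name__ == "__main__":
    main()
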