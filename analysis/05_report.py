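#!/usr/bin/env python
"""Run the whole pipeline end to end and print the headline result.

Equivalent to `casrdimer run --seed 1 --out results/pipeline`; the report
aggregates per-condition fits, the deconvolution, the trafficking
comparisons and the two headline ratios into results/pipeline/report.json.
"""

from pathlib import Path

from casrdimer import run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"
SEED = 1


def main() -> None:
    report = run_pipeline(seed=SEED, out_dir=OUT)
    head = report["headline"]
    print(f"report -> {OUT / 'report.json'}")
    print(f"WT EC50 (background-corrected) : {head['wt_ec50_mM']:.2f} mM")
    print(f"heterodimer EC50               : {head['het_ec50_mM']:.2f} mM")
    print(f"EC50 ratio het/WT              : {head['ec50_ratio_het_over_wt']:.2f}")
    print(f"max-response ratio mix/WT      : "
          f"{head['max_response_ratio_mix_over_wt']:.2f}")
    print("reading: the equimolar mix loses ~25% of its maximal response to "
          "retained mutant homodimers, and the surviving heterodimer "
          "component senses calcium with ~3-fold lower affinity than WT.")


if __name__ == "__main__":
    main()
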