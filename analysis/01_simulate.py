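#!/usr/bin/env python
"""Generate the synthetic study data: dose-response design + line profiles.

Simulates the full six-condition calcium-imaging design (per-cell traces,
peak extraction, per-coverslip aggregation) on the standard 0.5-50 mM grid,
plus the trafficking line-profile experiment, and writes the CSVs the later
stages consume under results/.
"""

from pathlib import Path

from casrdimer import GeneratorConfig, generate_experiment, generate_line_profiles
from casrdimer.hill import write_dose_response_csv
from casrdimer.pipeline import _mix_from_entry, default_config
from casrdimer.trafficking import write_profile_csv

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cfg = default_config()
    cfg["seed"] = SEED
    gen = GeneratorConfig(seed=SEED, **cfg["generator"])
    conditions = {
        e["label"]: _mix_from_entry(e, "conditions") for e in cfg["conditions"]
    }
    sim = generate_experiment(conditions, cfg["grid"], gen)
    OUT.mkdir(exist_ok=True)
    write_dose_response_csv(sim.tables.values(), OUT / "dose_response.csv")
    sim.peaks.to_csv(OUT / "peaks.csv", index=False)
    print(f"simulated {len(conditions)} conditions x {len(cfg['grid'])} "
          f"concentrations x {gen.coverslips_per_conc} coverslips "
          f"({len(sim.peaks)} cells) -> {OUT / 'dose_response.csv'}")

    profile_dir = OUT / "profiles"
    profile_dir.mkdir(exist_ok=True)
    tr = cfg["trafficking"]
    for entry in [tr["control"], *tr["conditions"]]:
        mix = _mix_from_entry(entry, "trafficking")
        tag = "EGFP" if "EGFP" in (mix.wt_tag, mix.mut_tag) else mix.wt_tag
        for cov, cells in enumerate(generate_line_profiles(mix, gen, tag=tag)):
            write_profile_csv(
                cells, profile_dir / f"{entry['label']}_cov{cov}.csv",
                condition=entry["label"], coverslip=cov,
            )
    print(f"line profiles -> {profile_dir}")


if __name__ == "__main__":
    main()
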