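"""Synthetic-data generator: reproducibility, limits, statistical structure."""

import numpy as np
import pytest

from casrdimer import (
    ConstructMix,
    DomainError,
    GeneratorConfig,
    HillParams,
    eval_hill,
    extract_peak,
    fit_hill,
    generate_experiment,
    generate_trace,
)
from casrdimer.synth import default_protocol

ZERO_BG = HillParams(0.0, 1.0, 1.0)
WT_MIX = ConstructMix(250.0, 0.0, "EGFP", "none", label="wt")


class TestGenerateTrace:
    def test_same_seed_same_trace(self):
        cfg = GeneratorConfig(seed=7)
        protocol = default_protocol(10.0, cfg)
        a = generate_trace(WT_MIX, protocol, cfg, "cellA")
        b = generate_trace(WT_MIX, protocol, cfg, "cellA")
        assert np.array_equal(a.f_over_f0, b.f_over_f0)
        c = generate_trace(WT_MIX, protocol, cfg, "cellB")
        assert not np.array_equal(a.f_over_f0, c.f_over_f0)

    def test_peak_occurs_within_55_s_of_switch(self):
        cfg = GeneratorConfig(seed=0, noise_sd=0.0, cell_cv=0.0)
        protocol = default_protocol(10.0, cfg)
        tr = generate_trace(WT_MIX, protocol, cfg)
        t_peak = tr.times[np.argmax(tr.f_over_f0)]
        assert protocol.t_switch_on < t_peak <= protocol.t_switch_on + 55.0

    def test_slow_decay_after_peak(self):
        cfg = GeneratorConfig(seed=0, noise_sd=0.0, cell_cv=0.0)
        protocol = default_protocol(10.0, cfg)
        tr = generate_trace(WT_MIX, protocol, cfg)
        in_app = (tr.times > protocol.t_switch_on) & (
            tr.times <= protocol.t_switch_off
        )
        f = tr.f_over_f0[in_app]
        i_peak = int(np.argmax(f))
        tail = f[i_peak:]
        assert np.all(np.diff(tail) <= 0), "monotone decay after the peak"
        assert tail[-1] > 1 + 0.5 * (f[i_peak] - 1), "decay is slow"

    def test_mut_only_response_is_background_sized(self):
        """Cells with only mutant receptor respond like untransfected cells."""
        cfg = GeneratorConfig(seed=3, noise_sd=0.0, cell_cv=0.0)
        mut = ConstructMix(0.0, 250.0, "none", "EGFP", label="mut")
        tr = generate_trace(mut, default_protocol(10.0, cfg), cfg)
        peak = extract_peak(tr).value
        assert peak == pytest.approx(
            eval_hill(cfg.background_hill, 10.0), rel=1e-9
        )
        assert peak < 0.06  # small, near the reported ~0.04 scale


class TestGenerateExperiment:
    def test_single_cell_noise_free_equals_model(self, grid):
        cfg = GeneratorConfig(
            seed=0, noise_sd=0.0, cell_cv=0.0, cells_per_coverslip=1,
            coverslips_per_conc=1, background_hill=ZERO_BG,
        )
        sim = generate_experiment({"wt": WT_MIX}, [10.0], cfg)
        table = sim.tables["wt"]
        assert len(table.points) == 1
        expected = eval_hill(HillParams(0.998, 4.552, 2.163), 10.0)
        assert table.points[0].response == pytest.approx(expected, rel=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(DomainError):
            generate_experiment({"wt": WT_MIX}, [], GeneratorConfig())

    def test_full_design_schema(self, grid):
        cfg = GeneratorConfig(seed=2, cells_per_coverslip=5)
        conds = {
            "wt": WT_MIX,
            "mix": ConstructMix(125.0, 125.0, "EGFP", "myc", label="mix"),
        }
        sim = generate_experiment(conds, grid, cfg)
        for label, table in sim.tables.items():
            assert table.n_distinct_conc == len(grid)
            assert len(table.points) == len(grid) * cfg.coverslips_per_conc
            assert np.all(table.sem >= 0)
            assert np.all(table.n_cells == cfg.cells_per_coverslip)
        assert len(sim.peaks) == 2 * len(grid) * 3 * 5

    def test_determinism_and_substream_independence(self, grid):
        """Identical seeds give identical tables; adding a condition leaves
        existing conditions' data untouched."""
        cfg = GeneratorConfig(seed=11, cells_per_coverslip=4)
        sim1 = generate_experiment({"wt": WT_MIX}, grid, cfg)
        sim2 = generate_experiment({"wt": WT_MIX}, grid, cfg)
        assert sim1.tables["wt"].response == pytest.approx(
            sim2.tables["wt"].response, rel=0, abs=0
        )
        both = generate_experiment(
            {"mix": ConstructMix(125.0, 125.0, label="mix"), "wt": WT_MIX},
            grid, cfg,
        )
        assert np.array_equal(
            both.tables["wt"].response, sim1.tables["wt"].response
        )

    def test_noise_scaling_of_cell_peaks(self):
        """Per-cell peak SD grows linearly with the trace noise level."""
        sds = []
        for noise in (0.02, 0.04):
            cfg = GeneratorConfig(seed=6, noise_sd=noise, cell_cv=0.0,
                                  cells_per_coverslip=60,
                                  coverslips_per_conc=1,
                                  background_hill=ZERO_BG)
            sim = generate_experiment({"wt": WT_MIX}, [10.0], cfg)
            sds.append(sim.peaks["peak_dff0"].std())
        assert sds[1] == pytest.approx(2 * sds[0], rel=0.3)

    def test_sem_scales_with_inverse_sqrt_cells(self):
        sems = []
        for n in (10, 40):
            cfg = GeneratorConfig(seed=8, cells_per_coverslip=n,
                                  coverslips_per_conc=1)
            sim = generate_experiment({"wt": WT_MIX}, [10.0], cfg)
            sems.append(sim.tables["wt"].points[0].sem)
        assert sems[1] == pytest.approx(sems[0] / 2, rel=0.5)

    def test_condition_fits_recover_noise_free_truth(self, grid):
        """Noisy fits of the responding conditions land close to the
        noise-free fits of the same design, and the silent conditions stay
        near-flat.

        Peak extraction is a maximum over a noisy window, which inflates
        near-zero responses (a property shared with the real measurement),
        so the comparison uses relative tolerances rather than fitted SEs
        and treats the background-only conditions separately.
        """
        conditions = {
            "wt_egfp": ConstructMix(250.0, 0.0, "EGFP", "none", label="wt_egfp"),
            "wt_myc": ConstructMix(250.0, 0.0, "myc", "none", label="wt_myc"),
            "wt_egfp_mut_myc": ConstructMix(125.0, 125.0, "EGFP", "myc",
                                            label="wt_egfp_mut_myc"),
            "mut_egfp_wt_myc": ConstructMix(125.0, 125.0, "myc", "EGFP",
                                            label="mut_egfp_wt_myc"),
            "mut_egfp": ConstructMix(0.0, 250.0, "none", "EGFP",
                                     label="mut_egfp"),
            "untransfected": ConstructMix(0.0, 250.0, "none", "none",
                                          label="untransfected"),
        }
        clean_cfg = GeneratorConfig(seed=0, noise_sd=0.0, cell_cv=0.0,
                                    cells_per_coverslip=1,
                                    coverslips_per_conc=1)
        noisy_cfg = GeneratorConfig(seed=12)
        clean = generate_experiment(conditions, grid, clean_cfg)
        noisy = generate_experiment(conditions, grid, noisy_cfg)
        responding = ["wt_egfp", "wt_myc", "wt_egfp_mut_myc", "mut_egfp_wt_myc"]
        for label in responding:
            truth = fit_hill(clean.tables[label])
            fit = fit_hill(noisy.tables[label])
            assert fit.converged
            assert fit.ec50 == pytest.approx(truth.ec50, rel=0.10)
            # Hill parameters are strongly correlated, so compare the fitted
            # curves where the data live; 0.1 bounds the peak-statistic bias
            curve_t = eval_hill(truth.params, grid)
            curve_f = eval_hill(fit.params, grid)
            assert np.max(np.abs(curve_f - curve_t)) < 0.1
        for label in ("mut_egfp", "untransfected"):
            # background-only conditions: small response throughout
            clean_top = clean.tables[label].response.max()
            noisy_top = noisy.tables[label].response.max()
            assert noisy_top == pytest.approx(clean_top, abs=0.08)
            assert noisy_top < 0.3
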