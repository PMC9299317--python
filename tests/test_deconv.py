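"""Curve-subtraction deconvolution and scaled-curve comparisons."""

import numpy as np
import pytest

from casrdimer import (
    AlignmentError,
    ConstructMix,
    DoseResponsePoint,
    DoseResponseTable,
    GeneratorConfig,
    HillParams,
    compare_scaled,
    fit_hill,
    isolate_heterodimer,
    subtract_background,
)
from casrdimer.hill import eval_hill
from casrdimer.synth import generate_experiment

from conftest import table_from_params

# Fitted parameter sets for the low-baseline study conditions
WT_100 = HillParams(0.99105, 2.452, 2.459)
CO_MIX = HillParams(0.750, 4.966, 1.703)
WT_25 = HillParams(0.341, 2.955, 1.866)
UNTRANSFECTED = HillParams(0.274, 42.722, 0.931)
WT_CORRECTED = HillParams(0.877, 2.294, 2.735)
WT_25_CORRECTED = HillParams(0.226, 2.442, 2.432)


class TestSubtractBackground:
    def test_self_subtraction_is_zero(self, grid):
        t = table_from_params(WT_100, grid, sem=0.02)
        diff = subtract_background(t, t)
        assert np.all(diff.response == 0.0)
        # SEMs combine in quadrature, n stays with the transfected table
        assert diff.sem == pytest.approx(0.02 * np.sqrt(2))
        assert diff.n_cells.tolist() == t.n_cells.tolist()

    def test_zero_table_is_identity(self, grid):
        t = table_from_params(WT_100, grid, sem=0.01)
        zero = DoseResponseTable(
            "zero", tuple(DoseResponsePoint(float(c), 0.0) for c in grid)
        )
        diff = subtract_background(t, zero)
        assert diff.response == pytest.approx(t.response)

    def test_grid_mismatch_rejected(self, grid):
        t = table_from_params(WT_100, grid)
        other = table_from_params(UNTRANSFECTED, grid * 1.5)
        with pytest.raises(AlignmentError):
            subtract_background(t, other)

    def test_wt_minus_untransfected_refit(self, grid):
        """Subtracting the untransfected curve from the full-dose WT curve
        and refitting recovers the background-corrected WT affinity."""
        diff = subtract_background(
            table_from_params(WT_100, grid, label="wt100"),
            table_from_params(UNTRANSFECTED, grid, label="bg"),
        )
        fit = fit_hill(diff)
        # frozen subtract-and-refit oracle values (scipy curve_fit)
        assert fit.ec50 == pytest.approx(2.2892, rel=1e-3)
        assert fit.f_max == pytest.approx(0.8873, rel=1e-3)
        # lands on the background-corrected fit of the same condition
        assert fit.ec50 == pytest.approx(WT_CORRECTED.ec50, rel=0.01)

    def test_near_zero_difference_fit_is_degenerate(self, grid):
        rng = np.random.default_rng(1)
        a = table_from_params(UNTRANSFECTED, grid, label="u1")
        noisy = table_from_params(
            UNTRANSFECTED, grid, label="u2", noise=0.004, rng=rng
        )
        diff = subtract_background(noisy, a)
        res = isolate_heterodimer(noisy, a)
        assert res.degenerate
        assert res.fit is None
        assert np.all(np.abs(diff.response) < 0.02)


class TestIsolateHeterodimer:
    def test_mix_equal_to_reference_flags_degenerate(self, grid):
        t = table_from_params(WT_25, grid, sem=0.01)
        res = isolate_heterodimer(t, t)
        assert res.degenerate and res.fit is None

    def test_worked_example_recovers_heterodimer_curve(self, grid):
        """Differencing the mixed-population curve against the quarter-dose
        WT curve isolates a component with ~3x lower affinity than WT."""
        res = isolate_heterodimer(
            table_from_params(CO_MIX, grid, label="mix"),
            table_from_params(WT_25, grid, label="ref"),
            full_wt_fit=WT_CORRECTED,
            scale_factor=0.5,
        )
        assert res.fit is not None and res.fit.converged
        # frozen subtract-and-refit oracle values (scipy curve_fit)
        assert res.fit.f_max == pytest.approx(0.3999, rel=1e-3)
        assert res.fit.ec50 == pytest.approx(7.2416, rel=1e-3)
        # equal-efficacy reference: full WT scaled by the membrane fraction
        assert res.reference_fit.f_max == pytest.approx(0.5 * WT_CORRECTED.f_max)
        assert not res.warnings

    def test_zero_efficacy_heterodimer_yields_flat_difference(self, grid):
        """If heterodimers were silent, mix-minus-reference is flat noise."""
        cfg = GeneratorConfig(seed=9, het_efficacy=0.0, coverslips_per_conc=6,
                              wt_component="wt_full_corrected")
        conds = {
            "mix": ConstructMix(125.0, 125.0, label="mix"),
            "ref": ConstructMix(62.5, 0.0, label="ref"),
        }
        sim = generate_experiment(conds, grid, cfg)
        res = isolate_heterodimer(
            sim.tables["mix"].aggregate(), sim.tables["ref"].aggregate()
        )
        diff = res.points
        # 6 coverslips/concentration stabilize the between-coverslip SEM
        # estimate; a 5e-3 floor guards the smallest-response points
        assert np.all(np.abs(diff.response) <= 3 * np.maximum(diff.sem, 5e-3))

    def test_parameter_recovery_from_synthetic_mixture(self, grid):
        """The pipeline recovers a known heterodimer EC50 from noisy data."""
        truth = HillParams(0.396, 7.149, 1.990)
        cfg = GeneratorConfig(seed=5, noise_sd=0.02,
                              wt_component="wt_full_corrected")
        conds = {
            "mix": ConstructMix(125.0, 125.0, label="mix"),
            "ref": ConstructMix(62.5, 0.0, label="ref"),
        }
        sim = generate_experiment(conds, grid, cfg)
        res = isolate_heterodimer(
            sim.tables["mix"].aggregate(), sim.tables["ref"].aggregate()
        )
        assert res.fit.ec50 == pytest.approx(truth.ec50, rel=0.10)

    def test_end_to_end_recovery_across_affinities(self, grid):
        """Median relative EC50 error < 10% for heterodimer EC50 in 3-12 mM."""
        errs = []
        for i, ec50 in enumerate([3.0, 5.0, 7.0, 9.0, 12.0]):
            presets = dict(GeneratorConfig().presets)
            presets["heterodimer"] = HillParams(0.396, ec50, 1.99)
            cfg = GeneratorConfig(seed=100 + i, presets=presets,
                                  wt_component="wt_full_corrected")
            conds = {
                "mix": ConstructMix(125.0, 125.0, label="mix"),
                "ref": ConstructMix(62.5, 0.0, label="ref"),
            }
            sim = generate_experiment(conds, grid, cfg)
            res = isolate_heterodimer(
                sim.tables["mix"].aggregate(), sim.tables["ref"].aggregate()
            )
            errs.append(abs(res.fit.ec50 - ec50) / ec50)
        assert np.median(errs) < 0.10


class TestCompareScaled:
    def test_exact_scaled_copy_has_zero_discrepancy(self, grid):
        from casrdimer import scale_hill_curve

        target = scale_hill_curve(WT_CORRECTED, 0.25)
        rec = compare_scaled(WT_CORRECTED, target, 0.25, grid)
        assert rec.max_abs_diff == pytest.approx(0.0, abs=1e-15)
        assert rec.ec50_ratio == pytest.approx(1.0)

    def test_quarter_scaled_wt_matches_quarter_dose_fit(self, grid):
        """Linear expression: the 0.25-scaled full-dose curve is almost
        indistinguishable from the independently fitted quarter-dose curve."""
        rec = compare_scaled(WT_CORRECTED, WT_25_CORRECTED, 0.25, grid)
        assert rec.rms_diff < 0.02

    def test_heterodimer_affinity_shift(self, grid):
        het = HillParams(0.396, 7.149, 1.990)
        rec = compare_scaled(WT_CORRECTED, het, 0.5, grid)
        assert rec.ec50_ratio == pytest.approx(3.0, rel=0.20)

    def test_invalid_scale_rejected(self, grid):
        with pytest.raises(AlignmentError):
            compare_scaled(WT_CORRECTED, WT_25, 1.5, grid)
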