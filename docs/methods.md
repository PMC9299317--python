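# Methods

This note documents the models, numerical choices and assumptions behind
`casrdimer`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Transduction model

All concentration–response relationships are described by the Hill equation

    (F − F0)/F0 = F_max / (1 + (EC50 / [Ca2+]o)^n)

with F_max the maximal fractional indicator-fluorescence increase (efficacy
surrogate, dimensionless), EC50 the half-maximally activating extracellular
calcium concentration (mM, affinity surrogate), and n the Hill coefficient.
The model is phenomenological: no IP₃/calcium-store kinetics are modeled,
because the analysis consumes only peak responses.

**Fitting.** Unweighted nonlinear least squares on per-coverslip mean peaks
(`scipy.optimize.least_squares`, trust-region reflective), matching an
analysis performed on coverslip means; 1/SEM² weighting is available behind
a flag.  Initialization: F_max from the largest response, EC50 from the
half-maximum crossing by linear interpolation, n = 2.  Bounds
F_max ∈ (0, 10], EC50 ∈ (0, 10³] mM, n ∈ (0, 10] keep
concentration-independent data (untransfected cells, whose fitted EC50 is
essentially unidentified) from diverging.  Three deterministic perturbed
restarts precede a flagged (never silent) non-convergence.  Standard errors
come from the Gauss-Newton curvature at the optimum,
s²(JᵀJ)⁻¹ with s² = RSS/(m−3).  Fewer than four distinct concentrations is
an error; a response range under 0.02 ΔF/F₀ raises a degenerate-fit error
rather than returning noise-chasing parameters.

**Default grid.** {0.5, 1, 2, 3, 5, 10, 20, 50} mM — eight roughly
log-spaced steps spanning the 0.5–50 mM experimental range.  The exact
concentrations used experimentally between those bounds are not recorded,
so the grid is a documented, configurable choice.

## Random-association dimer model

Assumptions, each a deliberate simplification:

* dimerization is complete (no monomer pool) and ligand-independent;
* expression is linear in plasmid dose (supported by the observed four-fold
  signal change for a four-fold dose change);
* WT–mutant heterodimers traffic as efficiently as WT homodimers
  (`het_trafficking = 1`, configurable for sensitivity analysis);
* mutant homodimers never reach the membrane;
* per-dimer efficacy of heterodimers equals that of WT homodimers
  (`het_efficacy = 1`, configurable); mutant homodimers are silent;
* fluorescent/epitope tags are signaling-neutral; a matching homodimer
  carries two tag copies, a heterodimer one of each.

Membrane fluorescence predictions follow by counting membrane-localized tag
copies per unit transfection; composite signaling follows by weighting
unit-efficacy Hill curves with membrane dimer amounts, scaled by the WT
F_max and (optionally) by total dose relative to a reference dose.  The
binomial fractions are cross-checked in the tests against a Monte-Carlo
random-pairing oracle (10⁶ monomers).

## Trace processing

F/F₀ traces enter with a step protocol (baseline → test concentration).
F₀ is the mean over the 10 s before the switch; traces whose pre-switch
mean deviates from 1 by more than 5% are rejected rather than silently
rescaled.  The peak is the maximum over the 55 s after the switch
(configurable; responses peak well inside the first minute), restricted to
the application window.  Negative peaks are clamped to 0 and flagged,
keeping responses in the Hill equation's range while recording indicator
bleaching or noise.  Coverslip aggregation reports mean, SD/√n and n.

## Deconvolution

Subtraction operates only on identical, strictly increasing concentration
grids (relative tolerance 10⁻⁶); there is no interpolation across grids, so
grid mismatches surface as errors.  SEMs combine in quadrature (the error
propagation is otherwise unspecified in this kind of design).  Heterodimer
isolation subtracts the *raw* quarter-dose WT table from the raw mixture
table — the endogenous background cancels between two transfected
conditions — while WT curves are background-corrected against the
untransfected table before use as efficacy references.  Differences more
negative than one combined SEM at more than two concentrations record a
model-inconsistency warning in the result.  The equal-efficacy reference is
the full-dose WT fit scaled by the heterodimer membrane fraction from the
dimer model (0.5 for an equimolar mix), not a free parameter.

## Trafficking quantification

Profiles are 1-D intensity tables; no image segmentation is performed.  The
off-cell baseline is the mean of the outermost 10% of samples at each end
(background handling is otherwise unspecified for this measurement); the
membrane readout is the baseline-subtracted profile maximum.  Fractions
relative to control propagate SEM by the first-order ratio (delta) method.
A condition whose observed fraction deviates from the random-association
prediction by more than two propagated SEMs is flagged; for mutant-alone
transfections the flagged residual (~13% of control) is interpreted as
out-of-focus cytoplasmic fluorescence, not membrane trafficking.

## Synthetic-data generator

The generator emulates the study conditions: 20 cells per coverslip, 3
coverslips per concentration, one concentration step per coverslip, samples
every 2 s, 100-s applications from a 0.2 mM (or 1 mM) baseline.  Packaged
Hill presets for every studied condition parameterize the mixture model;
the untransfected preset is added to every cell as endogenous background.

* **Trace shape** — rise time constant 8 s, decay 120 s, chosen so the peak
  falls ~22 s after the switch and decays slowly, matching the qualitative
  kinetics; kinetics do not feed any fitted quantity (only peaks do).  The
  sampled shape is normalized to a maximum of exactly 1, so in the
  zero-noise limit the extracted peak equals the model amplitude exactly,
  giving round-trip identity tests their exact oracle.  Each trace is
  renormalized by its own measured baseline mean, as an experimenter
  computes F/F₀; this guarantees the normalization invariant by
  construction.
* **Noise** — additive Gaussian noise (SD 0.03 F/F₀ units per sample) and a
  unit-mean lognormal per-cell amplitude factor (CV 0.15), chosen so
  simulated coverslip SEMs are comparable to reported ones (~0.06 on a peak
  of ~0.9 at n ≈ 11).  True cell-to-cell variability is not reported; the
  CV is a calibration choice.
* **Peak-statistic bias** — because the peak is a maximum over a noisy
  window, near-zero responses read ~2σ high.  Real peak-picking shares this
  bias; tests therefore compare fitted curves rather than raw parameters
  for low-amplitude conditions.
* **Line profiles** — two Gaussian edge peaks (σ 0.5 μm) proportional to
  membrane tag copies over a tanh-edged cytoplasmic plateau, on an 18 μm
  cell (10% size jitter) with 5.25 μm off-cell margins at 0.35 μm sampling.
  The cell radius is quantized to the sampling step so the membrane edge
  lands on a sample and the noise-free peak has no discretization loss.
  The retained-receptor plateau coefficient is calibrated so a mutant-alone
  transfection measures 13% of the WT control peak, modeling that residual
  as optical background; membrane-trafficked receptor leaks 10% of its
  signal into the plateau.  Profile noise is small (SD 0.005 of the control
  edge amplitude) because the max-statistic bias above would otherwise
  distort the low-signal conditions.
* **Randomness** — one integer seed; every coverslip (and every profile
  coverslip) draws from an independent substream keyed on the seed, the
  condition identity, the concentration and the replicate index, so adding
  conditions never perturbs existing data, and identical configurations
  produce bit-identical outputs.

**What passing tests show.** Synthetic data share the analysis' own
structural assumptions (additive background, lognormal amplitudes, Gaussian
noise, exact grid concentrations).  Passing therefore demonstrates internal
consistency and correct implementation of the estimators at realistic noise
levels — not robustness to desensitization, indicator saturation,
heterogeneous transfection efficiency, or optical artifacts beyond the
simple leak model.

## Pipeline sizes and determinism

The default design (6 conditions × 8 concentrations × 3 coverslips × 20
cells, plus 4 trafficking conditions × 3 coverslips × 20 profiles) runs in
about a second; the full test suite in well under a minute.  The
acceptance script's stochastic entries (WT EC₅₀ recovery, trafficking
fraction) use that same design.  Reports embed the seed, the config echo
and the package version; rerunning with the same configuration reproduces
every number except the timestamp.

## Known limitations

* No desensitization model beyond the one-step-per-coverslip design; no
  indicator saturation or bleaching model (negative peaks are clamped).
* No higher-order oligomers, ER-retention kinetics, or heterodimerization
  with other GPCRs.
* The heterodimer isolation assumes the mixture's WT-homodimer content is
  exactly reproduced by the quarter-dose reference transfection; deviations
  from dose linearity would bias the isolated component.
* Fits of concentration-independent (background-only) data are reported
  with very large standard errors and may sit at the parameter bounds;
  downstream code must treat such fits as unidentified rather than
  meaningful.
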