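"""Synthetic calcium-imaging traces, dose-response designs and line profiles.

Everything the analysis pipeline consumes can be generated here with the
statistical structure the analysis assumes, so every stage is testable with
no external data:

* single-cell F/F0 traces with a saturable Hill-type peak, a fast rise, a
  slow post-peak decay, additive Gaussian measurement noise and lognormal
  cell-to-cell amplitude variability;
* full dose-response designs (conditions x concentrations x coverslips x
  cells) honoring the one-step-per-coverslip protocol;
* membrane line profiles with edge peaks proportional to membrane-trafficked
  tag copies (from the random-association model) over a cytoplasmic plateau
  from retained receptor plus optical leak.

Randomness policy: a single integer seed; every coverslip draws from an
independent substream keyed on (seed, condition identity, concentration,
replicate), so adding conditions or concentrations never perturbs data
already generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dimer import ConstructMix, _membrane_tag_copies, predict_mixture_response
from .errors import DomainError
from .hill import DoseResponseTable, HillParams, eval_hill
from .presets import PRESETS
from .traces import FluorescenceTrace, StepProtocol, aggregate_coverslip, extract_peak

__all__ = [
    "GeneratorConfig",
    "SimulatedExperiment",
    "generate_trace",
    "generate_experiment",
    "generate_line_profiles",
]

# Line-profile geometry and intensity model (relative units: the full-dose
# WT-EGFP control has edge amplitude 1).
_CELL_DIAMETER_UM = 18.0
_MARGIN_UM = 5.25  # multiple of the sampling step, so edges land on samples
_STEP_UM = 0.35
_EDGE_SIGMA_UM = 0.5
_OFFCELL_BASELINE = 0.05
#: Cytoplasmic leak of membrane-trafficked receptor (out-of-focus light).
_LEAK_PER_MEMBRANE_COPY = 0.10
#: Cytoplasmic intensity per retained tag copy, calibrated so a mutant-alone
#: transfection measures 13% of the WT control peak (the control peak carries
#: the edge amplitude plus half its leak plateau at the membrane crossing).
_RHO_PER_RETAINED_COPY = 0.13 * (1.0 + 0.5 * _LEAK_PER_MEMBRANE_COPY)


def _substream(seed: int, *keys) -> np.random.Generator:
    """Independent RNG substream keyed on strings/ints (order-sensitive)."""
    words = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode()))
        else:
            words.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(words)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    Defaults reproduce the study conditions: 20 cells per coverslip, 3
    coverslips per concentration, samples every 2 s, 100-s applications from
    a 0.2 mM baseline, trace noise chosen so simulated coverslip SEMs are
    comparable to the reported ones (~0.06 on a peak of ~0.9 at n ~ 11).
    """

    presets: Mapping[str, HillParams] = field(
        default_factory=lambda: dict(PRESETS)
    )
    noise_sd: float = 0.03  # additive F/F0 noise per sample
    cell_cv: float = 0.15  # lognormal CV of per-cell response amplitude
    rise_tau: float = 8.0  # s; post-switch rise time constant
    decay_tau: float = 120.0  # s; slow post-peak decay time constant
    wash_tau: float = 20.0  # s; return to baseline after the application
    background_hill: HillParams = field(
        default_factory=lambda: PRESETS["untransfected"]
    )
    cells_per_coverslip: int = 20
    coverslips_per_conc: int = 3
    sample_interval: float = 2.0  # s
    seed: int = 0
    # component curves driving the mixture model
    wt_component: str = "wt_egfp"
    het_component: str = "heterodimer"
    control_dose_pM: float = 250.0
    het_efficacy: float = 1.0
    het_trafficking: float = 1.0
    # line-profile noise (relative to the control edge amplitude); kept small
    # because the peak statistic is a maximum, whose noise-induced upward bias
    # would otherwise distort the low-signal (mutant-alone) conditions
    profile_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.cell_cv < 0 or self.profile_noise_sd < 0:
            raise DomainError("noise parameters must be >= 0")
        if min(self.rise_tau, self.decay_tau, self.wash_tau) <= 0:
            raise DomainError("time constants must be > 0")
        if self.cells_per_coverslip < 1 or self.coverslips_per_conc < 1:
            raise DomainError("counts must be >= 1")
        if self.sample_interval <= 0:
            raise DomainError("sample_interval must be > 0")

    @property
    def hill_wt(self) -> HillParams:
        return self.presets[self.wt_component]

    @property
    def hill_het(self) -> HillParams:
        return self.presets[self.het_component]


def default_protocol(
    test_conc: float, cfg: GeneratorConfig, baseline_conc: float = 0.2
) -> StepProtocol:
    """Standard step: 30 s baseline, 100 s application, 40 s washout."""
    return StepProtocol(
        baseline_conc=baseline_conc,
        test_conc=test_conc,
        t_switch_on=30.0,
        t_switch_off=130.0,
        sample_interval=cfg.sample_interval,
    )


def _mean_amplitude(mix: ConstructMix, conc: float, cfg: GeneratorConfig) -> float:
    """Population-mean peak dF/F0 for a mix at a test concentration."""
    component = predict_mixture_response(
        mix,
        cfg.hill_wt,
        cfg.hill_het,
        conc,
        het_efficacy=cfg.het_efficacy,
        het_trafficking=cfg.het_trafficking,
        ref_dose_pM=cfg.control_dose_pM,
    )
    background = eval_hill(cfg.background_hill, conc)
    return component + background


def _cell_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal expression factor with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2)))


def generate_trace(
    mix: ConstructMix,
    protocol: StepProtocol,
    cfg: GeneratorConfig,
    cell_id: str = "cell000",
    rng: np.random.Generator | None = None,
) -> FluorescenceTrace:
    """One synthetic F/F0 trace; deterministic given the config seed.

    The trace is ``1 + amplitude * shape(t) + noise`` with the rise/decay
    shape normalized so its sampled in-application maximum is exactly 1:
    with zero noise and zero cell variability, the extracted peak equals the
    mixture-model prediction (plus background) exactly.  The trace is then
    renormalized by its own measured 10-s baseline mean, as in the
    experimental F/F0 computation.
    """
    if rng is None:
        rng = _substream(cfg.seed, "trace", mix.key, cell_id)
    t = np.arange(
        0.0, protocol.t_switch_off + 40.0 + 1e-9, protocol.sample_interval
    )
    dt_on = t - protocol.t_switch_on
    in_app = (dt_on > 0) & (t <= protocol.t_switch_off)
    shape = np.zeros_like(t)
    shape[in_app] = (1.0 - np.exp(-dt_on[in_app] / cfg.rise_tau)) * np.exp(
        -dt_on[in_app] / cfg.decay_tau
    )
    peak_val = shape[in_app].max() if in_app.any() else 1.0
    if peak_val > 0:
        shape /= peak_val  # sampled in-application maximum is exactly 1
    after = t > protocol.t_switch_off
    if after.any() and in_app.any():
        tail0 = shape[in_app][-1]
        shape[after] = tail0 * np.exp(
            -(t[after] - protocol.t_switch_off) / cfg.wash_tau
        )

    amplitude = _mean_amplitude(mix, protocol.test_conc, cfg) * _cell_factor(
        rng, cfg.cell_cv
    )
    f = 1.0 + amplitude * shape
    if cfg.noise_sd > 0:
        f = f + rng.normal(0.0, cfg.noise_sd, size=f.shape)
    f = np.clip(f, 1e-3, None)

    # renormalize by the measured baseline, as the experiment defines F0
    base_mask = (t < protocol.t_switch_on) & (
        t >= protocol.t_switch_on - 10.0
    )
    if base_mask.any():
        f = f / f[base_mask].mean()
    return FluorescenceTrace(cell_id, t, f, protocol)


@dataclass
class SimulatedExperiment:
    """Output of :func:`generate_experiment`."""

    tables: dict[str, DoseResponseTable]
    peaks: pd.DataFrame  # cell_id, condition, conc_mM, coverslip, peak_dff0, clamped
    traces: dict[str, list[FluorescenceTrace]] | None = None


def generate_experiment(
    conditions: Mapping[str, ConstructMix],
    grid: Sequence[float],
    cfg: GeneratorConfig,
    baseline_conc: float = 0.2,
    peak_window_s: float = 55.0,
    keep_traces: bool = False,
) -> SimulatedExperiment:
    """Simulate a full dose-response design and process it to tables.

    One coverslip record per condition x concentration x replicate, each
    coverslip receiving a single concentration step.  Peaks are extracted
    through the real trace-processing operations, so the returned tables
    exercise the same code path as imported data.
    """
    grid = list(grid)
    if not grid:
        raise DomainError("concentration grid must be non-empty")
    tables: dict[str, DoseResponseTable] = {}
    rows = []
    kept: dict[str, list[FluorescenceTrace]] = {}
    for label, mix in conditions.items():
        points = []
        for conc in grid:
            protocol = default_protocol(conc, cfg, baseline_conc)
            for rep in range(cfg.coverslips_per_conc):
                rng = _substream(
                    cfg.seed, "coverslip", label, int(round(conc * 1000)), rep
                )
                peaks = []
                for i in range(cfg.cells_per_coverslip):
                    cid = f"{label}_c{conc:g}_r{rep}_cell{i:03d}"
                    tr = generate_trace(mix, protocol, cfg, cid, rng)
                    pk = extract_peak(tr, peak_window_s)
                    peaks.append(pk)
                    rows.append(
                        {
                            "cell_id": cid,
                            "condition": label,
                            "conc_mM": conc,
                            "coverslip": rep,
                            "peak_dff0": pk.value,
                            "clamped": pk.clamped,
                        }
                    )
                    if keep_traces:
                        kept.setdefault(label, []).append(tr)
                points.append(aggregate_coverslip(peaks, conc))
        tables[label] = DoseResponseTable(label, tuple(points))
    return SimulatedExperiment(
        tables=tables,
        peaks=pd.DataFrame(rows),
        traces=kept if keep_traces else None,
    )


def _profile_signal(
    mix: ConstructMix, tag: str, cfg: GeneratorConfig
) -> tuple[float, float]:
    """(edge amplitude, cytoplasm plateau) in control-relative units."""
    membrane = _membrane_tag_copies(mix, tag, cfg.het_trafficking)
    tagged_total = (mix.wt_dose if mix.wt_tag == tag else 0.0) + (
        mix.mut_dose if mix.mut_tag == tag else 0.0
    )
    retained = max(0.0, tagged_total - membrane)
    unit = cfg.control_dose_pM
    edge = membrane / unit
    plateau = (
        _RHO_PER_RETAINED_COPY * retained / unit
        + _LEAK_PER_MEMBRANE_COPY * membrane / unit
    )
    return edge, plateau


def generate_line_profiles(
    mix: ConstructMix,
    cfg: GeneratorConfig,
    tag: str = "EGFP",
    n_cells: int | None = None,
    n_coverslips: int | None = None,
) -> list[list["LineProfile"]]:
    """Synthetic line profiles for one condition, grouped by coverslip.

    Each profile crosses the whole cell: off-cell background, a cytoplasmic
    plateau (retained receptor plus out-of-focus leak) and two membrane edge
    peaks whose amplitude is proportional to the membrane-localized tag
    copies predicted by the random-association model.  Cell size and
    expression level jitter multiplicatively; measurement noise is additive.
    Deterministic given the config seed.
    """
    from .trafficking import LineProfile

    n_cells = cfg.cells_per_coverslip if n_cells is None else n_cells
    n_cov = cfg.coverslips_per_conc if n_coverslips is None else n_coverslips
    edge_amp, plateau = _profile_signal(mix, tag, cfg)
    out: list[list[LineProfile]] = []
    for cov in range(n_cov):
        rng = _substream(cfg.seed, "profiles", mix.key, tag, cov)
        cells = []
        for i in range(n_cells):
            diameter = _CELL_DIAMETER_UM * float(rng.normal(1.0, 0.10))
            diameter = max(8.0, diameter)
            # quantize the cell radius to the sampling step so the membrane
            # edge coincides with a sample and the peak is read without
            # discretization loss
            half = round(diameter / 2.0 / _STEP_UM) * _STEP_UM
            length = diameter + 2.0 * _MARGIN_UM
            x = np.arange(0.0, length + 1e-9, _STEP_UM)
            center = length / 2.0
            d = x - center
            inside = 0.5 * (
                np.tanh((d + half) / 0.4) - np.tanh((d - half) / 0.4)
            )
            edges = np.exp(-0.5 * ((d + half) / _EDGE_SIGMA_UM) ** 2) + np.exp(
                -0.5 * ((d - half) / _EDGE_SIGMA_UM) ** 2
            )
            expr = _cell_factor(rng, cfg.cell_cv)
            inten = (
                _OFFCELL_BASELINE
                + expr * (plateau * inside + edge_amp * edges)
            )
            if cfg.profile_noise_sd > 0:
                inten = inten + rng.normal(0.0, cfg.profile_noise_sd, x.shape)
            inten = np.clip(inten, 0.0, None)
            cells.append(LineProfile(f"{mix.key}_r{cov}_cell{i:03d}", x, inten))
        out.append(cells)
    return out
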