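"""Random-association dimer assembly, trafficking rescue and mixed signaling.

The calcium-sensing receptor functions as a constitutive dimer.  When
wild-type (WT) and a trafficking-deficient mutant are co-expressed, monomers
are assumed to pair at random, so with WT monomer fraction
``p = wt_dose / (wt_dose + mut_dose)`` the dimer pool splits binomially into

    WT-WT : WT-mut : mut-mut  =  p^2 : 2 p (1-p) : (1-p)^2.

Trafficking rules: WT-WT homodimers and WT-mut heterodimers reach the plasma
membrane (the mutant's trafficking defect is fully rescued by the WT
partner); mut-mut homodimers are retained intracellularly.  Expression is
linear in plasmid dose.  Tag bookkeeping: a matching homodimer carries two
copies of its fluorescent/epitope tag, a heterodimer one copy of each
partner's tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DomainError
from .hill import HillParams, eval_hill

__all__ = [
    "Tag",
    "ConstructMix",
    "DimerDistribution",
    "dimer_fractions",
    "membrane_tag_fraction",
    "predict_mixture_response",
]

Tag = Literal["EGFP", "myc", "none"]
_VALID_TAGS = ("EGFP", "myc", "none")


@dataclass(frozen=True)
class ConstructMix:
    """Plasmid doses (pM) and tag assignment for one transfection condition."""

    wt_dose: float
    mut_dose: float = 0.0
    wt_tag: Tag = "none"
    mut_tag: Tag = "none"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.wt_dose < 0 or self.mut_dose < 0:
            raise DomainError("plasmid doses must be >= 0")
        if self.wt_dose + self.mut_dose <= 0:
            raise DomainError("at least one construct dose must be positive")
        for tag in (self.wt_tag, self.mut_tag):
            if tag not in _VALID_TAGS:
                raise DomainError(f"unknown tag {tag!r}")

    @property
    def total_dose(self) -> float:
        return self.wt_dose + self.mut_dose

    @property
    def p_wt(self) -> float:
        """WT monomer fraction of the expressed pool."""
        return self.wt_dose / self.total_dose

    @property
    def key(self) -> str:
        """Stable identity string (used for RNG substream derivation)."""
        if self.label:
            return self.label
        return (
            f"wt{self.wt_dose:g}{self.wt_tag}_mut{self.mut_dose:g}{self.mut_tag}"
        )


@dataclass(frozen=True)
class DimerDistribution:
    """Binomial dimer fractions and their membrane-trafficked amounts.

    ``f_*`` are fractions of all assembled dimers (summing to 1); ``m_*`` are
    the membrane-localized amounts expressed as fractions of total dimers, so
    ``0 <= m_x <= f_x`` and ``m_mut_mut = 0`` under the default full-rescue /
    full-retention trafficking rules.
    """

    f_wt_wt: float
    f_wt_mut: float
    f_mut_mut: float
    m_wt_wt: float
    m_wt_mut: float
    m_mut_mut: float

    def __post_init__(self) -> None:
        total = self.f_wt_wt + self.f_wt_mut + self.f_mut_mut
        if abs(total - 1.0) > 1e-12:
            raise DomainError(f"dimer fractions must sum to 1, got {total!r}")
        for f, m in (
            (self.f_wt_wt, self.m_wt_wt),
            (self.f_wt_mut, self.m_wt_mut),
            (self.f_mut_mut, self.m_mut_mut),
        ):
            if not (0.0 <= m <= f + 1e-12):
                raise DomainError("membrane amount must lie in [0, fraction]")

    @property
    def membrane_total(self) -> float:
        return self.m_wt_wt + self.m_wt_mut + self.m_mut_mut


def dimer_fractions(
    mix: ConstructMix, het_trafficking: float = 1.0
) -> DimerDistribution:
    """Dimer composition and membrane amounts for a transfection mix.

    Parameters
    ----------
    mix:
        Plasmid doses; expression is proportional to dose.
    het_trafficking:
        Trafficking efficiency of the WT-mut heterodimer relative to the
        WT-WT homodimer.  Default 1.0 (complete rescue); exposed for
        sensitivity analysis.
    """
    if not (0.0 <= het_trafficking <= 1.0):
        raise DomainError("het_trafficking must lie in [0, 1]")
    p = mix.p_wt
    f_ww = p * p
    f_wm = 2.0 * p * (1.0 - p)
    f_mm = (1.0 - p) * (1.0 - p)
    return DimerDistribution(
        f_ww, f_wm, f_mm,
        m_wt_wt=f_ww,
        m_wt_mut=f_wm * het_trafficking,
        m_mut_mut=0.0,
    )


def _membrane_tag_copies(
    mix: ConstructMix, tag: str, het_trafficking: float = 1.0
) -> float:
    """Expected membrane-localized tag copies per unit transfection volume.

    Each pM of construct contributes one tagged monomer; dimers number half
    the monomers.  A homodimer of a tagged construct carries 2 copies, a
    heterodimer carries 1 copy of each partner's tag; mutant homodimers never
    reach the membrane.
    """
    d = dimer_fractions(mix, het_trafficking)
    n_dimers = mix.total_dose / 2.0
    copies_ww = 2.0 if mix.wt_tag == tag else 0.0
    copies_wm = (1.0 if mix.wt_tag == tag else 0.0) + (
        1.0 if mix.mut_tag == tag else 0.0
    )
    return n_dimers * (d.m_wt_wt * copies_ww + d.m_wt_mut * copies_wm)


def membrane_tag_fraction(
    mix: ConstructMix,
    tag: str,
    control_mix: ConstructMix,
    het_trafficking: float = 1.0,
) -> float:
    """Predicted membrane fluorescence of ``tag`` relative to a control mix.

    Returns the expected membrane-localized tag-copy count of ``mix`` divided
    by that of ``control_mix`` (typically a full-dose, all-WT, singly tagged
    transfection).  Homogeneous of degree 1 in total dose at fixed
    composition, reproducing dose proportionality of expression.

    Raises
    ------
    DomainError
        If ``tag`` is carried by no construct in ``mix``, or the control has
        no membrane signal for ``tag``.
    """
    if tag not in (mix.wt_tag, mix.mut_tag):
        raise DomainError(f"tag {tag!r} absent from mix {mix.key}")
    control = _membrane_tag_copies(control_mix, tag, het_trafficking)
    if control <= 0:
        raise DomainError(
            f"control mix {control_mix.key} has no membrane {tag!r} signal"
        )
    return _membrane_tag_copies(mix, tag, het_trafficking) / control


def predict_mixture_response(
    mix: ConstructMix,
    hill_wt: HillParams,
    hill_het: HillParams,
    conc,
    het_efficacy: float = 1.0,
    het_trafficking: float = 1.0,
    ref_dose_pM: float | None = None,
):
    """Composite peak dF/F0 of a mixed WT/mutant receptor population.

    The population response is additive over membrane dimer species:

        R(c) = s * F_max_wt * [ m_ww * h_wt(c) + eff * m_wm * h_het(c) ]

    where ``h_*`` are the component Hill curves rescaled to unit efficacy,
    ``m_*`` are membrane amounts from :func:`dimer_fractions`, ``eff`` is the
    per-dimer efficacy of the heterodimer relative to the WT homodimer
    (default 1.0 -- homodimer and heterodimer have equal efficacy, only their
    affinities differ), mut-mut contributes nothing, and ``s`` scales the
    amplitude linearly with total plasmid dose relative to ``ref_dose_pM``
    (``s = 1`` when ``ref_dose_pM`` is None, i.e. mixes compared at equal
    total dose).
    """
    if het_efficacy < 0:
        raise DomainError("het_efficacy must be >= 0")
    d = dimer_fractions(mix, het_trafficking)
    scale = 1.0 if ref_dose_pM is None else mix.total_dose / ref_dose_pM
    unit_wt = hill_wt.unit_efficacy()
    unit_het = hill_het.unit_efficacy()
    resp = (
        d.m_wt_wt * np.asarray(eval_hill(unit_wt, conc))
        + het_efficacy * d.m_wt_mut * np.asarray(eval_hill(unit_het, conc))
    )
    out = scale * hill_wt.f_max * resp
    if np.isscalar(conc) or np.ndim(conc) == 0:
        return float(out)
    return out
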