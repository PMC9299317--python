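"""Packaged Hill-parameter presets for every receptor condition studied.

Two experimental designs are represented:

* the single-step design (1 -> 0.5-50 mM steps, one step per coverslip):
  ``wt_egfp``, ``wt_myc``, ``wt_egfp_mut_myc``, ``mut_egfp_wt_myc``,
  ``untransfected``, ``mut_egfp``;
* the low-baseline design (0.2 mM baseline, three steps per coverslip with
  10-min washes): raw fits ``wt_full`` (250 pM WT), ``wt_mut_mix`` (125 pM WT
  + 125 pM mutant), ``wt_quarter`` (62.5 pM WT); background-corrected fits
  ``wt_full_corrected`` and ``wt_quarter_corrected``; and the isolated
  ``heterodimer`` component.

These sets parameterize the synthetic-data generator and serve as fixed
inputs to the deterministic subtract-and-refit worked examples.
"""

from __future__ import annotations

from .hill import HillParams

__all__ = ["PRESETS", "get_preset"]

PRESETS: dict[str, HillParams] = {
    # --- single-step design (raw per-condition fits) ---
    "wt_egfp": HillParams(0.998, 4.552, 2.163, 0.021, 0.218, 0.171),
    "wt_myc": HillParams(0.979, 4.603, 2.310, 0.015, 0.154, 0.231),
    "wt_egfp_mut_myc": HillParams(0.803, 6.021, 1.910, 0.008, 0.153, 0.086),
    "mut_egfp_wt_myc": HillParams(0.793, 5.845, 1.889, 0.012, 0.171, 0.114),
    "untransfected": HillParams(0.274, 42.722, 0.931, 0.089, 33.6, 0.266),
    "mut_egfp": HillParams(0.162, 19.195, 2.039, 0.010, 2.49, 0.43),
    # --- low-baseline design (raw fits) ---
    "wt_full": HillParams(0.99105, 2.452, 2.459, 0.0158, 0.099, 0.184),
    "wt_mut_mix": HillParams(0.750, 4.966, 1.703, 0.026, 0.301, 0.139),
    "wt_quarter": HillParams(0.341, 2.955, 1.866, 0.010, 0.235, 0.223),
    # --- low-baseline design, untransfected background subtracted ---
    "wt_full_corrected": HillParams(0.877, 2.294, 2.735, 0.012, 0.081, 0.231),
    "wt_quarter_corrected": HillParams(0.226, 2.442, 2.432, 0.005, 0.131, 0.255),
    # --- isolated WT-mutant heterodimer component ---
    "heterodimer": HillParams(0.396, 7.149, 1.990, 0.019, 0.641, 0.295),
}


def get_preset(name: str) -> HillParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
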