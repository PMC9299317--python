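import numpy as np
import pytest

from casrdimer import ConstructMix, DoseResponsePoint, DoseResponseTable, HillParams
from casrdimer.hill import DEFAULT_GRID, eval_hill


@pytest.fixture
def grid():
    return np.array(DEFAULT_GRID)


@pytest.fixture
def wt_params():
    """Background-corrected full-dose WT curve used in worked examples."""
    return HillParams(0.877, 2.294, 2.735)


def table_from_params(params: HillParams, grid, label="synthetic", sem=0.0,
                      n_cells=20, noise=None, rng=None):
    """Noise-free (or Gaussian-noised) table generated from a Hill curve."""
    resp = eval_hill(params, np.asarray(grid))
    if noise:
        resp = resp + rng.normal(0.0, noise, size=resp.shape)
    pts = tuple(
        DoseResponsePoint(float(c), float(r), sem, n_cells)
        for c, r in zip(grid, resp)
    )
    return DoseResponseTable(label, pts)


@pytest.fixture
def make_table():
    return table_from_params


@pytest.fixture
def equimolar_mix():
    return ConstructMix(125.0, 125.0, "EGFP", "myc", label="equimolar")


@pytest.fixture
def wt_control_mix():
    return ConstructMix(250.0, 0.0, "EGFP", "none", label="control")
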