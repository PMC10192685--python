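import numpy as np
import pytest

from aimeshift.fitting import ConcResponseSeries, FitConfig
from aimeshift.models import eval_model
from aimeshift.plates import PRINTED_1X_LEVELS_UM


@pytest.fixture(scope="session")
def conc9() -> np.ndarray:
    """The printed 9-level 1X concentration design (µM)."""
    return np.array(PRINTED_1X_LEVELS_UM)


@pytest.fixture(scope="session")
def conc_design(conc9) -> np.ndarray:
    """Four experimental replicates of the 9-level design."""
    return np.repeat(conc9, 4)


@pytest.fixture(scope="session")
def fit_cfg() -> FitConfig:
    return FitConfig(seed=0)


def make_series(model, params, conc, noise_sd=0.0, seed=0, chem="chem", mode="MetNeg"):
    """Synthetic series from a named generating curve with additive noise."""
    resp = eval_model(model, params, conc)
    if noise_sd > 0:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise_sd, conc.size)
    return ConcResponseSeries(chem, mode, conc, resp)


@pytest.fixture(scope="session")
def hill_params():
    return {"tp": 2.0, "ga": 10.0, "p": 1.5}
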