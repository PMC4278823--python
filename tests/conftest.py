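import numpy as np
import pytest

from thermopop import ArrheniusModel, BDPParams, ExperimentalDesign, simulate_design


@pytest.fixture(scope="session")
def ref_params() -> BDPParams:
    """Baseline rates: birth 1.5/d, density coefficient 1, death 0.5/d, N=15000."""
    return BDPParams(1.5, 1.0, 0.5, 15000)


@pytest.fixture(scope="session")
def ref_model() -> ArrheniusModel:
    return ArrheniusModel(1.5, 1.0, 0.5, e_a=0.6)


@pytest.fixture(scope="session")
def small_dataset(ref_model):
    """One simulated experiment: 6 temperatures x 3 replicates, daily-ish sampling."""
    design = ExperimentalDesign.from_levels(6, 3, 10, 0.01)
    return simulate_design(ref_model, design, seed=424242)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250929)
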