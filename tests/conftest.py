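import warnings

import numpy as np
import pytest

from teaspec import (
    SimulationParams,
    make_design,
    simulate_sample_spectra,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-shaped fixture with default (noisy) parameters."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_sample_spectra(make_design(), params=SimulationParams(seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Same design with every nuisance term switched off."""
    return simulate_sample_spectra(
        make_design(), params=SimulationParams.noiseless(seed=11)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Compact noisy fixture for fast pipeline-level tests."""
    design = make_design(batches=8, replicates=2, n_channels=201)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_sample_spectra(design, params=SimulationParams(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
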