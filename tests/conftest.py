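import numpy as np
import pytest

from chveval import inference, load_params
from chveval.synthetic_trial import TrialDesign, simulate_trial


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def small_posterior(params):
    """Reconstructed posterior at a reduced draw count for fast unit tests."""
    return inference.reconstruct_from_params(params, S=4000, seed=11)


@pytest.fixture(scope="session")
def medium_panel():
    """A moderately informative synthetic panel shared across inference tests."""
    design = TrialDesign(
        seed=7,
        children_per_cluster_mean=60,
        true_rr={"diarrhoea": 0.85, "fever": 0.85},
    )
    return simulate_trial(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160391)
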