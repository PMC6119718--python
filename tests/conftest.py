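import warnings

import numpy as np
import pytest

import affectfanova as af
from affectfanova.data_model import GridLengthWarning


@pytest.fixture(autouse=True)
def _quiet_grid_warnings():
    # deliberately short grids are routine in unit tests
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GridLengthWarning)
        yield


@pytest.fixture(scope="session")
def tiny_config():
    """A small but structurally complete study: 12 raters, 2 stimuli."""
    stimuli = (
        af.StimulusSpec(
            "m1", "music", 48, ((0.0, 0.1, 0.1), (0.5, 0.5, 0.4), (1.0, -0.3, 0.5))
        ),
        af.StimulusSpec(
            "s1", "speech", 52, ((0.0, 0.0, 0.1), (0.6, -0.5, -0.4), (1.0, 0.2, -0.5))
        ),
    )
    return af.SimulationConfig(stimuli=stimuli, n_participants=12, seed=20260)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    dataset, manifest = af.simulate_study(tiny_config)
    return dataset, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(715)
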