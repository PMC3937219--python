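import numpy as np
import pytest

import fitscape as fs


@pytest.fixture(scope="session")
def design():
    return fs.default_design()


@pytest.fixture(scope="session")
def effects():
    return fs.default_effects()


@pytest.fixture(scope="session")
def true_params():
    return fs.default_true_params()


@pytest.fixture(scope="session")
def clean_study(design, effects, true_params):
    """Noise-free synthetic study: observations equal the truth."""
    return fs.generate_study(design, effects, true_params,
                             fs.NoiseModel.noiseless(seed=0))


@pytest.fixture(scope="session")
def noisy_study(design, effects, true_params):
    """Default-noise synthetic study at a fixed seed."""
    return fs.generate_study(design, effects, true_params,
                             fs.NoiseModel(seed=7))


@pytest.fixture(scope="session")
def clean_fit(clean_study):
    """Landscape fit to the noise-free study (shared; it is expensive)."""
    return fs.fit_landscape(clean_study, n_starts=60, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
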