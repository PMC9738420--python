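import numpy as np
import pytest

from bcipam.data import load_study_table
from bcipam.decoder import calibrate
from bcipam.eeg import generate_synthetic_eeg


@pytest.fixture(scope="session")
def study_table():
    return load_study_table()


@pytest.fixture(scope="session")
def erd_epochs():
    """Strongly separable calibration run (deep ERD, low noise)."""
    return generate_synthetic_eeg(30, 30, erd_depth=0.8, noise_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def chance_epochs():
    """Class-identical calibration run (no ERD)."""
    return generate_synthetic_eeg(30, 30, erd_depth=0.0, noise_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def erd_decoder(erd_epochs):
    model, cv_acc = calibrate(erd_epochs, seed=0)
    model.cv_accuracy_ = cv_acc
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
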