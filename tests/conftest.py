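import numpy as np
import pytest

from racpbpk.parameters import (
    DoseEvent, DrugParams, PhysioProfile, daily_oral_regimen, load_config,
    resolve,
)


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def profile(default_config):
    return default_config[0]


@pytest.fixture(scope="session")
def drug(default_config):
    return default_config[1]


@pytest.fixture(scope="session")
def physiology(profile):
    return resolve(profile)


@pytest.fixture(scope="session")
def oral_dose(profile):
    """Single 1 mg/kg oral gavage resolved to μg."""
    return [DoseEvent(0.0, "oral", 1000.0 * profile.body_mass)]


@pytest.fixture(scope="session")
def iv_dose(profile):
    return [DoseEvent(0.0, "iv", 1000.0 * profile.body_mass)]


@pytest.fixture(scope="session")
def regimen_28d(profile):
    return daily_oral_regimen(1.0, profile.body_mass, 28)
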