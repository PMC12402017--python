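import warnings

import numpy as np
import pytest

from aquadom.experiments import recovery_experiment
from aquadom.io_formats import EEM, standard_grids
from aquadom.synthetic import simulate_campaign


def make_eem(values=1.0, sample_id="S", units="QSU", dilution=1.0, mask=None):
    """EEM on the standard 45 x 301 grid filled with a constant or array."""
    ex, em = standard_grids()
    intensity = np.full((ex.size, em.size), float(values)) if np.isscalar(values) else np.asarray(values, float)
    return EEM(
        sample_id=sample_id, ex_grid=ex, em_grid=em, intensity=intensity,
        units=units, dilution_factor=dilution, mask=mask,
    )


@pytest.fixture
def flat_eem():
    """Uniform positive EEM: every index has a closed-form value."""
    return make_eem(2.0)


@pytest.fixture(scope="session")
def campaign():
    """Default 10-sample synthetic campaign (9 rivers + blank), seed 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_campaign(seed=0)


@pytest.fixture(scope="session")
def recovery():
    """Six-component recovery benchmark at a fixed seed (shared, expensive)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return recovery_experiment(seed=1)
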