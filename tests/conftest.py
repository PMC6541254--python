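import numpy as np
import pytest

from grapemx import CostParameters, two_hectare_plan, mossi_plan
from grapemx.presets import BARBERA, PROFILES
from grapemx.synthetic import simulate_season, synthesize_fluorescence_frame


@pytest.fixture(scope="session")
def costs():
    return CostParameters()


@pytest.fixture(scope="session")
def plans():
    return {
        "2ha-2": two_hectare_plan(2),
        "2ha-3": two_hectare_plan(3),
        "mossi": mossi_plan(6),
    }


@pytest.fixture(scope="session")
def barbera_profile():
    return PROFILES[BARBERA]


@pytest.fixture(scope="session")
def barbera_zero_noise(barbera_profile):
    """Deterministic Barbera season with model-exact fluorescence channels."""
    chem = simulate_season(barbera_profile, n_replicates=3, seed=11,
                           chem_sigma_frac=0.0)
    return synthesize_fluorescence_frame(chem, barbera_profile, seed=12,
                                         channel_sigma=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170921)
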