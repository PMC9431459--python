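import numpy as np
import pandas as pd
import pytest

from crococompete.config import (
    DEFAULT_CRO,
    DEFAULT_ECOSYSTEM_STATE,
    DEFAULT_OTH,
    DEFAULT_ZOO,
)
from crococompete.simulation_engine import NutrientForcing, run_incubation
from crococompete.synthetic_data import GeneratorConfig, generate_experiment


@pytest.fixture(scope="session")
def cro_params():
    return DEFAULT_CRO


@pytest.fixture(scope="session")
def oth_params():
    return DEFAULT_OTH


@pytest.fixture(scope="session")
def zoo_params():
    return DEFAULT_ZOO


@pytest.fixture(scope="session")
def ecosystem_initial():
    return DEFAULT_ECOSYSTEM_STATE


@pytest.fixture(scope="session")
def m3_forcing():
    """Quadratic drawdown resembling a +NH4 bottle: 115 -> ~1 nM over 3 d."""
    return NutrientForcing.quadratic((6.0, -56.0, 115.0), (0.17, -2.0, 5.0))


@pytest.fixture(scope="session")
def cro_observations(cro_params, m3_forcing):
    """Noise-free Cro cellular-N observations at days 0-3 under m3_forcing."""
    days = np.array([0.0, 1.0, 2.0, 3.0])
    traj = run_incubation([cro_params], m3_forcing, [5.0], t_end=3.0, dt=0.01)
    values = np.interp(days, traj.time, traj.pools[cro_params.name])
    return pd.DataFrame({"time_d": days, "n_nmol_l": values})


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment, shared across tests (read-only)."""
    return generate_experiment(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def clean_experiment():
    """Noise-free, sink-free experiment: exactly closed nitrogen budget."""
    cfg = GeneratorConfig(
        seed=11,
        noise_sigma=0.0,
        sink_fraction=0.0,
        bead_noise_sigma=0.0,
        median_fls_sigma=0.0,
    )
    return generate_experiment(cfg)
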