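import pandas as pd
import pytest

from dhscreen.evidence import (
    evidence_from_fixture,
    load_table1_fixture,
    replay_calls,
)
from dhscreen.simulate import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_calls(table1):
    return replay_calls(table1)


@pytest.fixture(scope="session")
def table1_evidence(table1):
    return evidence_from_fixture(table1)


@pytest.fixture(scope="session")
def small_sim():
    """A small default-noise simulated screen shared across tests."""
    return simulate_screen(SimulationConfig(seed=7, n_genes=5, sites_per_locus=3))


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        seed=11,
        n_genes=5,
        sites_per_locus=3,
        peak_signal_sd_log=0.0,
        subdued_noise_sd_log=0.0,
        well_cv=0.0,
        dct_noise_sd=0.0,
    )
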