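from dataclasses import replace

import pytest

from oatkin import (
    CompartmentGeometry,
    SimulationSettings,
    TransportParameters,
    integrate,
    scenario,
)
from oatkin.fitting import CASE1_EP_SETTINGS
from oatkin.synthetic import NoiseModel, generate_uptake_timeseries


@pytest.fixture(scope="session")
def geometry():
    return CompartmentGeometry()


@pytest.fixture(scope="session")
def transport():
    return TransportParameters()


@pytest.fixture(scope="session")
def standard_traj():
    """Standard scenario (25 µM IS, 1 mM albumin) integrated past clearance."""
    return integrate(scenario("standard"), SimulationSettings.for_standard(t_end=24 * 3600.0))


@pytest.fixture(scope="session")
def noiseless_dataset_25():
    """Exact (zero-noise) uptake dataset at 25 µM, generated at the
    default transporter parameters."""
    return generate_uptake_timeseries(
        initial_concs=(25.0,), noise=NoiseModel(cv_or_sd=0.0, seed=0)
    )[0]


@pytest.fixture
def quick_ep():
    """Small EP budget for tests that exercise mechanics, not convergence."""
    return replace(CASE1_EP_SETTINGS, generations=15, seed=11)
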