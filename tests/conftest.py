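import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from nanopbpk import (
    BloodEnvironment,
    CapillaryGeometry,
    NanoparticleSpec,
    SimulationConfig,
    simulate,
)
from nanopbpk.physiology import default_body, default_tumor


@pytest.fixture(scope="session")
def healthy_env() -> BloodEnvironment:
    return BloodEnvironment(viscosity_cP=4.0, hematocrit=0.45, rbc_radius_um=3.6)


@pytest.fixture(scope="session")
def healthy_cap() -> CapillaryGeometry:
    return CapillaryGeometry()


@pytest.fixture(scope="session")
def np_100nm() -> NanoparticleSpec:
    return NanoparticleSpec.from_diameter(100.0)


@pytest.fixture(scope="session")
def reference_tumor_sim(np_100nm):
    """Reference 100 nm tumor-bearing simulation, shared across tests."""
    return simulate(np_100nm, tumor=default_tumor())


@pytest.fixture(scope="session")
def reference_body():
    return default_body()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
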