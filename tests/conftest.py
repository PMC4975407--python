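import numpy as np
import pytest

from ratebif.params import NetworkParams, PopulationParams, table1_params


@pytest.fixture(scope="session")
def weak():
    """Benchmark network in the weak-inhibition regime (psi < 1)."""
    return table1_params(J_II=-10.0)


@pytest.fixture(scope="session")
def strong():
    """Benchmark network in the strong-inhibition regime (psi >= 1)."""
    return table1_params(J_II=-100.0)


@pytest.fixture(scope="session")
def strong34():
    return table1_params(J_II=-34.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_params(rng, N_E=None, N_I=None) -> NetworkParams:
    """A random valid parameter set for property tests."""
    N_E = int(N_E if N_E is not None else rng.integers(2, 7))
    N_I = int(N_I if N_I is not None else rng.integers(2, 7))
    E = PopulationParams(size=N_E, tau=float(rng.uniform(0.5, 2.0)),
                         nu_max=float(rng.uniform(0.5, 2.0)),
                         Lambda=float(rng.uniform(0.5, 4.0)),
                         V_T=float(rng.uniform(-1.0, 3.0)))
    I = PopulationParams(size=N_I, tau=float(rng.uniform(0.5, 2.0)),
                         nu_max=float(rng.uniform(0.5, 2.0)),
                         Lambda=float(rng.uniform(0.5, 4.0)),
                         V_T=float(rng.uniform(-1.0, 3.0)))
    return NetworkParams(
        E=E, I=I,
        J_EE=float(rng.uniform(0.1, 30.0)),
        J_EI=float(-rng.uniform(0.1, 100.0)),
        J_IE=float(rng.uniform(0.1, 100.0)),
        J_II=float(-rng.uniform(0.0, 120.0)),
        I_E=float(rng.uniform(-20, 20)),
        I_I=float(rng.uniform(-20, 20)),
    )
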