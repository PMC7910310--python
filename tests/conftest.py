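import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cdcpol.model_core import ModelParams
from cdcpol.surface_sim import build_icosphere


@pytest.fixture(scope="session")
def classic_params():
    """Classic-regime kinetics of the single-pole reference run (d=10, gamma=25)."""
    return ModelParams(c1=0.05, c_minus1=0.02, c2=0.45, c_max=3.0, V0=6.0,
                       gamma=25.0, d=10.0)


@pytest.fixture(scope="session")
def classic_params_alt():
    """Second classic kinetic set (c_minus1=0.04), used for the d/gamma sweeps."""
    return ModelParams(c1=0.05, c_minus1=0.04, c2=0.45, c_max=3.0, V0=6.0,
                       gamma=25.0, d=10.0)


@pytest.fixture(scope="session")
def nonclassic_params():
    """Non-classic regime kinetics (saddle of the inhomogeneous reaction matrix)."""
    return ModelParams(c1=0.05, c_minus1=0.01, c2=0.20, c_max=3.0, V0=6.0,
                       gamma=25.0, d=10.0)


@pytest.fixture(scope="session")
def nonclassic_params_alt():
    """Second non-classic set (c_minus1=0.03, c2=0.15) from the d-sweep runs."""
    return ModelParams(c1=0.05, c_minus1=0.03, c2=0.15, c_max=3.0, V0=6.0,
                       gamma=25.0, d=10.0)


@pytest.fixture(scope="session")
def mesh_l2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def mesh_l3():
    return build_icosphere(3)


@pytest.fixture(scope="session")
def mesh_l4():
    return build_icosphere(4)


def random_positive_params(rng: np.random.Generator) -> ModelParams:
    """Log-uniform draw of a positive kinetic parameter set."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ModelParams(
        c1=lu(1e-3, 1.0),
        c_minus1=lu(1e-3, 1.0),
        c2=lu(1e-2, 10.0),
        c_max=lu(0.5, 10.0),
        V0=lu(0.5, 20.0),
        gamma=lu(1.0, 100.0),
        d=lu(1.0, 50.0),
    )
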