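import numpy as np
import pytest

from crisprqsp.biodistribution import load_parameters
from crisprqsp.pd_response import load_pd_parameters
from crisprqsp.physiology import load_physiology

SPECIES = ("mouse", "nhp", "human")

# loose-but-adequate solver settings for tests that integrate the full model
LOOSE = {"rtol": 1e-6, "atol": 1e-9}


@pytest.fixture(scope="session", params=SPECIES)
def species(request):
    return request.param


@pytest.fixture(scope="session")
def phys(species):
    return load_physiology(species)


@pytest.fixture(scope="session")
def params(species):
    return load_parameters(species)


@pytest.fixture(scope="session")
def phys_nhp():
    return load_physiology("nhp")


@pytest.fixture(scope="session")
def params_nhp():
    return load_parameters("nhp")


@pytest.fixture(scope="session")
def phys_mouse():
    return load_physiology("mouse")


@pytest.fixture(scope="session")
def params_mouse():
    return load_parameters("mouse")


@pytest.fixture(scope="session")
def phys_human():
    return load_physiology("human")


@pytest.fixture(scope="session")
def params_human():
    return load_parameters("human")


@pytest.fixture(scope="session")
def ttr_nhp():
    return load_pd_parameters("nhp", "ttr")


@pytest.fixture(scope="session")
def ttr_human():
    return load_pd_parameters("human", "ttr")


def closed_params(params, **extra):
    """Parameter set with every loss/creation pathway switched off (closed system)."""
    updates = dict(
        k_deg_LNP=0.0,
        k_deg_sgRNA=0.0,
        k_deg_mRNA=0.0,
        k_deg_Cas=0.0,
        k_deg_DR=0.0,
        k_release=0.0,
        k_trans=0.0,
    )
    updates.update(extra)
    return params.replace(**updates)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
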