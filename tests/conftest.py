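import random

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from entrofold.params import load_parameters, zero_energy_like

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def turner():
    """Turner 2004 tables, plain Vienna-d0 conventions."""
    return load_parameters("turner2004")


@pytest.fixture(scope="session")
def classic():
    """Turner 2004 tables with the classic evaluation profile (default)."""
    return load_parameters("turner2004-classic")


@pytest.fixture(scope="session")
def nussinov():
    """Toy model: every base pair -1 kcal/mol, no loop terms."""
    return load_parameters("nussinov")


@pytest.fixture(scope="session")
def zero_params(nussinov):
    """Every structure has energy exactly zero."""
    return zero_energy_like(nussinov)


def random_rna_str(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


@pytest.fixture
def pyrng():
    return random.Random(20240917)


@pytest.fixture
def nprng():
    return np.random.default_rng(20240917)
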