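import numpy as np
import pytest

from cellentropy import GridSpec, SeriesControl, builtin_cases


@pytest.fixture(scope="session")
def cases():
    return builtin_cases()


@pytest.fixture(scope="session")
def normal(cases):
    return cases["normal"]


@pytest.fixture(scope="session")
def cancer(cases):
    return cases["cancer"]


@pytest.fixture(scope="session")
def ctrl():
    return SeriesControl(n_terms=200)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse lattice for fast structural tests."""
    return GridSpec(nx=41, nt=30)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170822)
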