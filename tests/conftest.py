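import pytest

from gltkin import build_canonical_scheme, derive_rate_law
from gltkin.data import load_table1
from gltkin.synthetic_data import DEFAULT_RATE_CONSTANTS

CANONICAL_SYMBOLS = ("k1", "k-1", "k2", "k-2", "k3", "k-3", "k4", "k-4", "kcat")


@pytest.fixture(scope="session")
def canonical_scheme():
    return build_canonical_scheme()


@pytest.fixture(scope="session")
def canonical_law(canonical_scheme):
    return derive_rate_law(canonical_scheme)


@pytest.fixture(scope="session")
def unit_constants():
    return {s: 1.0 for s in CANONICAL_SYMBOLS}


@pytest.fixture(scope="session")
def default_constants():
    return dict(DEFAULT_RATE_CONSTANTS)


@pytest.fixture(scope="session")
def table1():
    return load_table1()
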