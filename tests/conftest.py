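import warnings

import pytest
from hypothesis import HealthCheck, settings

import mabckit as mk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gmap():
    return mk.brassica_rapa_map()


@pytest.fixture(scope="session")
def parents(gmap):
    """Small-scale simulated parents shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec, don, variants = mk.make_parents(
            gmap, snp_density=10.0, indel_density=10.0, seed=12345
        )
    return rec, don, variants


@pytest.fixture(scope="session")
def f1(gmap, parents):
    rec, don, _ = parents
    return mk.cross(don, rec, 1, gmap, seed=7, generation="F1").members[0]
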