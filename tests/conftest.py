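import pytest
from hypothesis import settings

from apa.task_schedule import build_default_catalog, enumerate_pairs, make_schedule

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def catalog():
    return build_default_catalog()


@pytest.fixture(scope="session")
def pairs(catalog):
    return enumerate_pairs(catalog)


@pytest.fixture(scope="session")
def schedule(pairs, catalog):
    return make_schedule(pairs, n_blocks=4, seed=7, catalog=catalog)
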