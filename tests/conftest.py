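import numpy as np
import pytest

from cryoswim import fixtures, qscore, swim


@pytest.fixture(scope="session")
def map_fixture():
    """Default synthetic map fixture: 6-bp duplex, 5 waters + 1 Mg2+,
    SNR 10, full occupancy."""
    return fixtures.make_maps()


@pytest.fixture(scope="session")
def q_by_res(map_fixture):
    return qscore.q_by_residue_dict(map_fixture.full, map_fixture.model)


@pytest.fixture(scope="session")
def swim_result(map_fixture, q_by_res):
    fx = map_fixture
    return swim.run_swim(fx.full, fx.half1, fx.half2, fx.model, q_by_res)


@pytest.fixture(scope="session")
def small_rna():
    return fixtures.make_rna(4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
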