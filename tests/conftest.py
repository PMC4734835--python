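import pytest

from gemkit import FixtureSpec, make_fixture


@pytest.fixture
def chain():
    return make_fixture("chain")


@pytest.fixture
def blocked():
    return make_fixture("blocked")


@pytest.fixture
def loop():
    return make_fixture("loop")


@pytest.fixture
def branched():
    return make_fixture("branched")


@pytest.fixture
def glucose_pair():
    return make_fixture("glucose_pair")


@pytest.fixture
def uro_pair():
    return make_fixture("uro_pair")


def random_models(count, start=0, **params):
    for seed in range(start, start + count):
        yield make_fixture(FixtureSpec("random", seed=seed, **params))
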