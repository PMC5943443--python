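import random

import pytest

from taxatables import FixtureSpec, easplist_mini, generate_fixture


@pytest.fixture
def mini():
    """The three-concept sedge miniature (family > genus > papyrus)."""
    return easplist_mini()


@pytest.fixture
def random_list():
    """One deterministic mid-size random checklist."""
    return generate_fixture(FixtureSpec(seed=7))


@pytest.fixture
def rng():
    return random.Random(2026)


def make_fixture(seed: int, **overrides):
    return generate_fixture(FixtureSpec(seed=seed, **overrides))
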