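import numpy as np
import pytest

from ploidysim import SimParams, build_fixture_genome

TRIPLOID_SPEC = "1100101;1100101;0011010"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triploid():
    """The worked-example triploid: two identical chromosomes plus one
    complementary chromosome; viable (F=1) but with segregation load."""
    return build_fixture_genome(TRIPLOID_SPEC)


@pytest.fixture
def small_params():
    """Small population with the default rate constants."""
    return SimParams(n=100, g=20, max_generations=20, seed=7)


def random_cell(rng, p, g):
    from ploidysim import Cell

    return Cell(rng.random((p, g)))
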