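import numpy as np
import pytest

from kintag import (
    InitSpec,
    ModelParams,
    PopulationState,
    ResistHistory,
    build_space,
)
from kintag.genotype_core import AX_RESIST, allele_frequencies


@pytest.fixture
def small_space():
    """3 Resist x 2 Neutral tags: 24 genotypes, cheap enough for brute force."""
    return build_space(3, 2)


@pytest.fixture
def small_params():
    return ModelParams(L_resist=3, L_neutral=2, L_max=3)


@pytest.fixture
def default_space():
    return build_space(10, 10)


@pytest.fixture
def default_params():
    return ModelParams()


def random_state(space, seed, generation=0):
    rng = np.random.default_rng(seed)
    return PopulationState(rng.dirichlet(np.ones(space.size)), generation)


def history_for(state, space, lag):
    return ResistHistory(allele_frequencies(state.freqs, space, AX_RESIST), lag)


@pytest.fixture
def seeded_states(small_space):
    return [random_state(small_space, s) for s in range(5)]
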