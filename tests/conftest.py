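import numpy as np
import pandas as pd
import pytest

import loopchron as lc
from loopchron.census import CharacterMatrix


@pytest.fixture(scope="session")
def preset_data():
    """Census + planted truth at the desk-scale defaults (seed 1)."""
    return lc.simulate_accretion()


@pytest.fixture(scope="session")
def small_accretion():
    """A fast 12-family / 12-proteome dataset for pipeline-level tests."""
    params = lc.AccretionParams(n_families=12, group_sizes={g: 3 for g in "ABEV"}, seed=7)
    return lc.simulate_accretion(params)


def random_character_matrix(rng, n_leaves, n_chars=3, n_states=24):
    states = rng.integers(0, n_states, size=(n_leaves, n_chars))
    df = pd.DataFrame(states, index=[f"t{i}" for i in range(n_leaves)])
    return CharacterMatrix(df, n_states)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
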