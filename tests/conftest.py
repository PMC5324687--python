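import numpy as np
import pytest

import pupilglm as pg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def exp1_params():
    return pg.canonical_params("exp1")


@pytest.fixture
def time_grid_500hz():
    return np.arange(0, 10, 1 / 500)


@pytest.fixture
def small_paradigm():
    """A short paradigm (one session) keeping simulation tests fast."""
    return pg.ParadigmSpec(n_cspusp=3, n_cspusm=3, n_csm=6, sessions=1)


@pytest.fixture
def unreinforced_paradigm():
    """No CS+US+ trials: the cs_only GLM then matches the generator exactly."""
    return pg.ParadigmSpec(n_cspusp=0, n_cspusm=4, n_csm=8, sessions=1)
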