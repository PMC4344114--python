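import numpy as np
import pytest

from popinfo import (
    MCConfig,
    TuningCurve,
    make_population,
    make_uniform_discrete,
)


@pytest.fixture
def uni_tc():
    return TuningCurve("unimodal", f_bg=10.0, f_mod=40.0, omega=0.1, sigma=0.0)


@pytest.fixture
def mono_tc():
    return TuningCurve("monotonic", f_bg=10.0, f_mod=40.0, omega=0.044, sigma=0.0)


@pytest.fixture
def small_ens():
    """21-point uniform ensemble on [-0.5, 0.5]."""
    return make_uniform_discrete(21, -0.5, 0.5)


@pytest.fixture
def small_pop():
    """Two broad unimodal neurons with small mean counts (enumerable)."""
    template = TuningCurve("unimodal", f_bg=2.0, f_mod=10.0, omega=0.2, sigma=0.0)
    return make_population(2, template, -0.5, 0.5, tau=0.2)


@pytest.fixture
def mc_fast():
    return MCConfig(n_samples=400, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
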