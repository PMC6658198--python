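import numpy as np
import pytest
from hypothesis import settings

import colonysim as cs

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def wt_runs():
    """Three full default wildtype runs (distinct seeds), shared across tests."""
    return [cs.run(cs.default_params().replace(seed=s)) for s in (1, 2, 3)]


@pytest.fixture
def small_params():
    """A quick-to-run parameterization for mechanics-level tests."""
    return cs.default_params().replace(grid_size=41, init_radius=6, n_steps=60)


@pytest.fixture
def single_block_params():
    """One dark block, no diffusion, deterministic switching: the closed-form oracle."""
    return cs.default_params().replace(
        grid_size=9,
        init_radius=0,
        init_light_fraction=0.0,
        diffusion=0.0,
        switch_prob=1.0,
        g_dark=0.0,
        g_light=0.0,
        n_steps=60,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
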