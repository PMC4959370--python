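import numpy as np
import pandas as pd
import pytest

from progmod import SimConfig, fixture_small, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160718)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic cohort: 12 genes (two noise-free 4-gene blocks
    + 4 noise genes), 24 samples."""
    return fixture_small()


@pytest.fixture(scope="session")
def planted_cohort():
    """Moderate cohort with planted high/low blocks for stage tests."""
    cfg = SimConfig(n_samples=250, n_genes=400, seed=11)
    return simulate(cfg)


def random_survival(rng, n, censor_frac=0.3, scale=10.0):
    """Arbitrary right-censored sample for oracle fixtures."""
    t = rng.exponential(scale, n).round(1) + 0.1  # rounding forces ties
    e = (rng.random(n) > censor_frac).astype(int)
    return t, e


@pytest.fixture
def surv_pair(rng):
    def make(n_a=12, n_b=13, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        ta, ea = random_survival(r, n_a)
        tb, eb = random_survival(r, n_b, scale=14.0)
        return ta, ea, tb, eb
    return make
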