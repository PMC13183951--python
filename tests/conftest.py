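import numpy as np
import pytest

from hapnurture.sim import GenerativeParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed pair/trio cohort, small enough for exhaustive per-allele checks."""
    params = GenerativeParams(n_families=250, n_markers=900, n_chromosomes=2, seed=42)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def trio_cohort():
    """All-trio cohort without phase errors (clean transmission ground truth)."""
    params = GenerativeParams(
        n_families=200, n_markers=1200, n_chromosomes=2, fraction_trios=1.0,
        sibling_rate=0.0, seed=7,
    )
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
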