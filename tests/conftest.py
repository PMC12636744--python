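import numpy as np
import pytest

from vaxbiome.synthetic import SimulationSpec, generate_cohort_set


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(n_cohorts=2, n_samples_per_cohort=40, n_taxa=50,
                          n_signal_taxa=6, n_genes=30, n_signal_genes=4,
                          seed=3)


@pytest.fixture(scope="session")
def small_cohorts(small_spec):
    return generate_cohort_set(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
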