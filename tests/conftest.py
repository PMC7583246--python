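import numpy as np
import pytest

import ldridge as lr


@pytest.fixture(scope="session")
def focal_freqs():
    """Two-locus haplotype frequencies with implied r² ≈ 0.9797 and both
    alt-allele frequencies 0.29 (coupling-major layout)."""
    return (0.7079, 0.0021, 0.0021, 0.2879)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort with the default causal block + nulls."""
    return lr.sample_cohort(lr.default_config(n=600, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
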