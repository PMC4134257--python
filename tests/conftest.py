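import numpy as np
import pytest

from snpscreen.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact seeded study with one strong causal SNP, used by several
    pipeline-level tests."""
    cfg = SyntheticConfig(n_patients=168, n_snps=60, causal_snps=[(5, 1.2)],
                          seed=1234)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    cfg = SyntheticConfig(n_patients=168, n_snps=60, seed=4321)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(97531)
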