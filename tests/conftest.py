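import numpy as np
import pytest

from momics import preprocess
from momics.synthetic import SyntheticConfig, generate_cohort


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A fast, feasible scaled-down cohort for unit tests."""
    params = dict(
        n_patients=30,
        cohort_sizes=(20, 24, 18),
        triple_overlap=8,
        n_genes=200,
        k_true=3,
        signature_size=30,
        effect_size=2.0,
        noise_sd=1.0,
        n_proteins=120,
        n_metabolites=40,
        survival_medians=(8.0, 40.0, 15.0),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    filtered = preprocess.filter_low_detected(small_cohort.rna)
    return preprocess.normalize(filtered, log_base=2.0, pseudocount=1.0)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
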