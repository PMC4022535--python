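import numpy as np
import pytest

from hbsdt import SamplerConfig, Valence
from hbsdt.simulate import CellTruth, generate_condition, uniform_truth, generate_study


@pytest.fixture(scope="session")
def default_condition():
    """A 20-subject condition dataset from a known truth (seeded)."""
    rng = np.random.default_rng(12345)
    dataset, latents = generate_condition(
        CellTruth(mu_c=0.5, mu_d=2.0, sigma_c=0.4, sigma_d=0.4),
        "melancholic",
        Valence.POSITIVE,
        rng,
        n_subjects=20,
        missing_rate=0.0,
    )
    return dataset, latents


@pytest.fixture(scope="session")
def small_study():
    """A complete 3-group study at reduced size for pipeline tests."""
    truth = uniform_truth(mu_c=0.2, mu_d=2.0, sigma_c=0.3, sigma_d=0.3,
                          n_subjects=8, missing_rate=0.002, seed=7)
    return generate_study(truth)


@pytest.fixture
def fast_sampler():
    return SamplerConfig(n_chains=2, n_iterations=2000, adapt_iterations=1000, seed=0)
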