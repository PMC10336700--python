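import pytest

from bivoi.core_unli import BVNParams
from bivoi.synthetic_trial import SynthConfig, case_study_like, generate


@pytest.fixture(scope="session")
def pooled_case_params() -> BVNParams:
    """The worked-example pooled incremental-NB parameters at wtp=50,000."""
    return BVNParams(mu1=-4734.0, mu2=-2668.0, sigma1=4678.0, sigma2=4645.0, rho=0.50)


@pytest.fixture(scope="session")
def synth_trial():
    """A complete (no-missingness) default-size synthetic trial, fixed seed."""
    return generate(case_study_like(seed=1))


@pytest.fixture(scope="session")
def synth_trial_missing():
    """Default-size synthetic trial with ~7% MCAR missingness, fixed seed."""
    return generate(SynthConfig(seed=2, missing_rate=0.07))


@pytest.fixture(scope="session")
def big_synth_trial():
    """Large synthetic trial (1e5/arm, complete) for parameter recovery."""
    cfg = SynthConfig(n=(100_000, 100_000, 100_000), seed=5, missing_rate=0.0)
    return cfg, generate(cfg)
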