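import numpy as np
import pytest

from pelvisop.synthetic_data import (
    GeneratorConfig,
    generate_cohort,
    template_pelvis,
)


@pytest.fixture(scope="session")
def template():
    """The canonical (unjittered, unit-scale) template landmark set."""
    return template_pelvis()


@pytest.fixture(scope="session")
def jittered_template():
    """An asymmetric, anatomically plausible landmark set."""
    return template_pelvis(seed=7, jitter_sd=2.0)


@pytest.fixture(scope="session")
def big_cohort_b():
    """A large scenario-B cohort for marginal checks (n = 100000)."""
    return generate_cohort(GeneratorConfig(n=100_000, seed=2024, scenario="B"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
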