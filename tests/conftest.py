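import numpy as np
import pytest

from mciprog.synthetic import (GeneratorConfig, cohort_to_frame,
                               generate_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size cohort at the default study conditions."""
    config = GeneratorConfig(seed=42)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort_frame(default_cohort):
    _, cohort = default_cohort
    return cohort_to_frame(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
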