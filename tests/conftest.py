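import numpy as np
import pytest

from dpanet.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """24 patients, 64x64 images — shared by model/evaluation/CLI tests."""
    return generate_cohort(CohortSpec(n_patients=24, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
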