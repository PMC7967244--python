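"""Shared fixtures.

Cohort generation and preprocessing are the slow steps, so anything reused
across test modules is built once per session.
"""

import numpy as np
import pytest

from minet.datasets import build_datasets, tiny_selection_plan
from minet.synthetic import generate_record, tiny_cohort_spec


@pytest.fixture(scope="session")
def tiny_spec():
    return tiny_cohort_spec(seed=5)


@pytest.fixture(scope="session")
def tiny_bundles(tiny_spec):
    """(locating, detection, record manifest) for the tiny smoke cohort."""
    return build_datasets(tiny_spec, tiny_selection_plan(seed=5))


@pytest.fixture(scope="session")
def hc_record(tiny_spec):
    return generate_record("HC", patient_seed=11, beat_seed=3, spec=tiny_spec)


@pytest.fixture(scope="session")
def noiseless_spec():
    return tiny_cohort_spec(seed=5, noise_sd_uv=0.0, wander_amp_uv=0.0)


@pytest.fixture(scope="session")
def hc_record_noiseless(noiseless_spec):
    return generate_record("HC", patient_seed=11, beat_seed=3, spec=noiseless_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
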