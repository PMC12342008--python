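import numpy as np
import pytest

import npfit
from npfit.features import fit_normalizer, summarize


@pytest.fixture(scope="session")
def spec():
    return npfit.default_spec()


@pytest.fixture(scope="session")
def reference(spec):
    return spec.reference_param_vector()


@pytest.fixture(scope="session")
def small_cohort(spec):
    """Six sparse noisy synthetic patients with fixed truth."""
    patients, truth = npfit.generate_cohort(
        6, spec, pop_scale=0.35, biomarker_dropout=0.2, timepoint_dropout=0.2,
        noise_scale_range=(0.05, 0.2), seed=42,
    )
    return patients, truth


@pytest.fixture(scope="session")
def normalizer(spec, small_cohort):
    patients, _ = small_cohort
    return fit_normalizer([summarize(p, spec.biomarker_names) for p in patients])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
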