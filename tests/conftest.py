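"""Shared fixtures: tuned group models and small synthetic cohorts.

Model tuning and cohort generation are session-scoped — every test that
needs a cohort reuses the same seeded objects, keeping the suite fast and
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from leukoftir.preprocess import PreprocessConfig, preprocess_cohort
from leukoftir.synthetic import SyntheticConfig, default_group_models, generate_cohort


@pytest.fixture(scope="session")
def models():
    return default_group_models()


@pytest.fixture(scope="session")
def default_cohort(models):
    """Default study-sized cohort (10+10, 3 replicates, default noise)."""
    cfg = SyntheticConfig(seed=7)
    cohort, truth = generate_cohort(cfg, models)
    return cfg, cohort, truth.set_index("sample_id")


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    cfg, cohort, truth = default_cohort
    return cfg, preprocess_cohort(cohort), truth


@pytest.fixture(scope="session")
def noiseless_cohort(models):
    """Idealised cohort: no noise, no drift, unit thickness, one replicate."""
    cfg = SyntheticConfig(
        seed=3, noise_sd=0.0, baseline_coeffs_sd=0.0, thickness_sd=0.0, replicates=1
    )
    cohort, truth = generate_cohort(cfg, models)
    return cfg, cohort, truth.set_index("sample_id")


@pytest.fixture(scope="session")
def preprocessed_noiseless(noiseless_cohort):
    cfg, cohort, truth = noiseless_cohort
    return cfg, preprocess_cohort(cohort), truth


@pytest.fixture()
def pcfg():
    return PreprocessConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
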