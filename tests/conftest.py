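"""Shared fixtures: small synthetic cohorts and their SOM features.

Cohorts are generated programmatically (no stored fixtures); the
expensive per-user SOM featurization is session-scoped so many tests can
share one featurized cohort.
"""

from __future__ import annotations

import numpy as np
import pytest

from embar.cohort import CohortConfig, generate_cohort
from embar.pipeline import featurize_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40 labeled users at study proportions, clearly separated mixtures."""
    cfg = CohortConfig(n_users=40, records_per_user=(200, 200),
                       separation=1.0, seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """(features, levels) for the small cohort; shared across test modules."""
    X, y, _ids = featurize_cohort(small_cohort, seed=101)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
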