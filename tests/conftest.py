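import numpy as np
import pandas as pd
import pytest

from sehybrid import SyntheticSpec, derive_absorption_labels, generate_cohort

#: fixed classifier configuration used whenever a test needs a model but is
#: not about hyperparameter tuning
HP = {"max_depth": 3, "learning_rate": 0.3, "n_estimators": 100,
      "reg_lambda": 1.0}

#: single-config search space for tests that exercise tune_and_train but
#: do not care about the grid
TINY_SPACE = {"max_depth": [3], "learning_rate": [0.3], "n_estimators": [50],
              "reg_lambda": [1.0]}


def make_cohort(**kw):
    """Generate a cohort plus derived labels; kwargs override SyntheticSpec."""
    defaults = dict(n_samples_per_batch=[150], n_batches=1, n_regions=1,
                    batch_to_region={0: 0}, seed=0)
    defaults.update(kw)
    spec = SyntheticSpec(**defaults)
    table, meta, truth = generate_cohort(spec)
    labels = derive_absorption_labels(meta)
    return table, meta, truth, labels


@pytest.fixture(scope="session")
def single_batch_cohort():
    """One 150-subject batch at the default moderate planted effect."""
    return make_cohort(seed=0)


@pytest.fixture
def tiny_meta():
    return pd.DataFrame(
        {
            "gender": ["Male", "Female", "Male"],
            "age": [30, 36, 65],
            "bmi": [17.0, 20.0, 25.0],
            "probiotics": ["yes", "no", "no"],
            "health_status": ["healthy", "unhealthy", "healthy"],
            "batch": ["B1", "B1", "B1"],
            "region": ["R1", "R1", "R1"],
            "selenium_before": [0.40, 0.40, 0.40],
            "selenium_after": [0.46, 0.44, 0.41],
        },
        index=pd.Index(["A", "B", "C"], name="sample_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
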