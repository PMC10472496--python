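import numpy as np
import pandas as pd
import pytest

from opioidwce import synthetic as synth
from opioidwce.report import cohort_counting_rows


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-process cohort shared by read-only tests."""
    return synth.generate_cohort(synth.GeneratorConfig(n_subjects=200, seed=42))


@pytest.fixture(scope="session")
def small_rows(small_cohort):
    rows, dose = cohort_counting_rows(small_cohort)
    return rows, dose


def random_interval_data(rng, n=60, p=2, max_time=25, tied=True):
    """Random small counting-process dataset for Cox-engine checks."""
    start = np.zeros(n)
    if tied:
        stop = rng.integers(1, max_time, n).astype(float)
    else:
        stop = np.sort(rng.uniform(0.5, max_time, n))
    event = rng.random(n) < 0.55
    if not event.any():
        event[0] = True
    X = rng.standard_normal((n, p))
    return start, stop, event, X


@pytest.fixture
def toy_rows():
    """Three-subject toy data: exits 2, 4, 6; events 1, 1, 0; binary covariate 1, 0, 0."""
    return pd.DataFrame(
        {
            "subject_id": [1, 2, 3],
            "start": [0, 0, 0],
            "stop": [2.0, 4.0, 6.0],
            "event": [1, 1, 0],
            "x": [1.0, 0.0, 0.0],
        }
    )
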