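import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from mirlink.io import CountMatrix, SampleTable, load_fixture, table2_sample_table

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_counts")


@pytest.fixture(scope="session")
def table2_samples():
    return table2_sample_table()


@pytest.fixture
def small_counts():
    """3 features x 4 samples, hand-enterable numbers."""
    frame = pd.DataFrame(
        [[10, 20, 30, 40], [100, 200, 300, 400], [5, 5, 5, 5]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CountMatrix(frame)


@pytest.fixture
def small_samples():
    return SampleTable(
        pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3", "s4"], "condition": ["case", "case", "control", "control"]}
        )
    )


def make_nb_counts(rng, mu, alpha, n_samples, feature_prefix="f", sample_prefix="s"):
    """NB count matrix helper used by calibration tests: mu is per-feature or matrix."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if mu.ndim == 1:
        mu = np.repeat(mu[:, None], n_samples, axis=1)
    lam = rng.gamma(1.0 / alpha, alpha * mu) if alpha > 0 else mu
    counts = rng.poisson(lam)
    frame = pd.DataFrame(
        counts,
        index=[f"{feature_prefix}{i}" for i in range(mu.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(n_samples)],
    )
    return CountMatrix(frame)
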