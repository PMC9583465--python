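import numpy as np
import pandas as pd
import pytest

from oscml import CohortConfig, features_table, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The shipped 72-subject synthetic cohort (25/24/23, 3 replicates)."""
    return simulate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def feature_table(default_cohort):
    """16-feature table + group column for the default cohort (fits included)."""
    return features_table(default_cohort)


@pytest.fixture()
def separable_toy():
    """Tiny dataset where one feature equals the label; others are noise."""
    rng = np.random.default_rng(42)
    y = np.r_[np.zeros(20), np.ones(20)].astype(int)
    X = pd.DataFrame({
        "Ax": y.astype(float),
        "Rt": rng.normal(size=40),
        "Rm": rng.normal(size=40),
    })
    return X, y


@pytest.fixture()
def separable_fuzzy_toy():
    """Fuzzy-dialect analogue: memberships in [0, 1], one carries the label."""
    rng = np.random.default_rng(43)
    y = np.r_[np.zeros(20), np.ones(20)].astype(int)
    X = pd.DataFrame({
        "Ax_low": 1.0 - y.astype(float),
        "Ax_medium": rng.uniform(size=40),
        "Fr_high": rng.uniform(size=40),
    })
    return X, y
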