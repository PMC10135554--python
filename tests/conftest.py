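import numpy as np
import pytest

from wbancardio import data


@pytest.fixture(scope="session")
def cohort():
    """A mid-sized synthetic cohort shared across read-only tests."""
    return data.generate_dataset(data.DatasetSpec(n_records=400, seed=5))


@pytest.fixture(scope="session")
def vitals_xy(cohort):
    X = cohort[list(data.ATTRIBUTES)].to_numpy(float)
    y = cohort["label"].to_numpy(int)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
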