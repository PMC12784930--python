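import numpy as np
import pandas as pd
import pytest

from fowlplan import preprocessing as pp
from fowlplan import synthetic


@pytest.fixture(scope="session")
def full_dataset():
    """Study-scale dataset: 3 breeds x 3 batches x 77 days."""
    cfg = synthetic.SyntheticDatasetConfig(seed=7)
    return synthetic.gen_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Quick dataset: 1 breed x 2 batches x 25 days."""
    cfg = synthetic.SyntheticDatasetConfig(
        n_batches=2,
        n_days=25,
        breeds=("guzao",),
        batch_start_dates=("2024-11-05", "2024-11-12"),
        seed=3,
    )
    return synthetic.gen_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    records, env = small_dataset
    return pp.build_weight_matrix(records, env)


@pytest.fixture(scope="session")
def guzao_matrix(full_dataset):
    records, env = full_dataset
    records = records[records["breed"] == "guzao"].reset_index(drop=True)
    return pp.build_weight_matrix(records, env)


class CumulativeFeedWeightModel:
    """Stub daily-weight model: w_i = w_start + efficiency * cumulative feed."""

    def __init__(self, w_start: float, efficiency: float = 0.3):
        self.w_start = w_start
        self.efficiency = efficiency

    def predict(self, X):
        feed = np.asarray(X["feed_g_per_bird"], dtype=float)
        return self.w_start + self.efficiency * np.cumsum(feed)


class ConcaveFeedWeightModel:
    """Stub with concave terminal response: w_i = w_start + c * sqrt(cumulative feed)."""

    def __init__(self, w_start: float, c: float):
        self.w_start = w_start
        self.c = c

    def predict(self, X):
        feed = np.asarray(X["feed_g_per_bird"], dtype=float)
        return self.w_start + self.c * np.sqrt(np.cumsum(feed))


class ConstantFeedModel:
    """Stub interval total-feed model returning a fixed forecast."""

    def __init__(self, total: float):
        self.total = total

    def predict(self, X):
        return np.full(len(X), self.total)


@pytest.fixture
def stub_models():
    return CumulativeFeedWeightModel, ConcaveFeedWeightModel, ConstantFeedModel
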