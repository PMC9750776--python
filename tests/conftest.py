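import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Tiny mixed-type dataset with known missing entries."""
    from mongoosenet import TabularDataset

    values = np.array([
        [1.0, 2.0, 0.0],
        [3.0, np.nan, 1.0],
        [5.0, 6.0, np.nan],
        [7.0, 8.0, 1.0],
    ])
    return TabularDataset(
        values=values,
        attribute_types=["numeric", "numeric", "categorical"],
        labels=np.array([0, 1, 0, 1]),
        column_names=["a", "b", "c"],
    )
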