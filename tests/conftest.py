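import dataclasses

import numpy as np
import pytest

from hyperspad.indices import default_registry
from hyperspad.preprocess import resample_table
from hyperspad.spectral_io import SensorModel
from hyperspad.synth_field import (
    FieldLayout,
    LeafSpectrumModel,
    default_campaigns,
    simulate_samples,
)


@pytest.fixture(scope="session")
def sensor():
    return SensorModel()


@pytest.fixture(scope="session")
def registry(sensor):
    return default_registry(sensor)


@pytest.fixture(scope="session")
def campaigns():
    return default_campaigns()


@pytest.fixture(scope="session")
def leaf_model():
    return LeafSpectrumModel()


@pytest.fixture(scope="session")
def small_campaigns():
    """Down-sized campaigns (n=25 each) that keep model-fitting tests fast."""
    return [dataclasses.replace(c, n_samples=25) for c in default_campaigns()]


@pytest.fixture(scope="session")
def small_table(small_campaigns):
    return simulate_samples(small_campaigns, seed=42)


@pytest.fixture(scope="session")
def small_table_272(small_table, sensor):
    return resample_table(small_table, sensor)


@pytest.fixture(scope="session")
def mini_layout():
    return FieldLayout(n_rows=4, n_cols=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
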