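import numpy as np
import pandas as pd
import pytest

from gcdose import (
    ArrayTruth,
    GrowthTruth,
    MetabolicTruth,
    StudyDesign,
    generate_dataset,
    generate_microarray_set,
)
from gcdose.datatypes import DoseTimeSeries


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default study conditions with measurement noise switched off."""
    design = StudyDesign(seed=7)
    growth = GrowthTruth(noise_cv=0.0)
    metab = MetabolicTruth(noise_cv=0.0)
    return generate_dataset(design, growth, metab)


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(StudyDesign(seed=7))


@pytest.fixture(scope="session")
def noiseless_arrays():
    truth = ArrayTruth(spot_noise_sd=0.0)
    return generate_microarray_set(truth=truth, seed=3)


@pytest.fixture(scope="session")
def noisy_arrays():
    return generate_microarray_set(seed=11)


def make_series(values, times, doses=(0.0,), name="x", unit="u"):
    df = pd.DataFrame(np.atleast_2d(values), index=list(doses), columns=list(times))
    return DoseTimeSeries(name, unit, df)


@pytest.fixture
def series_factory():
    return make_series
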