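import numpy as np
import pytest

from mixproc import ModelSpec, fit_response, load_study_dataset
from mixproc.dataset import RESPONSES


@pytest.fixture(scope="session")
def dataset():
    return load_study_dataset()


@pytest.fixture(scope="session")
def dataset63(dataset):
    return dataset.drop_replicates()


@pytest.fixture(scope="session")
def spec28():
    return ModelSpec.from_name("multiplicative_deg3")


@pytest.fixture(scope="session")
def spec7():
    return ModelSpec.from_name("scheffe_reduced_cubic")


@pytest.fixture(scope="session")
def fits63(dataset63, spec28):
    """Fits of the 63 distinct design runs (the model-validation fit)."""
    return {r: fit_response(dataset63, spec28, r) for r in RESPONSES}


@pytest.fixture(scope="session")
def fits66(dataset, spec28):
    """Fits of all 66 records including replicates (the package default)."""
    return {r: fit_response(dataset, spec28, r) for r in RESPONSES}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
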