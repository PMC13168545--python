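import numpy as np
import pytest
from hypothesis import settings

from illinear.dataset import DatasetParams, build_dataset, dataset_modes, theoretical_spectrum

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

FIG2 = DatasetParams(nx=3, ny=2, kx=3, ky=1, r=2)
FIG4 = DatasetParams(nx=3, ny=2, kx=1, ky=1, r=2)


@pytest.fixture(scope="session")
def fig2_params():
    return FIG2


@pytest.fixture(scope="session")
def fig4_params():
    return FIG4


@pytest.fixture(scope="session")
def fig2_dataset():
    return build_dataset(FIG2)


@pytest.fixture(scope="session")
def fig2_spectrum():
    return theoretical_spectrum(FIG2)


@pytest.fixture(scope="session")
def fig2_modes(fig2_dataset):
    return dataset_modes(fig2_dataset)


def small_param_sample():
    """A modest, deterministic sample of dataset parameter tuples."""
    return [
        DatasetParams(1, 1, 1, 1, 1),
        DatasetParams(2, 1, 1, 2, 3),
        DatasetParams(2, 2, 3, 1, 1),
        DatasetParams(3, 2, 3, 1, 2),
        DatasetParams(3, 3, 2, 2, 2),
        DatasetParams(3, 1, 1, 4, 4),
        DatasetParams(4, 2, 2, 3, 1),
        DatasetParams(4, 4, 4, 4, 3),
    ]


@pytest.fixture(scope="session")
def param_sample():
    return small_param_sample()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
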