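import numpy as np
import pytest

from fluorounmix import WavelengthGrid, default_library, generate_phantom_dataset


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def library(grid):
    return default_library(grid)


@pytest.fixture(scope="session")
def small_phantom(library):
    """45 vials x 8 pixels: enough structure for metric/pipeline tests."""
    return generate_phantom_dataset(n_per_vial=8, seed=11, library=library)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def float64_engine(monkeypatch):
    """Run the NN engine in float64 so finite-difference checks are sharp."""
    from fluorounmix import nn

    monkeypatch.setattr(nn, "DTYPE", np.float64)
    yield
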