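import numpy as np
import pytest

from gloriaqc import Quantity, Spectrum
from gloriaqc.synthetic import BaseShapeParams, generate_base_spectrum

GRID = np.arange(350.0, 901.0)


def make_spectrum(values, grid=None, quantity=Quantity.RRS) -> Spectrum:
    grid = GRID if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(grid, np.asarray(values, dtype=float), quantity)


@pytest.fixture
def grid():
    return GRID.copy()


@pytest.fixture
def smooth_spectrum() -> Spectrum:
    """A clean, strictly positive peaked reflectance spectrum on 350-900 nm."""
    rng = np.random.default_rng(20230216)
    return generate_base_spectrum(BaseShapeParams(), rng)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
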