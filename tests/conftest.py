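import numpy as np
import pytest

from mealnir import simulate
from mealnir.spectra import ReferenceTable, SpectraSet, WavelengthGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    # 1100-1198 nm, 2 nm step, 50 points
    return WavelengthGrid(1100.0 + 2.0 * np.arange(50))


@pytest.fixture
def random_spectra(rng, small_grid):
    n = 12
    a = 0.2 + 0.05 * rng.standard_normal((n, len(small_grid)))
    return SpectraSet(small_grid, a, tuple(f"S{i}" for i in range(n)))


@pytest.fixture(scope="session")
def case_study():
    """Canonical synthetic fixture: 80 calibration / 40 validation samples."""
    return simulate.make_case_study(seed=20230114)
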