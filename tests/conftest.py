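import numpy as np
import pytest

from phykin.spectra import Band, StateSpectrum
from phykin.synthetic import load_table1, get_entry


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def entry_624(table1):
    return get_entry(table1, "1-624", "PPhiB")


@pytest.fixture(scope="session")
def entry_908(table1):
    return get_entry(table1, "1-908", "PPhiB")


@pytest.fixture
def nm_grid():
    """1-nm measurement-style grid over the red/far-red window."""
    return np.arange(630.0, 851.0, 1.0)


@pytest.fixture
def pr_pfr_states(nm_grid):
    """Synthetic Pr/Pfr single-Q-band states on a shared 1-nm grid."""
    pr = StateSpectrum("Pr", (Band(664.0, 28.0, 0.4),), nm_grid)
    pfr = StateSpectrum("Pfr", (Band(724.0, 28.0, 0.24),), nm_grid)
    return pr, pfr


def brute_force_extrema(bands, lo=600.0, hi=880.0, step=0.01):
    """Dense-grid oracle for extrema of a sum of Gaussian bands."""
    x = np.arange(lo, hi + step / 2, step)
    y = np.zeros_like(x)
    for b in bands:
        y += b.amplitude * np.exp(-((x - b.center) ** 2) / (2 * b.width**2))
    maxima, minima = [], []
    interior = slice(1, -1)
    is_max = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    is_min = (y[1:-1] < y[:-2]) & (y[1:-1] < y[2:])
    return list(x[interior][is_max]), list(x[interior][is_min])
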