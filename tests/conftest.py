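import numpy as np
import pytest

from hemestar import synthetic as synth


@pytest.fixture(scope="session")
def default_basis():
    """Default unit-area basis pair (Soret 417 nm vs 402 nm)."""
    return synth.make_basis_spectra()


@pytest.fixture
def gaussian_spectrum():
    """A single Gaussian absorption band with known analytic form."""
    grid = np.arange(300.0, 701.0, 1.0)
    center, sigma = 450.0, 12.0

    def analytic(x):
        return np.exp(-((np.asarray(x) - center) ** 2) / (2 * sigma**2))

    from hemestar.spectra import AbsorbanceSpectrum

    return AbsorbanceSpectrum(grid, analytic(grid), label="gaussian"), analytic, sigma
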