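import numpy as np
import pytest

from vitispec import io, simulate


@pytest.fixture(scope="session")
def native_lib() -> io.SpectralLibrary:
    """Small library on the native 1 nm grid (expensive to regenerate)."""
    return simulate.generate_library(n=30, seed=7)


@pytest.fixture(scope="session")
def small_lib(native_lib) -> io.SpectralLibrary:
    """Coarse library (factor-50 decimation, L=44) for fast model tests."""
    return io.subsample_wavelengths(native_lib, 50)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
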