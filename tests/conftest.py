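import numpy as np
import pytest

from biovocem.raster import RasterGrid
from biovocem.spectra import SpectralSignature


@pytest.fixture
def flat_signature():
    """Factory for constant-reflectance spectra on a 1 nm grid (350-2500 nm)."""
    def make(level=0.4, lo=350.0, hi=2500.0, **tags):
        w = np.arange(lo, hi + 1.0)
        return SpectralSignature(wavelengths=w,
                                 reflectance=np.full(w.shape, level), **tags)
    return make


@pytest.fixture
def small_grid():
    """Factory for small rasters with a shared georeference."""
    def make(values, nodata=-9999.0):
        return RasterGrid(values=np.asarray(values, dtype=float),
                          origin=(0.0, 3000.0), pixel_size=30.0,
                          nodata=nodata)
    return make
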