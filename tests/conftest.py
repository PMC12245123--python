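import numpy as np
import pytest

from sersquant import simulate
from sersquant.spectra import LabeledSpectrum, Spectrum


@pytest.fixture(scope="session")
def probe():
    return simulate.ProbeResponseModel()


@pytest.fixture(scope="session")
def probe128():
    """Coarse 128-point axis used for desk-scale model training."""
    return simulate.ProbeResponseModel().with_axis(np.linspace(400.0, 1800.0, 128))


@pytest.fixture(scope="session")
def noiseless():
    return simulate.NoiseModel.off()


@pytest.fixture()
def toy_spectrum():
    return Spectrum(np.array([100.0, 200.0, 300.0]), np.array([2.0, 4.0, 8.0]))


@pytest.fixture()
def spectra_table(tmp_path):
    """Tiny canonical spectra table + manifest on disk."""
    table = tmp_path / "spectra.csv"
    manifest = tmp_path / "manifest.csv"
    table.write_text(
        "# comment line\n"
        "wavenumber,s1,s2\n"
        "542,1.0,2.0\n"
        "628,0.5,0.25\n"
        "928,1.0,1.0\n"
    )
    manifest.write_text(
        "id,c_gsh_mM,c_h2o2_uM,tissue_class,grid_x,grid_y\n"
        "s1,10,,WT,0,1\n"
        "s2,,50,,,\n"
    )
    return table, manifest
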