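import numpy as np
import pytest

from specal import synthetic
from specal.spectra_io import SpectraSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_profiles():
    """Four 40-band class profiles on the visible-NIR grid."""
    return synthetic.make_class_profiles(
        n_classes=4, n_bands=40, wavelength_range=(400, 1000), seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_profiles):
    """A small labeled dataset with default scatter and noise."""
    return synthetic.simulate_spectra(small_profiles, n_per_class=12, seed=5)


@pytest.fixture
def tiny_spectra():
    wl = np.array([400.0, 500.0, 600.0, 700.0])
    refl = np.array([[0.1, 0.2, 0.3, 0.4],
                     [0.4, 0.3, 0.2, 0.1],
                     [0.2, 0.2, 0.5, 0.6]])
    return SpectraSet(wavelengths=wl, reflectance=refl,
                      labels=np.array([0, 1, 1]),
                      sample_ids=["a", "b", "c"])
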