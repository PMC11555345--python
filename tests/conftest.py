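import numpy as np
import pytest

from carsense.amide import DEFAULT_BAND_MODEL, amplitude_for_area, gaussian_band


@pytest.fixture(scope="session")
def amide_axis():
    """1 cm^-1 grid covering the amide fit window with margins."""
    return np.arange(1500.0, 1801.0, 1.0)


@pytest.fixture(scope="session")
def band_model():
    return DEFAULT_BAND_MODEL


def make_amide_spectrum(axis, areas, band_model=DEFAULT_BAND_MODEL):
    """Noiseless spectrum from component areas, built from the band model."""
    spec = np.zeros_like(np.asarray(axis, dtype=float))
    for area, (_, c, w) in zip(areas, band_model.components):
        spec += gaussian_band(axis, amplitude_for_area(area, w), c, w)
    return spec


@pytest.fixture(scope="session")
def small_phantom():
    from carsense.synthetic import PhantomLayout, make_phantom

    layout = PhantomLayout(shape=(96, 96), n_control=3, n_senescent=3)
    return make_phantom(layout, seed=7)
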