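import numpy as np
import pytest

from stereomrs.spectra_sim import AcquisitionConfig, default_peaks, ppm_axis


@pytest.fixture(scope="session")
def axis():
    """Default 2,048-point ppm axis."""
    return ppm_axis(AcquisitionConfig())


@pytest.fixture(scope="session")
def standard_peaks():
    """Default metabolite set with gaba_tcr = 0.12, glx_tcr = 0.15."""
    return default_peaks(0.12, 0.15)


@pytest.fixture(scope="session")
def noiseless_difference(axis, standard_peaks):
    """Noiseless ON−OFF difference spectrum of the default peak set."""
    from stereomrs.spectra_sim import render_peak

    diff = np.zeros_like(axis)
    for p in standard_peaks:
        if p.edit_class == "edited":
            diff += render_peak(p, axis)
        elif p.edit_class == "inverted":
            diff += -2.0 * render_peak(p, axis)
    return diff


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
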