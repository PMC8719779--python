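import numpy as np
import pytest

from beadcal.models import psd_closed_form
from beadcal.spectra import SpectrumEstimate

# canonical mid-band calibration conditions used across the suite
FS = 100.0
GAMMA = 1e-5
F_C = 5.0
KAPPA = 2.0 * np.pi * GAMMA * F_C
KT = 4.11


def gamma_sampled_psd(rng, bin_length=512, eta=3.0, gamma=GAMMA, kappa=KAPPA,
                      f_s=FS, kT=KT):
    """A synthetic Welch-like PSD: exact Gamma draws around the theory curve.

    This is the 'correct model' construction: every point is independently
    Gamma(eta, mean = closed-form PSD), which is the sampling distribution
    the likelihood assumes.
    """
    f = np.fft.rfftfreq(bin_length, 1.0 / f_s)[1:]
    y = psd_closed_form(f, gamma, kappa, kT, f_s=f_s)
    values = rng.gamma(shape=eta, scale=y / eta)
    return SpectrumEstimate(kind="psd", abscissa=f, values=values,
                            shape=np.full(f.size, float(eta)), f_s=f_s,
                            n_points_used=2 * bin_length)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
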