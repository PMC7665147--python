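import numpy as np
import pytest

import gaitspec as gs


@pytest.fixture(scope="session")
def ogrid():
    return gs.order_grid()


@pytest.fixture(scope="session")
def fgrid():
    return gs.freq_grid()


@pytest.fixture(scope="session")
def basis(ogrid):
    return gs.build_basis(ogrid)


@pytest.fixture(scope="session")
def Lop(basis):
    return gs.penalty_operator(gs.projection(basis.Q), a=2.0)


@pytest.fixture(scope="session")
def small_cohort(ogrid):
    """Noiseless 8-subject cohort with a known coefficient bump."""
    spec = gs.CohortSpec(
        n_subjects=8,
        beta_true=gs.bump_beta(ogrid, 2.5, 50.0),
        sigma_eps=0.0,
        seed=42,
    )
    return gs.simulate_cohort(spec)


def stft_oracle(window, fs, freqs):
    """Independent brute-force windowed Fourier magnitude.

    Direct complex summation |sum_u vm(u) h(u) e^{-i 2 pi f u / fs}|,
    evaluated frequency by frequency without any FFT.
    """
    window = np.asarray(window, float)
    tau = len(window)
    u = np.arange(tau)
    h = 0.5 * (1.0 - np.cos(2.0 * np.pi * u / (tau - 1)))
    tapered = window * h
    out = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        out[i] = abs(np.sum(tapered * np.exp(-2j * np.pi * f * u / fs)))
    return out
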