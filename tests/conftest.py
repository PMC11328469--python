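"""Shared fixtures and independent closed-form oracles."""

import math

import numpy as np
import pytest

from cylmre import SpringpotParams, WaveAcquisition


def springpot_dispersion_oracle(mu: float, alpha: float, f: float,
                                rho: float = 1000.0, eta: float = 1.0):
    """Analytic power-law dispersion of the spring-pot, in polar form.

    Independent of the package's wavenumber route: |G| = mu^(1-a) (w eta)^a,
    phase a*pi/2, and for a plane damped wave
        c = sqrt(|G|/rho) / cos(a pi/4)
        a_pen = sqrt(|G|/rho) / (2 pi sin(a pi/4)).
    """
    w = 2.0 * math.pi * f
    g_abs = mu ** (1.0 - alpha) * (w * eta) ** alpha
    speed = math.sqrt(g_abs / rho) / math.cos(alpha * math.pi / 4.0)
    if alpha == 0:
        return speed, math.inf
    pen = math.sqrt(g_abs / rho) / (2.0 * math.pi * math.sin(alpha * math.pi / 4.0))
    return speed, pen


@pytest.fixture
def default_acq() -> WaveAcquisition:
    return WaveAcquisition()


@pytest.fixture
def band_acq() -> WaveAcquisition:
    """The retained analysis band: 1300-5300 Hz (11 frequencies)."""
    return WaveAcquisition(frequencies=tuple(float(f) for f in range(1300, 5301, 400)))


@pytest.fixture
def midrange_params() -> SpringpotParams:
    return SpringpotParams(mu=2000.0, alpha=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
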