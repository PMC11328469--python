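"""Synthetic tabletop-MRE wave images of a cylindrical sample.

The forward model is the lowest azimuthal mode of a z-infinite cylinder driven
concentrically from the tube wall: the through-plane displacement field is

    u(r, t) = Re[ A * J0(k r) * exp(i omega t) ]

with complex wavenumber ``k`` from the spring-pot medium.  The scanner encodes
displacement into the MR signal phase through a motion-encoding gain
(radians per metre); phase images at ``n_offsets`` equally spaced time offsets
over one vibration period are wrapped to (-pi, pi] and carry additive Gaussian
phase noise, mimicking the raw data of the physical acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import j0

from .errors import InvalidInputError
from .springpot import (
    SpringpotParams,
    TISSUE_DENSITY,
    springpot_modulus,
    wavenumber_from_modulus,
)

#: Default vibration frequencies, Hz: 500 to 5300 in 400 Hz steps.
DEFAULT_FREQUENCIES = tuple(range(500, 5301, 400))

#: Default motion-encoding gain, rad/m.  With the default 20 um drive
#: amplitude this puts the on-axis phase amplitude at 2 rad, so the decaying
#: inward wave can push the near-wall phase beyond pi and exercise the
#: unwrapper.
DEFAULT_ENCODING_GAIN = 1.0e5

#: Default drive displacement amplitude, m.
DEFAULT_AMPLITUDE = 20.0e-6


@dataclass(frozen=True)
class WaveAcquisition:
    """Geometry and timing of one tabletop-MRE acquisition.

    Defaults follow the 0.5 T tabletop setup: 64 x 64 matrix at 150 um
    in-plane resolution, a 7 mm inner-diameter sample tube, four time offsets
    per vibration period, and drive frequencies 500-5300 Hz in 400 Hz steps.
    """

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    n_offsets: int = 4
    matrix: int = 64
    pixel_size: float = 150.0e-6
    tube_inner_diameter: float = 7.0e-3
    density: float = TISSUE_DENSITY

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) == 0:
            raise InvalidInputError("frequency list must not be empty")
        if any(not (f > 0) for f in freqs):
            raise InvalidInputError("frequencies must be positive")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise InvalidInputError("frequencies must be strictly increasing")
        if self.n_offsets < 3:
            raise InvalidInputError("need at least 3 time offsets per period")
        if self.matrix <= 0 or self.pixel_size <= 0:
            raise InvalidInputError("matrix and pixel_size must be positive")
        if self.tube_inner_diameter / self.pixel_size > self.matrix:
            raise InvalidInputError("tube does not fit inside the field of view")
        if not (self.density > 0):
            raise InvalidInputError("density must be positive")

    @property
    def tube_radius(self) -> float:
        return self.tube_inner_diameter / 2.0

    @property
    def center_px(self) -> tuple[float, float]:
        """Tube axis in pixel coordinates (row, col); image centre by default."""
        c = (self.matrix - 1) / 2.0
        return (c, c)

    def radius_map(self) -> np.ndarray:
        """Distance of each pixel centre from the tube axis, metres."""
        cy, cx = self.center_px
        yy, xx = np.mgrid[0:self.matrix, 0:self.matrix]
        return np.hypot(yy - cy, xx - cx) * self.pixel_size

    def tube_mask(self) -> np.ndarray:
        """Boolean mask of pixels inside the sample tube."""
        return self.radius_map() <= self.tube_radius


@dataclass
class PhaseImageSeries:
    """Wrapped multi-offset phase images for every acquired frequency.

    ``phase[f]`` has shape ``(n_offsets, matrix, matrix)`` with values in
    (-pi, pi].  ``encoding_gain`` is the phase per metre of displacement.
    ``overshoot`` flags frequencies whose noiseless phase excursion exceeded
    pi while wrapping was disabled (the simulated analogue of an acquisition
    lost to amplitude overshoot).
    """

    acquisition: WaveAcquisition
    phase: dict[float, np.ndarray]
    encoding_gain: float
    overshoot: dict[float, bool] = field(default_factory=dict)

    def frequencies(self) -> tuple[float, ...]:
        return tuple(sorted(self.phase))


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values into (-pi, pi]."""
    return -np.mod(-np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) + np.pi


def synthesize_wave_series(
    params: SpringpotParams,
    acq: WaveAcquisition,
    amplitude: float = DEFAULT_AMPLITUDE,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    encoding_gain: float = DEFAULT_ENCODING_GAIN,
    wrap: bool = True,
) -> PhaseImageSeries:
    """Simulate a full multifrequency phase-image series for one sample.

    Parameters
    ----------
    params
        Spring-pot medium of the sample.
    acq
        Acquisition geometry and frequency list.
    amplitude
        On-axis displacement amplitude A, metres.
    noise_sd
        Additive Gaussian phase noise, radians, applied per pixel and offset.
    seed
        Seed or Generator; the series is bit-identical for a fixed seed.
    encoding_gain
        Motion-encoding gain, rad/m.
    wrap
        If True (default), phases are wrapped to (-pi, pi].  If False and the
        noiseless excursion exceeds pi at some frequency, that frequency is
        flagged in ``series.overshoot`` instead (mirroring acquisitions that
        are unusable because the drive amplitude overshot the encoding range).
    """
    if amplitude < 0:
        raise InvalidInputError("amplitude must be >= 0")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    r = acq.radius_map()
    inside = r <= acq.tube_radius
    t_idx = np.arange(acq.n_offsets)
    phase_by_f: dict[float, np.ndarray] = {}
    overshoot: dict[float, bool] = {}

    for f in acq.frequencies:
        G = springpot_modulus(params, f)
        k = wavenumber_from_modulus(G, acq.density, f)
        shape = _j0_complex(k * r)
        shape = np.where(inside, shape, 0.0 + 0.0j)
        # The actuator drives the tube wall, so the prescribed amplitude is
        # the *peak* displacement (at the wall for lossy media, where |J0|
        # is largest); the wave then decays toward the axis.
        peak_shape = np.max(np.abs(shape))
        field_c = amplitude * shape / peak_shape if peak_shape > 0 else shape
        # u(r, t) at the n_offsets phases of one vibration period
        phases_t = 2.0 * np.pi * t_idx / acq.n_offsets
        stack = np.empty((acq.n_offsets, acq.matrix, acq.matrix), dtype=float)
        for i, ph in enumerate(phases_t):
            u = (field_c * np.exp(1j * ph)).real
            stack[i] = encoding_gain * u
        peak = float(np.max(np.abs(stack))) if stack.size else 0.0
        if noise_sd > 0:
            stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
        if wrap:
            stack = wrap_phase(stack)
            overshoot[f] = False
        else:
            overshoot[f] = peak > np.pi
        phase_by_f[f] = stack

    return PhaseImageSeries(
        acquisition=acq,
        phase=phase_by_f,
        encoding_gain=encoding_gain,
        overshoot=overshoot,
    )


def _j0_complex(z: np.ndarray) -> np.ndarray:
    """J0 for complex argument.

    scipy.special.jv supports complex z; j0 is kept for the real fast path.
    """
    z = np.asarray(z)
    if np.isrealobj(z):
        return j0(z).astype(complex)
    from scipy.special import jv

    return jv(0, z.astype(complex))


def snr_noise_sd(params: SpringpotParams, acq: WaveAcquisition,
                 amplitude: float, snr_db: float,
                 encoding_gain: float = DEFAULT_ENCODING_GAIN) -> float:
    """Phase-noise standard deviation giving a target SNR in dB.

    SNR is defined on the encoded phase signal: RMS of the noiseless in-tube
    phase time courses over all frequencies, divided by the noise SD.
    """
    clean = synthesize_wave_series(params, acq, amplitude=amplitude,
                                   noise_sd=0.0, seed=0,
                                   encoding_gain=encoding_gain, wrap=False)
    mask = acq.tube_mask()
    sq_sum = 0.0
    n = 0
    for f, stack in clean.phase.items():
        vals = stack[:, mask]
        sq_sum += float(np.sum(vals**2))
        n += vals.size
    rms = math.sqrt(sq_sum / n)
    return rms / 10.0 ** (snr_db / 20.0)
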