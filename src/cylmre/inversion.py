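"""Inversion of wrapped multi-offset phase images to dispersion data.

Pipeline per frequency: 2D phase unwrapping inside the tube mask, temporal
Fourier transformation to the complex wave image at the drive frequency,
radial averaging around the tube axis, and a least-squares fit of the profile
by A * J0(k r) with complex amplitude A and complex wavenumber k = k' + i k''.
The dispersion proxies follow

    c = omega / k'          (shear wave speed, m/s)
    a = -omega / (2 pi k'') (shear penetration rate, m/s)

and a per-frequency validity rule discards points whose wavelength exceeds
twice the sample diameter — the resolution limit of the cylindrical geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.restoration import unwrap_phase as _sk_unwrap

from .bessel import j0_complex
from .errors import EmptyProfileError, InvalidInputError, UndersampledError
from .simulate import PhaseImageSeries

#: Default grid-search ranges for the Bessel fit, m/s.
DEFAULT_C_RANGE = (0.5, 20.0)
DEFAULT_A_RANGE = (0.1, 20.0)
DEFAULT_GRID = 40

#: Normalized residual above which a fit is flagged as failed.
FIT_RESIDUAL_THRESHOLD = 0.5


@dataclass(frozen=True)
class ComplexWaveImage:
    """Complex displacement field (arbitrary units) at one drive frequency."""

    data: np.ndarray
    frequency: float
    pixel_size: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("wave image contains non-finite values")


@dataclass(frozen=True)
class RadialProfile:
    """Complex displacement averaged in annular bins around the tube axis."""

    r: np.ndarray       # mean pixel radius per bin, m, ascending
    u: np.ndarray       # complex mean displacement per bin
    n_px: np.ndarray    # pixels per bin


@dataclass(frozen=True)
class DispersionPoint:
    """Per-frequency wavenumber and the dispersion proxies c and a."""

    f: float
    k_re: float
    k_im: float
    c: float
    a: float
    valid: bool = True
    reason: str = "none"   # none | wavelength | overshoot | fit-failure


def unwrap_phase(wrapped: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """2D phase unwrapping, optionally restricted to a mask.

    Uses a reliability-sorted unwrapper; the output differs from the input by
    an integer multiple of 2 pi at every pixel.  Pixels outside ``mask`` are
    returned unchanged.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if wrapped.ndim != 2:
        raise InvalidInputError("expected a 2D phase image")
    if mask is not None:
        arr = np.ma.array(wrapped, mask=~np.asarray(mask, dtype=bool))
        out = np.asarray(_sk_unwrap(arr))
        return np.where(mask, out, wrapped)
    return np.asarray(_sk_unwrap(wrapped))


def temporal_harmonic(stack: np.ndarray) -> np.ndarray:
    """First temporal Fourier coefficient of an offset stack, per pixel.

    For a pixel time course x_t = A cos(2 pi t / N + phi0) over N equally
    spaced offsets the result is A * exp(i phi0): modulus = oscillation
    amplitude, argument = temporal phase.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise InvalidInputError("expected stack of shape (n_offsets, ny, nx)")
    n = stack.shape[0]
    if n < 3:
        raise UndersampledError(f"need >= 3 time offsets, got {n}")
    coef = np.fft.fft(stack, axis=0)[1]
    return 2.0 * coef / n


def estimate_center(magnitude: np.ndarray, threshold_frac: float = 0.2,
                    snap: bool = True) -> tuple[float, float]:
    """Tube-axis estimate: centroid of the above-threshold magnitude mask.

    Tolerates samples that are not perfectly centred in the field of view.
    With ``snap`` (default) the centroid is rounded to the nearest
    half-pixel, which lets pixels at equal distance from the axis share a
    radial bin (the sub-pixel centroid of a noisy mask carries no usable
    precision anyway).  Falls back to the image centre for an all-zero image.
    """
    mag = np.abs(np.asarray(magnitude))
    peak = mag.max()
    if peak == 0:
        return ((mag.shape[0] - 1) / 2.0, (mag.shape[1] - 1) / 2.0)
    # magnitude-squared-weighted centroid over the above-threshold support:
    # continuous in the data, so single noisy pixels cannot jerk it around
    # (a plain mask centroid is unstable when attenuation leaves only a thin
    # bright ring at the tube wall)
    w = np.where(mag > threshold_frac * peak, mag**2, 0.0)
    yy, xx = np.mgrid[0:mag.shape[0], 0:mag.shape[1]]
    tot = w.sum()
    cy, cx = float((w * yy).sum() / tot), float((w * xx).sum() / tot)
    if snap:
        cy, cx = round(2.0 * cy) / 2.0, round(2.0 * cx) / 2.0
    return (cy, cx)


def extract_radial_profile(
    img: ComplexWaveImage,
    center: tuple[float, float],
    tube_radius: float,
    bin_width: float | None = None,
) -> RadialProfile:
    """Average the complex field in annular bins around ``center``.

    ``center`` is in pixel coordinates (row, col); ``tube_radius`` and
    ``bin_width`` in metres.  With ``bin_width=None`` (default) every
    distinct pixel radius becomes its own bin: for a radially symmetric
    field this averaging is exact and leaves no discretisation bias in the
    subsequent fit, which matters at high frequencies where the wavelength
    approaches the pixel size.  With an explicit ``bin_width``, annular bins
    are used and each bin is assigned the mean pixel radius within it (not
    the geometric bin centre).  Bins beyond the tube radius are discarded.
    """
    if bin_width is None:
        return _exact_radius_profile(img, center, tube_radius)
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be > 0")
    ny, nx = img.data.shape
    cy, cx = center
    if not (0 <= cy <= ny - 1 and 0 <= cx <= nx - 1):
        raise InvalidInputError("center must lie inside the image")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r_px = np.hypot(yy - cy, xx - cx) * img.pixel_size
    inside = r_px <= tube_radius
    if not inside.any():
        raise EmptyProfileError("no pixels inside the tube radius")
    idx = np.floor(r_px[inside] / bin_width).astype(int)
    vals = img.data[inside]
    radii = r_px[inside]
    nbins = idx.max() + 1
    counts = np.bincount(idx, minlength=nbins)
    u_sum = np.bincount(idx, weights=vals.real, minlength=nbins) + 1j * np.bincount(
        idx, weights=vals.imag, minlength=nbins
    )
    r_sum = np.bincount(idx, weights=radii, minlength=nbins)
    nonempty = counts > 0
    return RadialProfile(
        r=r_sum[nonempty] / counts[nonempty],
        u=u_sum[nonempty] / counts[nonempty],
        n_px=counts[nonempty],
    )


def _exact_radius_profile(img: ComplexWaveImage, center: tuple[float, float],
                          tube_radius: float) -> RadialProfile:
    ny, nx = img.data.shape
    cy, cx = center
    if not (0 <= cy <= ny - 1 and 0 <= cx <= nx - 1):
        raise InvalidInputError("center must lie inside the image")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r_px = np.hypot(yy - cy, xx - cx) * img.pixel_size
    inside = r_px <= tube_radius
    if not inside.any():
        raise EmptyProfileError("no pixels inside the tube radius")
    radii = np.round(r_px[inside], 12)
    vals = img.data[inside]
    uniq, idx = np.unique(radii, return_inverse=True)
    counts = np.bincount(idx)
    u_sum = (np.bincount(idx, weights=vals.real)
             + 1j * np.bincount(idx, weights=vals.imag))
    return RadialProfile(r=uniq, u=u_sum / counts, n_px=counts)


def _k_from_ca(c: float, a: float, omega: float) -> complex:
    return complex(omega / c, -omega / (2.0 * math.pi * a))


def _bessel_residual(k: complex, r: np.ndarray, u: np.ndarray,
                     w: np.ndarray | None) -> tuple[complex, float]:
    """Closed-form complex amplitude and normalized residual for one trial k."""
    model = j0_complex(k * r)
    if w is None:
        num = np.vdot(model, u)
        den = np.vdot(model, model).real
        ss_u = np.vdot(u, u).real
    else:
        num = np.sum(w * np.conj(model) * u)
        den = np.sum(w * np.abs(model) ** 2)
        ss_u = np.sum(w * np.abs(u) ** 2)
    if den == 0 or ss_u == 0:
        return 0.0 + 0.0j, 1.0
    A = num / den
    resid = np.sum((np.abs(u - A * model) ** 2) if w is None else w * np.abs(u - A * model) ** 2)
    return A, float(resid / ss_u)


def fit_bessel(
    profile: RadialProfile,
    f: float,
    c_range: tuple[float, float] = DEFAULT_C_RANGE,
    a_range: tuple[float, float] = DEFAULT_A_RANGE,
    n_grid: int = DEFAULT_GRID,
    weight_by_npx: bool = False,
) -> tuple[complex, complex, float]:
    """Fit the radial profile by A * J0(k r) over complex A and k.

    The complex amplitude is solved in closed form for each trial wavenumber;
    k is parameterized through (c, a) and found by a log-spaced global grid
    search over ``c_range`` x ``a_range`` followed by a deterministic
    zoom-grid refinement in (log c, log a) down to ~1e-9 relative step.
    Returns (A, k, normalized residual); a residual above
    :data:`FIT_RESIDUAL_THRESHOLD`, a degenerate (flat or empty) profile, or
    non-convergence is signalled by residual = inf and k = 0 (fit failure —
    flagged downstream, never raised).
    """
    if f <= 0:
        raise InvalidInputError("frequency must be > 0")
    r = np.asarray(profile.r, dtype=float)
    u = np.asarray(profile.u, dtype=complex)
    if r.size < 8:
        raise InvalidInputError(f"need >= 8 profile points, got {r.size}")
    w = np.asarray(profile.n_px, dtype=float) if weight_by_npx else None

    ss_u = float(np.vdot(u, u).real)
    var_u = float(np.vdot(u - u.mean(), u - u.mean()).real)
    if ss_u == 0 or var_u / ss_u < 1e-12:
        return 0.0 + 0.0j, 0.0 + 0.0j, math.inf

    omega = 2.0 * math.pi * f
    cs = np.geomspace(*c_range, n_grid)
    as_ = np.geomspace(*a_range, n_grid)
    # vectorized grid search: model matrix for all trial k at once, optimal
    # complex amplitude in closed form per row
    k_grid = (omega / cs)[:, None, None] - 1j * (omega / (2.0 * math.pi * as_))[None, :, None]
    M = j0_complex((k_grid * r[None, None, :]).reshape(-1, r.size))
    wv = np.ones_like(r) if w is None else w
    num = M.conj() @ (wv * u)
    den = np.abs(M) ** 2 @ wv
    ss_w = float(np.sum(wv * np.abs(u) ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        resid_grid = ss_w - np.abs(num) ** 2 / den
    resid_grid = np.where(np.isfinite(resid_grid), resid_grid, np.inf)
    i_best = int(np.argmin(resid_grid))
    c_fit, a_fit = float(cs[i_best // n_grid]), float(as_[i_best % n_grid])

    # deterministic zoom refinement: shrink a log-space window around the
    # best grid cell until the relative step is ~1e-9
    log_step_c = math.log(c_range[1] / c_range[0]) / (n_grid - 1)
    log_step_a = math.log(a_range[1] / a_range[0]) / (n_grid - 1)
    span_c, span_a = log_step_c, log_step_a
    n_local = 9
    for _ in range(14):
        cs_l = np.exp(np.linspace(math.log(c_fit) - span_c,
                                  math.log(c_fit) + span_c, n_local))
        as_l = np.exp(np.linspace(math.log(a_fit) - span_a,
                                  math.log(a_fit) + span_a, n_local))
        k_l = (omega / cs_l)[:, None, None] - 1j * (
            omega / (2.0 * math.pi * as_l))[None, :, None]
        M_l = j0_complex((k_l * r[None, None, :]).reshape(-1, r.size))
        num_l = M_l.conj() @ (wv * u)
        den_l = np.abs(M_l) ** 2 @ wv
        with np.errstate(divide="ignore", invalid="ignore"):
            res_l = ss_w - np.abs(num_l) ** 2 / den_l
        res_l = np.where(np.isfinite(res_l), res_l, np.inf)
        j = int(np.argmin(res_l))
        c_fit, a_fit = float(cs_l[j // n_local]), float(as_l[j % n_local])
        span_c *= 2.0 / (n_local - 1)
        span_a *= 2.0 / (n_local - 1)
        if max(span_c, span_a) < 1e-9:
            break
    k = _k_from_ca(c_fit, a_fit, omega)
    A, resid = _bessel_residual(k, r, u, w)
    if resid > FIT_RESIDUAL_THRESHOLD or not math.isfinite(resid):
        return A, k, math.inf
    return A, k, resid


def dispersion_from_k(k: complex, f: float) -> tuple[float, float]:
    """c = omega/k' and a = -omega/(2 pi k'') for wavenumber k at ``f`` Hz.

    k'' = 0 (lossless medium) gives a = inf.
    """
    if f <= 0:
        raise InvalidInputError("frequency must be > 0")
    if not (k.real > 0):
        raise InvalidInputError(f"wavenumber must have k' > 0, got {k}")
    if k.imag > 0:
        raise InvalidInputError(f"wavenumber must have k'' <= 0, got {k}")
    omega = 2.0 * math.pi * f
    c = omega / k.real
    a = math.inf if k.imag == 0 else -omega / (2.0 * math.pi * k.imag)
    return c, a


def validate_frequency(point: DispersionPoint, tube_diameter: float,
                       overshoot: bool = False) -> DispersionPoint:
    """Apply the wavelength-resolution rule and the overshoot flag.

    A point is excluded when its wavelength lambda = c / f strictly exceeds
    twice the sample diameter ("exceeding" is strict: lambda == 2 d is
    retained), or when the acquisition at that frequency was flagged for
    amplitude overshoot.  Fit failures stay excluded.
    """
    if point.reason == "fit-failure":
        return point
    if overshoot:
        return replace(point, valid=False, reason="overshoot")
    wavelength = point.c / point.f
    if wavelength > 2.0 * tube_diameter:
        return replace(point, valid=False, reason="wavelength")
    return replace(point, valid=True, reason="none")


def invert_series(
    series: PhaseImageSeries,
    c_range: tuple[float, float] = DEFAULT_C_RANGE,
    a_range: tuple[float, float] = DEFAULT_A_RANGE,
    n_grid: int = DEFAULT_GRID,
    bin_width: float | None = None,
    weight_by_npx: bool = False,
) -> list[DispersionPoint]:
    """Full inversion of one phase-image series to per-frequency dispersion.

    Per frequency: unwrap each offset image inside the tube mask, extract the
    temporal harmonic, radially average around the estimated tube axis, fit
    the Bessel profile, convert to (c, a) and apply the validity rules.
    """
    acq = series.acquisition
    mask = acq.tube_mask()
    points: list[DispersionPoint] = []
    for f in series.frequencies():
        stack = series.phase[f]
        unwrapped = np.stack([unwrap_phase(im, mask=mask) for im in stack])
        harm = temporal_harmonic(unwrapped)
        harm = np.where(mask, harm, 0.0 + 0.0j)
        img = ComplexWaveImage(data=harm, frequency=f, pixel_size=acq.pixel_size)
        center = estimate_center(harm)
        try:
            profile = extract_radial_profile(img, center, acq.tube_radius,
                                             bin_width=bin_width)
            _, k, resid = fit_bessel(profile, f, c_range=c_range,
                                     a_range=a_range, n_grid=n_grid,
                                     weight_by_npx=weight_by_npx)
        except EmptyProfileError:
            k, resid = 0.0 + 0.0j, math.inf
        if not math.isfinite(resid) or k.real <= 0:
            points.append(DispersionPoint(f=f, k_re=k.real, k_im=k.imag,
                                          c=math.nan, a=math.nan,
                                          valid=False, reason="fit-failure"))
            continue
        c, a = dispersion_from_k(k, f)
        point = DispersionPoint(f=f, k_re=k.real, k_im=k.imag, c=c, a=a)
        points.append(validate_frequency(point, acq.tube_inner_diameter,
                                         overshoot=series.overshoot.get(f, False)))
    return points
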