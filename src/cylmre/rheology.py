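"""Fit frequency-independent spring-pot parameters to dispersion data.

Each valid frequency provides a complex shear modulus observation
G*_obs(omega) = rho * omega**2 / k**2, with k reconstructed from the
dispersion proxies (k' = omega/c, k'' = -omega/(2 pi a)).  The spring-pot
parameters (mu, alpha) minimize the sum of squared complex-modulus residuals

    sum_omega | G*_obs(omega) - mu**(1-alpha) * (i omega eta)**alpha |**2

with alpha constrained to [0, 1].  Fitting in complex-modulus space uses the
storage and loss components coherently; a curve-space alternative (fitting
c(f) and a(f) separately) is available for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, InvalidInputError
from .inversion import DispersionPoint
from .springpot import ETA_REF, SpringpotParams, TISSUE_DENSITY, springpot_modulus


@dataclass(frozen=True)
class SpringpotFit:
    """Converged spring-pot parameters for one sample."""

    mu: float
    alpha: float
    rss: float
    n_freq_used: int
    converged: bool


def modulus_from_dispersion(c: float, a: float, f: float,
                            density: float = TISSUE_DENSITY) -> complex:
    """Complex shear modulus implied by (c, a) at frequency ``f``.

    Inverts the Helmholtz relation: k = omega/c - i omega/(2 pi a), then
    G* = rho omega**2 / k**2.  ``a = inf`` (lossless) gives a real modulus.
    """
    if c <= 0 or a <= 0:
        raise InvalidInputError("c and a must be positive")
    omega = 2.0 * math.pi * f
    k_im = 0.0 if math.isinf(a) else -omega / (2.0 * math.pi * a)
    k = complex(omega / c, k_im)
    return density * omega**2 / (k * k)


def _alpha_init(freqs: np.ndarray, cs: np.ndarray) -> float:
    """Warm start for alpha from the log-log slope of c(f).

    For the spring-pot, d log c / d log omega = alpha / 2.
    """
    slope = np.polyfit(np.log(freqs), np.log(cs), 1)[0]
    return float(np.clip(2.0 * slope, 0.0, 1.0))


def _mu_init(alpha0: float, G_abs: float, omega: float, eta: float) -> float:
    """Warm start for mu: invert |G*| = mu**(1-alpha) (omega eta)**alpha."""
    if alpha0 >= 0.999:
        return G_abs
    return float((G_abs / (omega * eta) ** alpha0) ** (1.0 / (1.0 - alpha0)))


def fit_springpot(
    points: Sequence[DispersionPoint],
    density: float = TISSUE_DENSITY,
    eta_ref: float = ETA_REF,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1e7), (0.0, 1.0)),
    init: tuple[float, float] | None = None,
) -> SpringpotFit:
    """Fit (mu, alpha) to the valid dispersion points of one sample.

    Only points with ``valid=True`` enter the fit; at least 3 are required.
    The optimizer works in (log mu, alpha) with box bounds; residuals are the
    stacked real and imaginary parts of G*_obs - G*_SP.  ``converged`` is
    False when the optimizer stops at a bound with a non-vanishing gradient
    or fails to converge.
    """
    pts = [p for p in points if p.valid]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 valid frequencies, got {len(pts)}")
    freqs = np.array([p.f for p in pts])
    cs = np.array([p.c for p in pts])
    as_ = np.array([p.a for p in pts])
    G_obs = np.array([modulus_from_dispersion(c, a, f, density)
                      for c, a, f in zip(cs, as_, freqs)])

    if init is None:
        alpha0 = _alpha_init(freqs, cs)
        omega_lo = 2.0 * math.pi * freqs[0]
        mu0 = _mu_init(alpha0, abs(G_obs[0]), omega_lo, eta_ref)
    else:
        mu0, alpha0 = init
    (mu_lo, mu_hi), (al_lo, al_hi) = bounds
    mu0 = float(np.clip(mu0, mu_lo, mu_hi))
    alpha0 = float(np.clip(alpha0, al_lo, al_hi))

    def residuals(x: np.ndarray) -> np.ndarray:
        mu, alpha = math.exp(x[0]), x[1]
        G_mod = np.array([springpot_modulus(
            SpringpotParams(mu=mu, alpha=alpha, eta_ref=eta_ref), f)
            for f in freqs])
        d = G_obs - G_mod
        return np.concatenate([d.real, d.imag])

    res = least_squares(
        residuals,
        x0=[math.log(mu0), alpha0],
        bounds=([math.log(mu_lo), al_lo], [math.log(mu_hi), al_hi]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=500,
    )
    mu_fit, alpha_fit = math.exp(res.x[0]), float(res.x[1])
    rss = float(np.sum(res.fun**2))
    converged = bool(res.success)
    # At an active alpha bound, require the gradient to point outward;
    # otherwise the optimum is interior-infeasible and the fit is not trusted.
    if converged and res.grad is not None:
        at_lo = alpha_fit <= al_lo + 1e-12 and res.grad[1] < -1e-6 * max(rss, 1.0)
        at_hi = alpha_fit >= al_hi - 1e-12 and res.grad[1] > 1e-6 * max(rss, 1.0)
        if at_lo or at_hi:
            converged = False
    return SpringpotFit(mu=mu_fit, alpha=alpha_fit, rss=rss,
                        n_freq_used=len(pts), converged=converged)


def fit_springpot_curvespace(
    points: Sequence[DispersionPoint],
    density: float = TISSUE_DENSITY,
    eta_ref: float = ETA_REF,
) -> SpringpotFit:
    """Alternative fit on the (c(f), a(f)) curves instead of moduli.

    Minimizes relative residuals of c and a jointly; intended as a
    sensitivity check on the modulus-space objective, not the default path.
    """
    from .springpot import springpot_dispersion

    pts = [p for p in points if p.valid and math.isfinite(p.a)]
    if len(pts) < 3:
        raise InsufficientDataError("need >= 3 valid finite frequencies")
    freqs = np.array([p.f for p in pts])
    cs = np.array([p.c for p in pts])
    as_ = np.array([p.a for p in pts])
    alpha0 = _alpha_init(freqs, cs)
    G0 = modulus_from_dispersion(cs[0], as_[0], freqs[0], density)
    mu0 = _mu_init(alpha0, abs(G0), 2.0 * math.pi * freqs[0], eta_ref)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = SpringpotParams(mu=math.exp(x[0]),
                            alpha=float(np.clip(x[1], 0.0, 1.0)),
                            eta_ref=eta_ref)
        model = np.array([springpot_dispersion(p, f, density) for f in freqs])
        return np.concatenate([(model[:, 0] - cs) / cs,
                               (model[:, 1] - as_) / as_])

    res = least_squares(residuals, x0=[math.log(max(mu0, 1.0)), alpha0],
                        bounds=([0.0, 0.0], [math.log(1e7), 1.0]),
                        xtol=1e-14, ftol=1e-14)
    return SpringpotFit(mu=math.exp(res.x[0]), alpha=float(res.x[1]),
                        rss=float(np.sum(res.fun**2)),
                        n_freq_used=len(pts), converged=bool(res.success))


def classify_solid_fluid(fit: SpringpotFit) -> str:
    """Label a converged fit: 'elastic-solid' (alpha < 0.5),
    'viscous-fluid' (alpha > 0.5) or 'boundary' (alpha == 0.5)."""
    if fit.alpha < 0.5:
        return "elastic-solid"
    if fit.alpha > 0.5:
        return "viscous-fluid"
    return "boundary"
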