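"""Spring-pot fractional viscoelastic model and the plane-shear-wave relations.

The spring-pot is a single fractional element interpolating between a spring
(Hookean solid) and a dashpot (Newtonian fluid).  Its complex shear modulus is

    G*(omega) = mu**(1 - alpha) * (1j * omega * eta)**alpha

where ``mu`` (Pa) is the shear modulus, ``alpha`` in [0, 1] the power-law
exponent (0 = pure elastic solid, 1 = pure viscous fluid) and ``eta`` a
reference viscosity that is fixed at 1 Pa*s so that (mu, alpha) are the only
free parameters and mu directly carries the stiffness scale.

For a time-harmonic shear wave in a homogeneous medium of density ``rho`` the
complex wavenumber follows the Helmholtz relation k = omega * sqrt(rho / G*).
The square-root branch is chosen so k' > 0 and k'' < 0 (a wave decaying along
its direction of travel), which makes both dispersion proxies positive:

    c = omega / k'            shear wave speed, m/s       (stiffness proxy)
    a = -omega / (2 pi k'')   shear penetration rate, m/s (inverse-viscosity proxy)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, SingularMediumError

#: Reference viscosity of the spring-pot parameterization, Pa*s.  Fixed by
#: convention so that (mu, alpha) are the two free parameters.
ETA_REF = 1.0

#: Soft-tissue mass density used throughout, kg/m^3.
TISSUE_DENSITY = 1000.0


@dataclass(frozen=True)
class SpringpotParams:
    """Frequency-independent rheology of one sample.

    Parameters
    ----------
    mu : float
        Shear modulus, Pa.  Must be positive.
    alpha : float
        Dimensionless power-law exponent in [0, 1].
    eta_ref : float
        Reference viscosity, Pa*s (fixed convention, default 1.0).
    """

    mu: float
    alpha: float
    eta_ref: float = ETA_REF

    def __post_init__(self) -> None:
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise InvalidInputError(f"mu must be finite and > 0, got {self.mu}")
        if not (0.0 <= self.alpha <= 1.0):
            raise InvalidInputError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (self.eta_ref > 0):
            raise InvalidInputError("eta_ref must be > 0")


def springpot_modulus(params: SpringpotParams, f: float) -> complex:
    """Complex shear modulus G*(omega) of the spring-pot at frequency ``f`` (Hz).

    Evaluated in polar form, |G*| = mu**(1-alpha) * (omega*eta)**alpha and
    arg G* = alpha*pi/2, which is exact for alpha in [0, 1] and avoids the
    branch ambiguity of complex exponentiation.
    """
    f = float(f)
    if not (math.isfinite(f) and f > 0):
        raise InvalidInputError(f"frequency must be finite and > 0, got {f}")
    omega = 2.0 * math.pi * f
    mag = params.mu ** (1.0 - params.alpha) * (omega * params.eta_ref) ** params.alpha
    phase = params.alpha * math.pi / 2.0
    return complex(mag * math.cos(phase), mag * math.sin(phase))


def wavenumber_from_modulus(G: complex, density: float, f: float) -> complex:
    """Complex wavenumber k = k' + i k'' from the Helmholtz relation.

    k = omega * sqrt(density / G), with the square-root branch chosen so that
    k' > 0 and k'' <= 0 (k'' = 0 only for a purely elastic, lossless medium).
    """
    if not (density > 0):
        raise InvalidInputError(f"density must be > 0, got {density}")
    f = float(f)
    if not (math.isfinite(f) and f > 0):
        raise InvalidInputError(f"frequency must be finite and > 0, got {f}")
    G = complex(G)
    if G == 0:
        raise SingularMediumError("zero modulus has no finite wavenumber")
    omega = 2.0 * math.pi * f
    mag = omega * math.sqrt(density / abs(G))
    half_arg = np.angle(G) / 2.0
    # exp(-i arg(G)/2) puts k in the fourth quadrant for arg(G) in (0, pi].
    k = mag * complex(math.cos(half_arg), -math.sin(half_arg))
    if k.real < 0:
        k = -k
    return k


def springpot_dispersion(params: SpringpotParams, f: float,
                         density: float = TISSUE_DENSITY) -> tuple[float, float]:
    """Shear wave speed c and penetration rate a of the spring-pot at ``f`` Hz.

    Convenience composition of :func:`springpot_modulus`,
    :func:`wavenumber_from_modulus` and the dispersion identities
    c = omega/k', a = -omega/(2 pi k'').  For alpha = 0 the medium is
    lossless and a is ``math.inf``.
    """
    G = springpot_modulus(params, f)
    k = wavenumber_from_modulus(G, density, f)
    omega = 2.0 * math.pi * f
    c = omega / k.real
    a = math.inf if k.imag == 0 else -omega / (2.0 * math.pi * k.imag)
    return c, a
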