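"""Homogeneous lossy dispersive medium (model cytosol).

The cytosol surrounding the MTs is treated as a homogeneous single-Debye
dielectric (water-like: eps_s = 78.3, eps_inf = 5.2, tau = 8.27 ps at 25 C)
with an optional ionic conductivity term.  Phasor convention e^{+i omega t}:

    eps(f) = eps_inf + (eps_s - eps_inf) / (1 + i 2 pi f tau) - i sigma / (2 pi f eps0)

so the lossy imaginary part of eps is negative, the principal square root
gives a wavenumber with Im(k) <= 0, and outgoing waves e^{-i k r} decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.constants as const

from . import constants


@dataclass(frozen=True)
class MediumModel:
    """Single-Debye dielectric with conductivity; relative permeability mu_r."""

    eps_static: float = constants.EPS_STATIC
    eps_inf: float = constants.EPS_INF
    tau: float = constants.DEBYE_TAU_S          # s
    conductivity: float = constants.CONDUCTIVITY_S_M  # S/m
    mu_r: float = constants.MU_R

    def __post_init__(self):
        if not (self.eps_static >= self.eps_inf >= 1.0):
            raise ValueError("need eps_static >= eps_inf >= 1")
        if self.tau <= 0:
            raise ValueError("relaxation time must be positive")
        if self.conductivity < 0:
            raise ValueError("conductivity must be non-negative")


def lossless_medium(eps_r: float = 60.0) -> MediumModel:
    """Non-dispersive lossless test medium of permittivity ``eps_r``."""
    return MediumModel(eps_static=eps_r, eps_inf=eps_r, conductivity=0.0)


def medium_at(f: float, medium: MediumModel | None = None
              ) -> tuple[complex, complex, complex]:
    """Complex relative permittivity, wavenumber and impedance at ``f`` [Hz].

    Returns ``(eps_c, k, Z)`` with ``k = (2 pi f / c0) sqrt(mu_r eps_c)``
    (principal branch, Im k <= 0 so that e^{-i k r} decays) and
    ``Z = 2 pi f mu0 mu_r / k``.
    """
    medium = medium or MediumModel()
    if f <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    eps_c = (medium.eps_inf
             + (medium.eps_static - medium.eps_inf) / (1.0 + 1j * omega * medium.tau)
             - 1j * medium.conductivity / (omega * const.epsilon_0))
    k = omega / const.c * np.sqrt(medium.mu_r * eps_c + 0j)
    if k.imag > 0:
        k = -k
    Z = omega * const.mu_0 * medium.mu_r / k
    return complex(eps_c), complex(k), complex(Z)
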