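"""Longitudinal vibration dynamics of the microtubules.

Each MT vibrates in its fundamental longitudinal mode.  The principal
frequency follows a length-extrapolation law

    nu(L) = beta_bc * k1 * l_TH / L + k2

whose coefficients come from molecular-dynamics/normal-mode analysis of
polymerised tubulin: the frequency falls off with MT length and approaches
the additive offset ``k2`` (~0.91 GHz) for very long MTs.  The
boundary-condition factor ``beta`` is 2 for fixed-fixed MTs (half-wavelength
equals the length) and 1 for fixed-free MTs (quarter-wave resonator, free
antinode at the equatorial end).

The mode shape scales each monomer's displacement, the antinode amplitude is
1 nm by default, and the oscillating part of a monomer's dipole moment is the
fraction 1/3.8 of its static moment at that reference amplitude.  Damping is
an amplitude envelope exp(-pi nu t / Q) of a resonator of quality Q.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import constants
from .geometry import BoundaryCondition


class FeedingMode(enum.Enum):
    PULSED = "pulsed"
    RANDOM = "random"


@dataclass(frozen=True)
class FrequencyLaw:
    """Length-to-frequency extrapolation of the fundamental longitudinal mode."""

    k1: float = constants.FREQ_K1_HZ
    k2: float = constants.FREQ_K2_HZ
    lTH: float = constants.HETERODIMER_LENGTH_NM
    bc_factor_fixed: float = constants.BC_FACTOR_FIXED
    bc_factor_free: float = constants.BC_FACTOR_FREE

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0 or self.lTH <= 0:
            raise ValueError("frequency-law coefficients must be positive")

    def bc_factor(self, bc: BoundaryCondition) -> float:
        return (self.bc_factor_fixed if bc is BoundaryCondition.FIXED_FIXED
                else self.bc_factor_free)


@dataclass(frozen=True)
class ExcitationSpec:
    """How the spindle vibrations are fed.

    ``pulsed``: all MTs start in phase (synchronised, e.g. after an external
    pulse).  ``random``: i.i.d. uniform phases (endogenous noise-driven).
    """

    mode: FeedingMode = FeedingMode.PULSED
    antinode_amplitude: float = constants.ANTINODE_AMPLITUDE_NM  # nm
    Q: float = constants.Q_DEFAULT
    damped: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.antinode_amplitude <= 0:
            raise ValueError("antinode amplitude must be positive")
        if self.Q <= 0:
            raise ValueError("quality factor must be positive")


def principal_frequency(length: float | np.ndarray, bc: BoundaryCondition,
                        law: FrequencyLaw | None = None) -> float | np.ndarray:
    """Fundamental longitudinal frequency of an MT of the given length [Hz].

    Strictly decreasing in length; tends to ``k2`` for very long MTs.
    """
    law = law or FrequencyLaw()
    length = np.asarray(length, dtype=float)
    if np.any(length < law.lTH):
        raise ValueError("MT shorter than one heterodimer has no mode")
    nu = law.bc_factor(bc) * law.k1 * law.lTH / length + law.k2
    return float(nu) if nu.ndim == 0 else nu


def mode_shape(xi: float | np.ndarray, length: float,
               bc: BoundaryCondition) -> float | np.ndarray:
    """Dimensionless displacement amplitude of the fundamental mode in [0, 1].

    ``fixed_fixed``: sin(pi xi / L), nodes at both ends, antinode at L/2.
    ``fixed_free``: sin(pi xi / 2L), node at the MTOC end (xi = 0), antinode
    at the free equatorial end (xi = L).
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0) or np.any(xi > length):
        raise ValueError("axial coordinate outside the MT")
    if bc is BoundaryCondition.FIXED_FIXED:
        u = np.sin(np.pi * xi / length)
    else:
        u = np.sin(np.pi * xi / (2.0 * length))
    return float(u) if u.ndim == 0 else u


def assign_frequencies(model, law: FrequencyLaw | None = None) -> None:
    """Fill ``principal_frequency`` of every MT of the model in place."""
    law = law or FrequencyLaw()
    for mt in model.microtubules:
        mt.principal_frequency = principal_frequency(
            mt.length, mt.boundary_condition, law)


def assign_phases(model, excitation: ExcitationSpec) -> np.ndarray:
    """Assign per-MT vibration phases in place and return them [rad].

    Pulsed feeding synchronises all MTs (phase 0); random feeding draws
    i.i.d. uniform phases on [0, 2 pi) from the excitation seed.
    """
    n = len(model.microtubules)
    if excitation.mode is FeedingMode.PULSED:
        phases = np.zeros(n)
    else:
        rng = np.random.default_rng(excitation.seed)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    for mt, phi in zip(model.microtubules, phases):
        mt.phase = float(phi)
    return phases


def damping_envelope(t: float | np.ndarray, nu: float, Q: float,
                     damped: bool = True) -> float | np.ndarray:
    """Amplitude decay exp(-pi nu t / Q) of a resonator of quality Q.

    The undamped case returns 1.  ``t`` must be non-negative.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not damped:
        env = np.ones_like(t)
    else:
        env = np.exp(-np.pi * nu * t / Q)
    return float(env) if env.ndim == 0 else env


def oscillating_amplitudes(mt, excitation: ExcitationSpec) -> np.ndarray:
    """Peak oscillating dipole magnitude of every dipole of one MT [Debye].

    magnitude = p_a * D_monomer * mode_shape(xi) * (A / 1 nm); the direction
    is the dipole's lattice axis and the time factor
    cos(2 pi nu t + phi) * envelope(t) is applied by the field evaluator.
    """
    d = mt.dipoles()
    shape = mode_shape(d.xi, mt.length, mt.boundary_condition)
    scale = excitation.antinode_amplitude / constants.ANTINODE_AMPLITUDE_NM
    return constants.OSC_FRACTION * d.static_D * shape * scale


def oscillating_dipole(mt, dipole_index: int, t: float,
                       excitation: ExcitationSpec) -> np.ndarray:
    """Instantaneous oscillating dipole vector of one monomer [Debye]."""
    if mt.principal_frequency is None:
        raise ValueError("assign principal frequencies first")
    amps = oscillating_amplitudes(mt, excitation)
    env = damping_envelope(t, mt.principal_frequency, excitation.Q,
                           excitation.damped)
    osc = np.cos(2.0 * np.pi * mt.principal_frequency * t + mt.phase)
    d = mt.dipoles()
    return amps[dipole_index] * env * osc * d.axis[dipole_index]
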