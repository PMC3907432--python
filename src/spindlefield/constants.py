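"""Packaged model constants.

All defaults of the coarse-grained spindle model live here as plain module
constants so that every module (and the config layer) draws from a single
source.  Units follow the interface convention of the package: lengths in
nanometres at module boundaries (cell semi-axes are expressed in nm as well),
dipole moments in Debye, frequencies in Hz.
"""

from __future__ import annotations

import scipy.constants as _const

# --- electrical constants of the tubulin monomers -------------------------
DIPOLE_ALPHA_D: float = 369.0  #: static dipole moment of an alpha monomer [D]
DIPOLE_BETA_D: float = 26.0    #: static dipole moment of a beta monomer [D]
OSC_FRACTION: float = 1.0 / 3.8  #: oscillating part of the monomer dipole at 1 nm antinode displacement

#: Debye per e*nm (from CODATA e and the Debye definition, 1 D = 1e-21/c C*m)
DEBYE_PER_E_NM: float = _const.e * 1e-9 / (1e-21 / _const.c)
DEBYE_SI: float = 1e-21 / _const.c  #: one Debye in C*m

# --- microtubule lattice ---------------------------------------------------
N_PROTOFILAMENTS: int = 13
AXIAL_SHIFT_NM: float = 0.92        #: axial shift s between neighbouring protofilaments [nm]
RING_DIAMETER_NM: float = 10.76     #: diameter zeta of the MT ring (dipole circle) [nm]
LEADING_ANGLE_DEG: float = 10.28    #: leading angle Xi of the ring spiral [deg]; metadata only
HETERODIMER_LENGTH_NM: float = 8.0  #: heterodimer length l_TH [nm]
OUTER_WALL_RADIUS_NM: float = 12.5  #: outer wall radius of the MT [nm]; metadata only

# --- cell / spindle geometry ----------------------------------------------
SEMI_MAJOR_NM: float = 5.16e3   #: semi-major axis a of the ellipsoidal cell [nm]
SEMI_MINOR_NM: float = 2.64e3   #: semi-minor axis b [nm]
EQUIV_RADIUS_NM: float = 3.3e3  #: radius R of the volume-equivalent sphere [nm]
MTOC_OFFSET_NM: float = 2.64e3  #: MTOC centre distance c from the origin on the x-axis [nm]
MTOC_DIAMETER_NM: float = 200.0 #: MTOC sphere diameter rho [nm]

N_MT_TOTAL: int = 300
N_ASTRAL_PER_MTOC: int = 50
N_KINETOCHORE_PER_MTOC: int = 50
N_POLAR_PER_MTOC: int = 50

KAPPA_ASTRAL: int = 120          #: equivalent Thomson point count for the astral cap
OMEGA_ASTRAL_SR: float = 2.8212  #: solid angle of the astral cap [sr]
KAPPA_KP: int = 225              #: equivalent Thomson point count for the kinetochore+polar cap
OMEGA_KP_SR: float = 2.9154      #: solid angle of the kinetochore+polar cap [sr]
THOMSON_CHARGE: float = 1.0      #: arbitrary constant m_q of the repulsion energy

EQUATORIAL_SPREAD: float = 0.8   #: kinetochore/polar targets tile a disc of radius spread*b

# --- vibration law ---------------------------------------------------------
FREQ_K1_HZ: float = 2.5304e12    #: extrapolation coefficient k1 [Hz]
FREQ_K2_HZ: float = 9.0966e8     #: extrapolation coefficient k2 [Hz]
BC_FACTOR_FIXED: float = 2.0     #: boundary-condition factor, both ends fixed
BC_FACTOR_FREE: float = 1.0      #: boundary-condition factor, one end free

ANTINODE_AMPLITUDE_NM: float = 1.0
Q_DEFAULT: float = 10.0
Q_RANGE: tuple[float, float] = (0.1, 50.0)

# --- medium (single-Debye water-like cytosol at 25 C) ----------------------
EPS_STATIC: float = 78.3
EPS_INF: float = 5.2
DEBYE_TAU_S: float = 8.27e-12
CONDUCTIVITY_S_M: float = 0.0
MU_R: float = 1.0

# --- evaluation ------------------------------------------------------------
VOXEL_EDGE_NM: float = 8.0     #: default cubic voxel edge for the smallest cell
EXCLUSION_RADIUS_NM: float = 4.0  #: field contributions clamped below this source distance
N_PERIODS_DEFAULT: int = 5
N_SAMPLES_DEFAULT: int = 300
N_REALIZATIONS_DEFAULT: int = 100
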