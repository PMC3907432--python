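"""Spindle geometry: cell ellipsoid, MTOCs, microtubule trajectories and the
dipole lattice.

The mitotic spindle is modelled inside a prolate ellipsoidal cell with two
microtubule organising centres (MTOCs) on the x-axis.  Nucleation directions
are spread on each MTOC sphere by minimising the Coulomb energy of mutually
repelling points (the Thomson problem) and split into an astral cap (facing
the membrane) and a kinetochore/polar cap (facing the equator).  Astral MTs
run straight to the membrane; kinetochore and polar MTs follow planar
quarter-ellipse arcs that end in the equatorial plane.  Each MT centerline is
divided into 8 nm heterodimer sections; every section carries an "MT ring" of
13 alpha/beta dipole pairs arranged on the 13:3 lattice spiral.

All lengths are in nm.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import constants
from .tubulin import MonomerCG, default_monomers

logger = logging.getLogger(__name__)

MTClass = Literal["astral", "kinetochore", "polar"]


class BoundaryCondition(enum.Enum):
    """Longitudinal-mode boundary condition of one MT."""

    FIXED_FIXED = "fixed_fixed"
    FIXED_FREE = "fixed_free"  # free at the equatorial end


class GeometryError(ValueError):
    """A trajectory or placement request is geometrically impossible."""


# ---------------------------------------------------------------------------
# cell and lattice parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """Ellipsoidal cell with two MTOCs on the x-axis.  Lengths in nm."""

    a: float = constants.SEMI_MAJOR_NM        #: semi-major axis
    b: float = constants.SEMI_MINOR_NM        #: semi-minor axis
    R_equiv: float = constants.EQUIV_RADIUS_NM  #: volume-equivalent sphere radius
    c: float = constants.MTOC_OFFSET_NM       #: MTOC centre offset on x
    rho: float = constants.MTOC_DIAMETER_NM   #: MTOC sphere diameter

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError("cell semi-axes must satisfy a >= b > 0")
        if not (0 < self.c < self.a):
            raise ValueError("MTOC offset must lie inside the cell")
        if not self.rho > 0:
            raise ValueError("MTOC diameter must be positive")
        r_vol = (self.a * self.b ** 2) ** (1.0 / 3.0)
        if abs(r_vol - self.R_equiv) > 0.01 * self.R_equiv:
            raise ValueError(
                f"(a*b^2)^(1/3) = {r_vol:.1f} nm is not volume-equivalent to "
                f"R = {self.R_equiv:.1f} nm within 1%")

    def scaled(self, factor: float) -> "CellGeometry":
        """Isotropically scale a, b, c and R (lattice and MTOC size fixed)."""
        return replace(self, a=self.a * factor, b=self.b * factor,
                       c=self.c * factor, R_equiv=self.R_equiv * factor)

    def ellipsoid_excess(self, points: np.ndarray) -> np.ndarray:
        """(x/a)^2 + (y^2+z^2)/b^2 for an (n, 3) array of points."""
        p = np.atleast_2d(points)
        return (p[:, 0] / self.a) ** 2 + (p[:, 1] ** 2 + p[:, 2] ** 2) / self.b ** 2


@dataclass(frozen=True)
class RingSpec:
    """MT ring lattice constants (13:3 B lattice).  Lengths in nm."""

    n_protofilaments: int = constants.N_PROTOFILAMENTS
    axial_shift_s: float = constants.AXIAL_SHIFT_NM
    ring_diameter_zeta: float = constants.RING_DIAMETER_NM
    leading_angle_Xi: float = constants.LEADING_ANGLE_DEG  # metadata only
    heterodimer_length_lTH: float = constants.HETERODIMER_LENGTH_NM
    outer_wall_radius_r: float = constants.OUTER_WALL_RADIUS_NM  # metadata only
    spiral_phase0: float = 0.0           #: azimuth of protofilament j = 0 [rad]
    alpha_toward_minus: bool = True      #: alpha monomer placed toward the MTOC

    def __post_init__(self):
        for name in ("axial_shift_s", "ring_diameter_zeta", "leading_angle_Xi",
                     "heterodimer_length_lTH", "outer_wall_radius_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_protofilaments < 1:
            raise ValueError("need at least one protofilament")


# ---------------------------------------------------------------------------
# Thomson distribution of nucleation centres
# ---------------------------------------------------------------------------

def thomson_energy(points: np.ndarray, m_q: float = constants.THOMSON_CHARGE) -> float:
    """Coulomb energy sum_{i<j} m_q / |x_i - x_j| of unit-sphere points."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(len(points), k=1)
    return float(m_q * (1.0 / d[iu]).sum())


def distribute_nucleation_centers(kappa: int, seed: int | np.random.Generator = 0,
                                  tol: float = 1e-9, max_iter: int = 200_000,
                                  m_q: float = constants.THOMSON_CHARGE) -> np.ndarray:
    """Spread ``kappa`` unit vectors on the sphere by Coulomb-energy descent.

    Projected gradient descent on the Thomson energy with step halving on
    energy increase; converged when the maximum per-iteration point
    displacement falls below ``tol``.  Deterministic for a given seed.

    Returns a ``(kappa, 3)`` array of unit vectors.
    """
    if kappa < 2:
        raise ValueError("need at least two nucleation centres")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.normal(size=(kappa, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)

    def energy_grad(p):
        diff = p[:, None, :] - p[None, :, :]
        d2 = (diff ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        d = np.sqrt(d2)
        e = m_q * (1.0 / d).sum() / 2.0
        g = -m_q * (diff / d[..., None] ** 3).sum(axis=1)
        # project onto the sphere tangent plane (radial part is constrained away)
        g -= (g * p).sum(axis=1, keepdims=True) * p
        return e, g

    e, g = energy_grad(x)
    step = 0.1 / kappa
    x_prev = g_prev = None
    for _ in range(max_iter):
        x_new = x - step * g
        x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
        e_new, g_new = energy_grad(x_new)
        if e_new > e:
            step *= 0.5
            if step < 1e-18:
                break
            continue
        disp = np.max(np.linalg.norm(x_new - x, axis=1))
        x_prev, g_prev, x, e, g = x, g, x_new, e_new, g_new
        # Barzilai-Borwein step guess, guarded by the halving above
        dx = (x - x_prev).ravel()
        dg = (g - g_prev).ravel()
        denom = dx @ dg
        step = dx @ dx / denom if denom > 0 else step * 1.5
        if disp < tol:
            break
    else:
        logger.warning("Thomson descent hit max_iter=%d before tol=%g", max_iter, tol)
    return x


def cap_half_angle(solid_angle: float) -> float:
    """Half-angle theta of a spherical cap of the given solid angle [sr]."""
    return float(np.arccos(np.clip(1.0 - solid_angle / (2.0 * np.pi), -1.0, 1.0)))


def select_cap_centers(centers: np.ndarray, cap_axis: np.ndarray,
                       solid_angle: float, target_count: int) -> np.ndarray:
    """Pick ``target_count`` directions closest in angle to ``cap_axis``.

    The solid angle defines the nominal cap; a warning is logged when the
    number of points strictly inside the nominal cap differs from the target.
    """
    centers = np.asarray(centers, dtype=float)
    if target_count > len(centers):
        raise ValueError("target_count exceeds the number of centres")
    axis = np.asarray(cap_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cosang = np.clip(centers @ axis, -1.0, 1.0)
    order = np.argsort(-cosang, kind="stable")
    theta = cap_half_angle(solid_angle)
    inside = int(np.sum(cosang > np.cos(theta)))
    if inside != target_count:
        logger.warning(
            "nominal cap (Omega=%.4f sr, theta=%.1f deg) holds %d points, "
            "target is %d; taking the %d closest to the cap axis",
            solid_angle, np.degrees(theta), inside, target_count, target_count)
    return centers[order[:target_count]]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

class Trajectory:
    """Arc-length parameterised MT centerline."""

    mt_class: MTClass
    arc_length: float

    def point(self, s: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def tangent(self, s: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def normal_frame(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unit normals (n1, n2) completing the tangent to a right-handed frame."""
        raise NotImplementedError

    def sample(self, n: int = 64) -> np.ndarray:
        """(n, 3) centerline points at equispaced arc length."""
        s = np.linspace(0.0, self.arc_length, n)
        return self.point(s)


def _complete_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stable orthonormal (n1, n2) for an array of unit tangents (n, 3)."""
    t = np.atleast_2d(t)
    ref = np.zeros_like(t)
    smallest = np.argmin(np.abs(t), axis=1)
    ref[np.arange(len(t)), smallest] = 1.0
    n1 = np.cross(ref, t)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(t, n1)
    return n1, n2


class StraightTrajectory(Trajectory):
    """Straight segment from ``start`` to ``end`` (astral MTs)."""

    def __init__(self, start: np.ndarray, end: np.ndarray, mt_class: MTClass = "astral"):
        self.start = np.asarray(start, dtype=float)
        self.end = np.asarray(end, dtype=float)
        self.mt_class = mt_class
        self.arc_length = float(np.linalg.norm(self.end - self.start))
        if self.arc_length <= 0:
            raise GeometryError("zero-length trajectory")
        self._dir = (self.end - self.start) / self.arc_length

    def point(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return self.start + s[:, None] * self._dir

    def tangent(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return np.broadcast_to(self._dir, (len(s), 3)).copy()

    def normal_frame(self, s):
        t = self.tangent(s)
        return _complete_frame(t)


class PlanarEllipseTrajectory(Trajectory):
    """Quarter-ellipse arc of a kinetochore or polar MT.

    The arc lies in the plane spanned by the spindle (x) axis and the
    nucleation azimuth, on the origin-centred ellipse with semi-axes
    ``(x_semi, q_u)``; it runs from the parameter nearest the nucleation
    point to the equatorial plane (x = 0), where it has radius ``q_u``.
    """

    def __init__(self, x_semi: float, q_u: float, azimuth: float,
                 x_sign: float, t0: float, mt_class: MTClass = "kinetochore",
                 n_arc_samples: int = 16385):
        if q_u <= 0:
            raise GeometryError("equatorial radius q_u must be positive")
        if not (0.0 <= t0 < np.pi / 2):
            raise GeometryError("start parameter must precede the equator")
        self.x_semi = float(x_semi)
        self.q_u = float(q_u)
        self.azimuth = float(azimuth)
        self.x_sign = float(np.sign(x_sign) or 1.0)
        self.t0 = float(t0)
        self.mt_class = mt_class
        self._e_r = np.array([0.0, np.cos(self.azimuth), np.sin(self.azimuth)])
        self._e_x = np.array([self.x_sign, 0.0, 0.0])
        # dense arc-length table t -> s, inverted with a monotone spline
        tt = np.linspace(self.t0, np.pi / 2, n_arc_samples)
        speed = np.sqrt(self.x_semi ** 2 * np.sin(tt) ** 2
                        + self.q_u ** 2 * np.cos(tt) ** 2)
        ss = np.concatenate([[0.0], np.cumsum(np.diff(tt) * 0.5 * (speed[1:] + speed[:-1]))])
        self.arc_length = float(ss[-1])
        self._t_of_s = PchipInterpolator(ss, tt, extrapolate=True)

    def _param(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return np.clip(self._t_of_s(s), self.t0, np.pi / 2)

    def point(self, s):
        t = self._param(s)
        return (self.x_semi * np.cos(t))[:, None] * self._e_x \
            + (self.q_u * np.sin(t))[:, None] * self._e_r

    def tangent(self, s):
        t = self._param(s)
        d = (-self.x_semi * np.sin(t))[:, None] * self._e_x \
            + (self.q_u * np.cos(t))[:, None] * self._e_r
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def normal_frame(self, s):
        tangents = self.tangent(s)
        n2 = np.cross(self._e_x, self._e_r)  # plane normal, constant
        n2 = np.broadcast_to(n2 / np.linalg.norm(n2), tangents.shape).copy()
        n1 = np.cross(n2, tangents)
        return n1, n2


def astral_trajectory(mtoc_center: np.ndarray, direction: np.ndarray,
                      cell: CellGeometry) -> StraightTrajectory:
    """Straight astral MT from the MTOC sphere surface to the membrane."""
    mtoc_center = np.asarray(mtoc_center, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    start = mtoc_center + 0.5 * cell.rho * direction
    if cell.ellipsoid_excess(start)[0] > 1.0:
        raise GeometryError("astral MT starts outside the cell")
    # solve (x0 + t dx)^2/a^2 + ((y0 + t dy)^2 + (z0 + t dz)^2)/b^2 = 1
    w = np.array([1.0 / cell.a ** 2, 1.0 / cell.b ** 2, 1.0 / cell.b ** 2])
    A = float(np.sum(w * direction ** 2))
    B = 2.0 * float(np.sum(w * start * direction))
    C = float(np.sum(w * start ** 2)) - 1.0
    disc = B * B - 4 * A * C
    if disc <= 0:
        raise GeometryError("astral ray does not reach the membrane")
    t_hit = (-B + np.sqrt(disc)) / (2 * A)
    if t_hit <= 0:
        raise GeometryError("astral ray does not reach the membrane")
    return StraightTrajectory(start, start + t_hit * direction, mt_class="astral")


def equatorial_magnification(d_u: float, d_max: float, cell: CellGeometry,
                             spread: float = constants.EQUATORIAL_SPREAD,
                             x_u: float | None = None) -> float:
    """Radial equatorial target distance q_u of a kinetochore/polar MT.

    Default rule: nucleation-centre axis distances ``d_u`` on the cap are
    scaled linearly so that the largest one (``d_max``) maps onto a disc of
    radius ``spread * b`` in the equatorial plane.  Monotone in ``d_u``.
    ``x_u`` (the nucleation centre's x-coordinate) is accepted for alternative
    magnification rules but unused by the default.
    """
    if d_u < 0 or d_max <= 0:
        raise ValueError("axis distances must be non-negative, d_max > 0")
    if not (0.0 < spread <= 1.0):
        raise ValueError("spread must lie in (0, 1]")
    return d_u * (spread * cell.b / d_max)


def kp_trajectory(mtoc_center: np.ndarray, nucleation_point: np.ndarray,
                  q_u: float, cell: CellGeometry,
                  mt_class: MTClass = "kinetochore") -> PlanarEllipseTrajectory:
    """Planar quarter-ellipse of a kinetochore/polar MT.

    The arc lies on the origin-centred ellipse with semi-axes
    ``(|mtoc_x|, q_u)`` in the plane of the spindle axis and the nucleation
    azimuth; it starts at the parameter nearest the nucleation point and ends
    in the equatorial plane.
    """
    mtoc_center = np.asarray(mtoc_center, dtype=float)
    p = np.asarray(nucleation_point, dtype=float)
    x_semi = abs(mtoc_center[0])
    x_sign = 1.0 if mtoc_center[0] >= 0 else -1.0
    r_trans = np.hypot(p[1], p[2])
    azimuth = np.arctan2(p[2], p[1]) if r_trans > 0 else 0.0
    # parameter nearest the nucleation point on the (x_semi, q_u) ellipse
    t0 = float(np.arctan2(r_trans / q_u, (p[0] * x_sign) / x_semi))
    t0 = float(np.clip(t0, 0.0, np.pi / 2 * (1 - 1e-12)))
    traj = PlanarEllipseTrajectory(x_semi, q_u, azimuth, x_sign, t0, mt_class)
    start_dist = float(np.linalg.norm(traj.point(0.0)[0] - p))
    if start_dist > 2.0 * cell.rho:
        logger.warning("kp arc starts %.0f nm from its nucleation point "
                       "(> 2 rho = %.0f nm)", start_dist, 2 * cell.rho)
    return traj


# ---------------------------------------------------------------------------
# rings and dipoles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingPoses:
    """Poses of all rings of one MT: arc coords and local frames."""

    s: np.ndarray          # (n,) arc-length coordinates of ring origins
    position: np.ndarray   # (n, 3)
    axis: np.ndarray       # (n, 3) local tangent
    n1: np.ndarray         # (n, 3)
    n2: np.ndarray         # (n, 3)

    def __len__(self) -> int:
        return len(self.s)


def place_rings(trajectory: Trajectory,
                ring_spec: RingSpec | None = None) -> RingPoses:
    """Ring poses at arc-length multiples of the heterodimer length.

    One ring sits at the beginning of each full 8 nm section;
    ``floor(arc_length / l_TH)`` rings in total.  A trajectory shorter than
    one heterodimer yields no rings (logged as a skipped MT).
    """
    spec = ring_spec or RingSpec()
    n = int(np.floor(trajectory.arc_length / spec.heterodimer_length_lTH))
    if n < 1:
        logger.warning("trajectory of %.1f nm is shorter than one heterodimer; "
                       "MT skipped", trajectory.arc_length)
        empty3 = np.zeros((0, 3))
        return RingPoses(np.zeros(0), empty3, empty3.copy(), empty3.copy(), empty3.copy())
    s = np.arange(n, dtype=float) * spec.heterodimer_length_lTH
    pos = trajectory.point(s)
    axis = trajectory.tangent(s)
    n1, n2 = trajectory.normal_frame(s)
    return RingPoses(s, pos, axis, n1, n2)


@dataclass(frozen=True)
class DipoleSet:
    """Dipole placements: positions, common-per-ring axes and lattice data."""

    position: np.ndarray   # (m, 3) nm
    axis: np.ndarray       # (m, 3) unit dipole axis (local MT tangent)
    xi: np.ndarray         # (m,) axial coordinate along the MT [nm]
    is_alpha: np.ndarray   # (m,) bool
    static_D: np.ndarray   # (m,) static dipole magnitude [Debye]
    ring_index: np.ndarray  # (m,) int

    def __len__(self) -> int:
        return len(self.xi)


def ring_dipoles(position: np.ndarray, axis: np.ndarray, n1: np.ndarray,
                 n2: np.ndarray, s_arc: float, ring_spec: RingSpec | None = None,
                 monomers: tuple[MonomerCG, MonomerCG] | None = None,
                 mt_length: float | None = None,
                 ring_index: int = 0) -> DipoleSet:
    """The 26 monomer dipoles of one MT ring.

    13 heterodimer sites sit at azimuths ``phase0 + 2 pi j / 13`` on the
    circle of diameter zeta about the local axis, each shifted axially by
    ``j * s`` (the lattice spiral).  Per site, the alpha and beta monomers are
    offset by -/+ ``l_TH / 4`` along the axis (alpha toward the MTOC by
    default).  Axial coordinates are clamped to the MT extent when a length
    is given, so terminal rings do not protrude past the tip.
    """
    spec = ring_spec or RingSpec()
    alpha, beta = monomers or default_monomers()
    npf = spec.n_protofilaments
    j = np.arange(npf, dtype=float)
    theta = spec.spiral_phase0 + 2.0 * np.pi * j / npf
    radial = 0.5 * spec.ring_diameter_zeta * (
        np.cos(theta)[:, None] * np.asarray(n1, dtype=float)
        + np.sin(theta)[:, None] * np.asarray(n2, dtype=float))
    site_axial = j * spec.axial_shift_s
    quarter = spec.heterodimer_length_lTH / 4.0
    sign_alpha = -1.0 if spec.alpha_toward_minus else 1.0
    ax_alpha = site_axial + sign_alpha * quarter
    ax_beta = site_axial - sign_alpha * quarter

    xi = np.concatenate([s_arc + ax_alpha, s_arc + ax_beta])
    if mt_length is not None:
        xi = np.clip(xi, 0.0, mt_length)
    axial_off = xi - s_arc
    axis = np.asarray(axis, dtype=float)
    pos = (np.asarray(position, dtype=float)
           + axial_off[:, None] * axis
           + np.vstack([radial, radial]))
    m = 2 * npf
    return DipoleSet(
        position=pos,
        axis=np.broadcast_to(axis, (m, 3)).copy(),
        xi=xi,
        is_alpha=np.concatenate([np.ones(npf, bool), np.zeros(npf, bool)]),
        static_D=np.concatenate([
            np.full(npf, alpha.static_dipole_magnitude),
            np.full(npf, beta.static_dipole_magnitude)]),
        ring_index=np.full(m, ring_index, dtype=int),
    )


def _concat_dipoles(sets: Sequence[DipoleSet]) -> DipoleSet:
    return DipoleSet(*[np.concatenate([getattr(d, f) for d in sets])
                       for f in ("position", "axis", "xi", "is_alpha",
                                 "static_D", "ring_index")])


# ---------------------------------------------------------------------------
# microtubule and spindle model
# ---------------------------------------------------------------------------

@dataclass
class Microtubule:
    """One microtubule: centerline, lattice, vibration state."""

    trajectory: Trajectory
    boundary_condition: BoundaryCondition
    ring_spec: RingSpec = field(default_factory=RingSpec)
    monomers: tuple[MonomerCG, MonomerCG] = field(default_factory=default_monomers)
    principal_frequency: float | None = None  # Hz
    phase: float = 0.0                        # rad
    index: int = 0
    _rings: RingPoses | None = field(default=None, repr=False)
    _dipoles: DipoleSet | None = field(default=None, repr=False)

    @property
    def mt_class(self) -> MTClass:
        return self.trajectory.mt_class

    @property
    def length(self) -> float:
        return self.trajectory.arc_length

    @property
    def rings(self) -> RingPoses:
        if self._rings is None:
            self._rings = place_rings(self.trajectory, self.ring_spec)
        return self._rings

    def dipoles(self) -> DipoleSet:
        """All 26 x ring-count dipole placements of this MT (built lazily)."""
        if self._dipoles is None:
            rings = self.rings
            sets = [ring_dipoles(rings.position[k], rings.axis[k], rings.n1[k],
                                 rings.n2[k], float(rings.s[k]), self.ring_spec,
                                 self.monomers, mt_length=self.length,
                                 ring_index=k)
                    for k in range(len(rings))]
            self._dipoles = _concat_dipoles(sets) if sets else DipoleSet(
                np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0),
                np.zeros(0, bool), np.zeros(0), np.zeros(0, int))
        return self._dipoles


@dataclass(frozen=True)
class SpindleParams:
    """Parameters of the spindle builder (geometry block of a run config)."""

    cell: CellGeometry = field(default_factory=CellGeometry)
    ring_spec: RingSpec = field(default_factory=RingSpec)
    n_astral_per_mtoc: int = constants.N_ASTRAL_PER_MTOC
    n_kinetochore_per_mtoc: int = constants.N_KINETOCHORE_PER_MTOC
    n_polar_per_mtoc: int = constants.N_POLAR_PER_MTOC
    kappa_astral: int = constants.KAPPA_ASTRAL
    omega_astral: float = constants.OMEGA_ASTRAL_SR
    kappa_kp: int = constants.KAPPA_KP
    omega_kp: float = constants.OMEGA_KP_SR
    spread: float = constants.EQUATORIAL_SPREAD
    scenario: Literal["fixed", "free"] = "fixed"
    thomson_tol: float = 1e-9

    def scaled(self, factor: float) -> "SpindleParams":
        return replace(self, cell=self.cell.scaled(factor))


@dataclass
class SpindleModel:
    """The full spindle: cell, MTOC poses and all microtubules."""

    cell: CellGeometry
    params: SpindleParams
    mtoc_centers: np.ndarray          # (2, 3)
    microtubules: list[Microtubule]
    seed: int

    @property
    def n_mt(self) -> int:
        return len(self.microtubules)

    def count_by_class(self) -> dict[str, int]:
        counts = {"astral": 0, "kinetochore": 0, "polar": 0}
        for mt in self.microtubules:
            counts[mt.mt_class] += 1
        return counts

    def frequencies(self) -> np.ndarray:
        """Principal frequencies of all MTs [Hz] (must be assigned first)."""
        if any(mt.principal_frequency is None for mt in self.microtubules):
            raise ValueError("principal frequencies have not been assigned")
        return np.array([mt.principal_frequency for mt in self.microtubules],
                        dtype=float)

    def dipole_table(self):
        """All dipoles of the model as a pandas DataFrame."""
        import pandas as pd

        frames = []
        for mt in self.microtubules:
            d = mt.dipoles()
            frames.append(pd.DataFrame({
                "x_nm": d.position[:, 0], "y_nm": d.position[:, 1],
                "z_nm": d.position[:, 2],
                "ax": d.axis[:, 0], "ay": d.axis[:, 1], "az": d.axis[:, 2],
                "xi_nm": d.xi,
                "kind": np.where(d.is_alpha, "alpha", "beta"),
                "static_D": d.static_D,
                "mt": mt.index, "ring": d.ring_index,
            }))
        return pd.concat(frames, ignore_index=True)


def build_spindle(params: SpindleParams | None = None, seed: int = 0,
                  assign_dynamics: bool = True) -> SpindleModel:
    """Construct the full spindle model deterministically from a seed.

    Per MTOC: a Thomson distribution of ``kappa_astral`` points supplies the
    astral nucleation directions (cap facing the membrane) and an independent
    ``kappa_kp``-point distribution supplies the kinetochore/polar directions
    (cap facing the equator).  The kinetochore/polar split alternates along
    the angular ranking, since both classes share the same trajectory rule.
    """
    params = params or SpindleParams()
    cell = params.cell
    root = np.random.SeedSequence(seed)
    children = root.spawn(4)  # (astral, kp) x two MTOCs
    mtoc_centers = np.array([[cell.c, 0.0, 0.0], [-cell.c, 0.0, 0.0]])

    mts: list[Microtubule] = []
    n_kp = params.n_kinetochore_per_mtoc + params.n_polar_per_mtoc
    for i_mtoc, mtoc in enumerate(mtoc_centers):
        pole_axis = np.array([np.sign(mtoc[0]), 0.0, 0.0])
        rng_a = np.random.default_rng(children[2 * i_mtoc])
        rng_kp = np.random.default_rng(children[2 * i_mtoc + 1])

        # astral: cap faces away from the equator
        pts_a = distribute_nucleation_centers(params.kappa_astral, rng_a,
                                              tol=params.thomson_tol)
        dirs_a = select_cap_centers(pts_a, pole_axis, params.omega_astral,
                                    params.n_astral_per_mtoc)
        for d in dirs_a:
            traj = astral_trajectory(mtoc, d, cell)
            mts.append(Microtubule(traj, BoundaryCondition.FIXED_FIXED,
                                   params.ring_spec))

        # kinetochore + polar: cap faces the equator
        pts_kp = distribute_nucleation_centers(params.kappa_kp, rng_kp,
                                               tol=params.thomson_tol)
        dirs_kp = select_cap_centers(pts_kp, -pole_axis, params.omega_kp, n_kp)
        nucleation = mtoc + 0.5 * cell.rho * dirs_kp
        d_u = np.hypot(nucleation[:, 1], nucleation[:, 2])
        d_max = float(d_u.max())
        bc_kp = (BoundaryCondition.FIXED_FREE if params.scenario == "free"
                 else BoundaryCondition.FIXED_FIXED)
        for k, (p, d) in enumerate(zip(nucleation, d_u)):
            q_u = equatorial_magnification(float(d), d_max, cell, params.spread)
            mt_class: MTClass = "kinetochore" if k % 2 == 0 else "polar"
            traj = kp_trajectory(mtoc, p, q_u, cell, mt_class=mt_class)
            mts.append(Microtubule(traj, bc_kp, params.ring_spec))

    for idx, mt in enumerate(mts):
        mt.index = idx

    model = SpindleModel(cell=cell, params=params, mtoc_centers=mtoc_centers,
                         microtubules=mts, seed=seed)
    if assign_dynamics:
        from .dynamics import FrequencyLaw, assign_frequencies
        assign_frequencies(model, FrequencyLaw())
    return model
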