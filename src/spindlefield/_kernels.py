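"""Numerical kernels for the Hertzian-dipole field superposition.

The hot loop (millions of dipoles x thousands of evaluation points) is
written once in plain numpy (reference path, exact) and once as a numba
kernel with an optional near/far split: each MT ring's 26 parallel dipoles
are summed into a single equivalent dipole at their amplitude-weighted
centroid and that aggregate is used for evaluation points farther than
``r_switch`` from the ring; nearby points see the exact 26 dipoles.  The
aggregation error is second order in (ring extent / distance) because the
first-order displacement moments vanish at the weighted centroid.

All kernel inputs are SI (metres, C*m, 1/m); fields come out in V/m.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


def dipole_field_numpy(p: np.ndarray, position: np.ndarray, points: np.ndarray,
                       k: complex, prefactor: complex, r_min: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact Hertzian-dipole phasor field of one dipole at many points.

    ``p``: complex dipole vector [C*m]; ``position``/``points`` in metres;
    ``prefactor`` = 1 / (4 pi eps0 eps_c).  Points closer than ``r_min`` are
    clamped to ``r_min`` (flagged in the returned boolean mask).

    Returns ``(E (n, 3) complex [V/m], clamped (n,) bool)``.
    """
    rvec = points - position
    r = np.linalg.norm(rvec, axis=1)
    clamped = r < r_min
    safe = np.where(r > 0, r, 1.0)
    n = np.where(r[:, None] > 0, rvec / safe[:, None],
                 np.array([0.0, 0.0, 1.0]))
    r = np.maximum(r, r_min)
    ndp = n @ p
    transverse = p[None, :] - n * ndp[:, None]          # (n x p) x n
    longitudinal = 3.0 * n * ndp[:, None] - p[None, :]  # 3 n (n.p) - p
    E = prefactor * np.exp(-1j * k * r)[:, None] * (
        k * k * transverse / r[:, None]
        + longitudinal * (1.0 / r ** 3 + 1j * k / r ** 2)[:, None])
    return E, clamped


def mt_field_numpy(points: np.ndarray, dip_pos: np.ndarray, dip_axis: np.ndarray,
                   dip_amp: np.ndarray, k: complex, prefactor: complex,
                   r_min: float, chunk: int = 256
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Exact phasor field of one MT's dipoles on all points (numpy path).

    ``dip_amp`` are real amplitudes [C*m]; axes are unit vectors.  Returns
    the summed complex field and per-point clamped-contribution counts.
    """
    n = len(points)
    E = np.zeros((n, 3), dtype=np.complex128)
    clamp_counts = np.zeros(n, dtype=np.int64)
    for lo in range(0, n, chunk):
        pts = points[lo:lo + chunk]
        rvec = pts[:, None, :] - dip_pos[None, :, :]     # (c, m, 3)
        r = np.sqrt((rvec ** 2).sum(-1))
        clamped = r < r_min
        safe = np.where(r > 0, r, 1.0)
        nhat = rvec / safe[..., None]
        nhat[r == 0] = (0.0, 0.0, 1.0)
        r = np.maximum(r, r_min)
        ndp = (nhat * dip_axis[None, :, :]).sum(-1) * dip_amp[None, :]
        pvec = dip_axis[None, :, :] * dip_amp[None, :, None]
        transverse = pvec - nhat * ndp[..., None]
        longitudinal = 3.0 * nhat * ndp[..., None] - pvec
        phase = np.exp(-1j * k * r)
        contrib = phase[..., None] * (
            k * k * transverse / r[..., None]
            + longitudinal * (1.0 / r ** 3 + 1j * k / r ** 2)[..., None])
        E[lo:lo + chunk] = prefactor * contrib.sum(axis=1)
        clamp_counts[lo:lo + chunk] = clamped.sum(axis=1)
    return E, clamp_counts


@njit(cache=True)
def _contrib(dx, dy, dz, ax, ay, az, amp, k, r_min):  # pragma: no cover - jit
    r2 = dx * dx + dy * dy + dz * dz
    r = np.sqrt(r2)
    clamped = False
    if r < r_min:
        clamped = True
        if r == 0.0:
            dx, dy, dz = ax, ay, az
            r = 1.0
        dx *= r_min / r
        dy *= r_min / r
        dz *= r_min / r
        r = r_min
    nx, ny, nz = dx / r, dy / r, dz / r
    ndp = (nx * ax + ny * ay + nz * az) * amp
    px, py, pz = ax * amp, ay * amp, az * amp
    tx, ty, tz = px - nx * ndp, py - ny * ndp, pz - nz * ndp
    lx, ly, lz = 3.0 * nx * ndp - px, 3.0 * ny * ndp - py, 3.0 * nz * ndp - pz
    phase = np.exp(-1j * k * r)
    near = 1.0 / (r2 * r) + 1j * k / r2
    rad = k * k / r
    ex = phase * (rad * tx + near * lx)
    ey = phase * (rad * ty + near * ly)
    ez = phase * (rad * tz + near * lz)
    return ex, ey, ez, clamped


@njit(cache=True)
def mt_field_kernel(points, ring_pos, ring_axis, ring_amp, ring_start,
                    dip_pos, dip_axis, dip_amp, k, prefactor, r_min,
                    r_switch):  # pragma: no cover - jit
    """Phasor field of one MT with near/far ring aggregation.

    For each (point, ring) pair: if the point is farther than ``r_switch``
    from the ring centroid, one aggregated dipole contribution is used;
    otherwise the ring's individual dipoles (``ring_start`` delimits slices
    of the dipole arrays).  ``r_switch <= 0`` forces the exact path.
    """
    n = points.shape[0]
    n_rings = ring_pos.shape[0]
    E = np.zeros((n, 3), dtype=np.complex128)
    clamp_counts = np.zeros(n, dtype=np.int64)
    r_switch2 = r_switch * r_switch
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        ex = 0.0 + 0.0j
        ey = 0.0 + 0.0j
        ez = 0.0 + 0.0j
        for g in range(n_rings):
            dx = px - ring_pos[g, 0]
            dy = py - ring_pos[g, 1]
            dz = pz - ring_pos[g, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if r_switch > 0.0 and d2 > r_switch2:
                cx, cy, cz, cl = _contrib(dx, dy, dz, ring_axis[g, 0],
                                          ring_axis[g, 1], ring_axis[g, 2],
                                          ring_amp[g], k, r_min)
                ex += cx
                ey += cy
                ez += cz
                if cl:
                    clamp_counts[i] += 1
            else:
                for m in range(ring_start[g], ring_start[g + 1]):
                    cx, cy, cz, cl = _contrib(px - dip_pos[m, 0],
                                              py - dip_pos[m, 1],
                                              pz - dip_pos[m, 2],
                                              dip_axis[m, 0], dip_axis[m, 1],
                                              dip_axis[m, 2], dip_amp[m],
                                              k, r_min)
                    ex += cx
                    ey += cy
                    ez += cz
                    if cl:
                        clamp_counts[i] += 1
        E[i, 0] = prefactor * ex
        E[i, 1] = prefactor * ey
        E[i, 2] = prefactor * ez
    return E, clamp_counts
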