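"""Spindle geometry: Thomson layout, trajectories, rings, dipole lattice."""

import itertools

import numpy as np
import pytest

import spindlefield as sf
from spindlefield.geometry import (CellGeometry, GeometryError, RingSpec,
                                   StraightTrajectory, place_rings)
from spindlefield.tubulin import default_monomers

CELL = CellGeometry()


def pairwise_angles_deg(points):
    return [np.degrees(np.arccos(np.clip(a @ b, -1, 1)))
            for a, b in itertools.combinations(points, 2)]


class TestThomson:
    def test_two_points_are_antipodal(self):
        pts = sf.distribute_nucleation_centers(2, seed=3)
        assert pairwise_angles_deg(pts)[0] == pytest.approx(180.0, abs=1e-6)

    def test_four_points_form_tetrahedron(self):
        pts = sf.distribute_nucleation_centers(4, seed=1)
        assert np.allclose(pairwise_angles_deg(pts), 109.4712, atol=1e-3)

    def test_six_points_form_octahedron(self):
        pts = sf.distribute_nucleation_centers(6, seed=5)
        min_chord = min(np.linalg.norm(a - b)
                        for a, b in itertools.combinations(pts, 2))
        assert min_chord == pytest.approx(np.sqrt(2.0), abs=1e-6)

    def test_beats_random_configurations(self, rng):
        pts = sf.distribute_nucleation_centers(20, seed=9)
        e_opt = sf.thomson_energy(pts)
        for _ in range(100):
            x = rng.normal(size=(20, 3))
            x /= np.linalg.norm(x, axis=1, keepdims=True)
            assert e_opt <= sf.thomson_energy(x)

    def test_deterministic_and_unit_norm(self):
        a = sf.distribute_nucleation_centers(15, seed=4)
        b = sf.distribute_nucleation_centers(15, seed=4)
        assert np.array_equal(a, b)
        assert np.allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)

    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            sf.distribute_nucleation_centers(1)


class TestCapSelection:
    def test_full_hemisphere_cap(self):
        pts = sf.distribute_nucleation_centers(16, seed=2)
        axis = np.array([0.0, 0.0, 1.0])
        n_hemi = int((pts @ axis > 0).sum())
        sel = sf.select_cap_centers(pts, axis, 2 * np.pi, n_hemi)
        assert len(sel) == n_hemi
        assert np.all(sel @ axis > 0)

    def test_returns_exact_target_count_ranked_by_angle(self):
        pts = sf.distribute_nucleation_centers(30, seed=8)
        axis = np.array([1.0, 0.0, 0.0])
        sel = sf.select_cap_centers(pts, axis, 1.0, 10)
        assert len(sel) == 10
        worst_selected = np.min(sel @ axis)
        rest = [p for p in pts if not any(np.allclose(p, s) for s in sel)]
        assert all(p @ axis <= worst_selected + 1e-12 for p in rest)


class TestAstralTrajectory:
    def test_on_axis_length_analytic(self):
        traj = sf.astral_trajectory([2640.0, 0, 0], [1.0, 0, 0], CELL)
        assert traj.arc_length == pytest.approx(5160 - 2640 - 100, abs=1e-9)

    def test_perpendicular_length_analytic(self):
        traj = sf.astral_trajectory([2640.0, 0, 0], [0, 1.0, 0], CELL)
        expected = CELL.b * np.sqrt(1 - (CELL.c / CELL.a) ** 2) - CELL.rho / 2
        assert traj.arc_length == pytest.approx(expected, abs=1e-9)

    def test_endpoint_against_ray_march_oracle(self, rng):
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            traj = sf.astral_trajectory([2640.0, 0, 0], d, CELL)
            end = traj.point(traj.arc_length)[0]
            # oracle: bisection on the ellipsoid implicit function
            from scipy.optimize import brentq
            start = np.array([2640.0, 0, 0]) + 100.0 * d

            def f(t):
                p = start + t * d
                return CELL.ellipsoid_excess(p)[0] - 1.0

            t_hit = brentq(f, 0.0, 4 * CELL.a, xtol=1e-10)
            assert np.allclose(end, start + t_hit * d, atol=1e-5)

    def test_start_outside_cell_rejected(self):
        with pytest.raises(GeometryError):
            sf.astral_trajectory([5100.0, 0, 0], [1.0, 0, 0], CELL)


class TestEquatorialMagnification:
    def test_fixed_point_and_boundary(self):
        assert sf.equatorial_magnification(0.0, 100.0, CELL) == 0.0
        assert sf.equatorial_magnification(100.0, 100.0, CELL) == \
            pytest.approx(0.8 * CELL.b)

    def test_monotone(self, rng):
        d = np.sort(rng.uniform(0, 100, size=20))
        q = [sf.equatorial_magnification(x, 100.0, CELL) for x in d]
        assert np.all(np.diff(q) >= 0)


class TestKpTrajectory:
    def test_quarter_circle_arc_length(self):
        # q_u = c and a nucleation point at the apex: quarter circle of radius c
        nuc = np.array([CELL.c, 0.0, 0.0])
        traj = sf.kp_trajectory([CELL.c, 0, 0], nuc, CELL.c, CELL)
        assert traj.arc_length == pytest.approx(np.pi / 2 * CELL.c, rel=1e-4)

    def test_endpoint_in_equatorial_plane(self, rng):
        for _ in range(5):
            nuc = np.array([CELL.c, *rng.normal(size=2)])
            q_u = rng.uniform(200.0, 2000.0)
            traj = sf.kp_trajectory([CELL.c, 0, 0], nuc, q_u, CELL)
            end = traj.point(traj.arc_length)[0]
            assert abs(end[0]) < 1e-9 * CELL.c + 1e-9
            assert np.hypot(end[1], end[2]) == pytest.approx(q_u, abs=1e-6)

    def test_arc_at_least_chord(self, rng):
        nuc = np.array([CELL.c, 30.0, -40.0])
        traj = sf.kp_trajectory([CELL.c, 0, 0], nuc, 1500.0, CELL)
        chord = np.linalg.norm(traj.point(traj.arc_length)[0] - traj.point(0.0)[0])
        assert traj.arc_length >= chord

    def test_arc_parameterization_against_chord_sum_oracle(self):
        nuc = np.array([CELL.c, 50.0, 20.0])
        traj = sf.kp_trajectory([CELL.c, 0, 0], nuc, 1800.0, CELL)
        rings = place_rings(traj)
        # oracle: dense chord-sum reparameterization of the same ellipse
        t = np.linspace(traj.t0, np.pi / 2, 200_001)
        pts = (traj.x_semi * np.cos(t))[:, None] * traj._e_x \
            + (traj.q_u * np.sin(t))[:, None] * traj._e_r
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                            axis=1))])
        assert s[-1] == pytest.approx(traj.arc_length, rel=1e-6)
        t_at_rings = np.interp(rings.s, s, t)
        oracle = (traj.x_semi * np.cos(t_at_rings))[:, None] * traj._e_x \
            + (traj.q_u * np.sin(t_at_rings))[:, None] * traj._e_r
        assert np.allclose(np.linalg.norm(rings.position - oracle, axis=1),
                           0.0, atol=1e-3)


class TestRings:
    def test_ring_count_examples(self):
        straight = StraightTrajectory([0, 0, 0], [2420.0, 0, 0])
        assert len(place_rings(straight)) == 302
        assert len(place_rings(StraightTrajectory([0, 0, 0], [8.0, 0, 0]))) == 1

    def test_ring_spacing_is_heterodimer_length(self):
        rings = place_rings(StraightTrajectory([0, 0, 0], [500.0, 0, 0]))
        gaps = np.linalg.norm(np.diff(rings.position, axis=0), axis=1)
        assert np.allclose(gaps, 8.0, atol=1e-6)

    def test_short_trajectory_yields_no_rings(self):
        rings = place_rings(StraightTrajectory([0, 0, 0], [5.0, 0, 0]))
        assert len(rings) == 0

    def test_ring_dipoles_radial_distance_and_span(self):
        spec = RingSpec()
        dip = sf.ring_dipoles([0, 0, 0], [0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0],
                              0.0, spec, default_monomers())
        assert len(dip) == 26
        assert dip.is_alpha.sum() == 13
        radial = np.hypot(dip.position[:, 0], dip.position[:, 1])
        assert np.allclose(radial, spec.ring_diameter_zeta / 2)
        # site centres (alpha/beta midpoints) span 12 * s = 11.04 nm axially
        centers = 0.5 * (dip.position[:13, 2] + dip.position[13:, 2])
        assert centers.max() - centers.min() == pytest.approx(12 * 0.92, abs=1e-9)
        # alpha sits toward the minus (MTOC) end by default
        assert np.all(dip.position[:13, 2] < dip.position[13:, 2])

    def test_ring_dipoles_rigid_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=11).as_matrix()
        d0 = sf.ring_dipoles([0, 0, 0], [0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0],
                             0.0)
        d1 = sf.ring_dipoles([0, 0, 0], R @ [0, 0, 1.0], R @ [1.0, 0, 0],
                             R @ [0, 1.0, 0], 0.0)
        g0 = np.linalg.norm(d0.position[:, None] - d0.position[None], axis=-1)
        g1 = np.linalg.norm(d1.position[:, None] - d1.position[None], axis=-1)
        assert np.allclose(g0, g1, atol=1e-12)
        assert np.allclose(d1.position, d0.position @ R.T, atol=1e-12)


class TestBuildSpindle:
    def test_mini_counts_and_mtocs(self, mini_free):
        assert mini_free.count_by_class() == \
            {"astral": 2, "kinetochore": 2, "polar": 2}
        assert np.allclose(mini_free.mtoc_centers,
                           [[2640.0, 0, 0], [-2640.0, 0, 0]])

    def test_dipole_count_is_26_per_ring(self, mini_free):
        for mt in mini_free.microtubules:
            assert len(mt.dipoles()) == 26 * len(mt.rings)

    def test_centerline_inside_cell_dipoles_on_lattice(self, mini_free):
        cell = mini_free.cell
        for mt in mini_free.microtubules:
            excess = cell.ellipsoid_excess(mt.trajectory.sample(200))
            assert np.all(excess <= 1.0 + 1e-9)
            d = mt.dipoles()
            rings = mt.rings
            offsets = np.linalg.norm(
                d.position - rings.position[d.ring_index], axis=1)
            # lattice extent: zeta/2 radially, <= 13.04 nm axially
            assert offsets.max() <= np.hypot(5.38, 13.04) + 1e-9

    def test_boundary_conditions_by_scenario(self, mini_free, mini_fixed):
        from spindlefield.geometry import BoundaryCondition
        for mt in mini_fixed.microtubules:
            assert mt.boundary_condition is BoundaryCondition.FIXED_FIXED
        for mt in mini_free.microtubules:
            expect = (BoundaryCondition.FIXED_FIXED if mt.mt_class == "astral"
                      else BoundaryCondition.FIXED_FREE)
            assert mt.boundary_condition is expect

    def test_seed_reproducibility(self):
        from spindlefield.fixtures import mini_spindle
        a = mini_spindle(seed=5).dipole_table()
        b = mini_spindle(seed=5).dipole_table()
        c = mini_spindle(seed=6).dipole_table()
        assert a.equals(b)
        assert not a.equals(c)

    def test_free_ends_reach_equatorial_disc(self, mini_free):
        for mt in mini_free.microtubules:
            if mt.mt_class == "astral":
                continue
            end = mt.trajectory.point(mt.length)[0]
            assert abs(end[0]) < 1e-6
            assert np.hypot(end[1], end[2]) <= 0.8 * mini_free.cell.b + 1e-6

    def test_default_model_counts(self, default_free_model):
        assert default_free_model.n_mt == 300
        assert default_free_model.count_by_class() == \
            {"astral": 100, "kinetochore": 100, "polar": 100}

    def test_volume_equivalence_of_table_defaults(self):
        r = (CELL.a * CELL.b ** 2) ** (1 / 3)
        assert r == pytest.approx(CELL.R_equiv, rel=0.01)
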