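"""Medium response and Hertzian-dipole field superposition."""

import numpy as np
import pytest
import scipy.constants as const
from scipy.spatial.transform import Rotation

import spindlefield as sf
from spindlefield import constants
from spindlefield.dynamics import ExcitationSpec
from spindlefield.geometry import (BoundaryCondition, Microtubule,
                                   SpindleModel, SpindleParams,
                                   StraightTrajectory)

FF = BoundaryCondition.FIXED_FIXED


def tiny_model(phases=(0.0,), length=160.0, offsets=((0.0, 0.0, 0.0),)):
    """Stub spindle of identical straight MTs with prescribed phases."""
    mts = []
    for i, (phi, off) in enumerate(zip(phases, offsets)):
        off = np.asarray(off)
        mt = Microtubule(StraightTrajectory(off, off + [length, 0, 0]), FF)
        mt.principal_frequency = sf.principal_frequency(length, FF)
        mt.phase = phi
        mt.index = i
        mts.append(mt)
    params = SpindleParams()
    return SpindleModel(cell=params.cell, params=params,
                        mtoc_centers=np.zeros((2, 3)), microtubules=mts, seed=0)


class TestMedium:
    def test_debye_static_limit(self):
        eps, k, Z = sf.medium_at(1e3, sf.MediumModel())
        assert eps.real == pytest.approx(78.3, rel=1e-6)
        assert abs(eps.imag) < 1e-3

    def test_max_loss_at_inverse_relaxation_frequency(self):
        m = sf.MediumModel()
        f0 = 1.0 / (2 * np.pi * m.tau)
        eps, _, _ = sf.medium_at(f0, m)
        assert -eps.imag == pytest.approx((m.eps_static - m.eps_inf) / 2, rel=1e-9)

    def test_lossless_medium_real_k_and_Z(self):
        eps, k, Z = sf.medium_at(10e9, sf.lossless_medium(60.0))
        assert eps == 60.0 + 0j
        assert k.imag == 0.0 and k.real > 0
        assert Z.imag == pytest.approx(0.0, abs=1e-12)

    def test_lossy_k_decays_outgoing_wave(self):
        eps, k, Z = sf.medium_at(10e9, sf.MediumModel())
        assert k.imag < 0  # e^{-ikr} decay with e^{+i omega t}

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            sf.medium_at(0.0)


class TestDipoleField:
    def test_quasi_static_oracle_on_axis(self):
        eps, k, _ = sf.medium_at(10e9, sf.lossless_medium(60.0))
        E, cl = sf.dipole_field([0, 0, 1.0], [0, 0, 0], [[0, 0, 100.0]],
                                k, eps, r_min=1.0)
        oracle = 2 * constants.DEBYE_SI / (
            4 * np.pi * const.epsilon_0 * 60.0 * (100e-9) ** 3)
        assert abs(E[0, 2]) == pytest.approx(oracle, rel=1e-3)
        assert not cl.any()

    def test_quasi_static_equatorial_half_antiparallel(self):
        eps, k, _ = sf.medium_at(10e9, sf.lossless_medium(60.0))
        E_ax, _ = sf.dipole_field([0, 0, 1.0], [0, 0, 0], [[0, 0, 100.0]], k, eps)
        E_eq, _ = sf.dipole_field([0, 0, 1.0], [0, 0, 0], [[100.0, 0, 0]], k, eps)
        assert abs(E_eq[0, 2]) == pytest.approx(abs(E_ax[0, 2]) / 2, rel=1e-3)
        assert np.sign(E_eq[0, 2].real) == -np.sign(E_ax[0, 2].real)

    def test_far_field_one_over_r(self):
        eps, k, _ = sf.medium_at(10e9, sf.lossless_medium(60.0))
        r = np.geomspace(10 / k.real, 100 / k.real, 16) / 1e-9  # nm
        pts = np.column_stack([r, np.zeros_like(r), np.zeros_like(r)])
        E, _ = sf.dipole_field([0, 0, 1.0], [0, 0, 0], pts, k, eps, r_min=1.0)
        product = np.abs(E[:, 2]) * r
        assert product.max() / product.min() - 1 < 0.01

    def test_rigid_rotation_invariance(self):
        eps, k, _ = sf.medium_at(10e9, sf.MediumModel())
        R = Rotation.random(random_state=5).as_matrix()
        p = np.array([0.3, -0.5, 1.1])
        pts = np.array([[120.0, 40.0, -60.0], [5.0, 300.0, 10.0]])
        E0, _ = sf.dipole_field(p, [10.0, 0, 0], pts, k, eps)
        E1, _ = sf.dipole_field(R @ p, R @ [10.0, 0, 0], pts @ R.T, k, eps)
        assert np.allclose(np.linalg.norm(E1, axis=1),
                           np.linalg.norm(E0, axis=1), rtol=1e-9)
        assert np.allclose(E1, E0 @ R.T, rtol=1e-9, atol=1e-12)

    def test_clamped_inside_exclusion_radius(self):
        eps, k, _ = sf.medium_at(10e9, sf.MediumModel())
        E, cl = sf.dipole_field([0, 0, 1.0], [0, 0, 0], [[0, 0, 2.0]], k, eps,
                                r_min=4.0)
        E_at_rmin, _ = sf.dipole_field([0, 0, 1.0], [0, 0, 0], [[0, 0, 4.0]],
                                       k, eps, r_min=4.0)
        assert cl.all()
        assert abs(E[0, 2]) == pytest.approx(abs(E_at_rmin[0, 2]), rel=1e-12)


class TestSuperposition:
    GRID = sf.points_grid([[80.0, 120.0, 90.0], [200.0, -50.0, 40.0],
                           [-60.0, 30.0, 250.0]])

    def test_opposite_phases_cancel(self):
        model = tiny_model(phases=(0.0, np.pi), offsets=((0, 0, 0), (0, 0, 0)))
        frame = sf.superpose(model, ExcitationSpec(), 0.0, self.GRID,
                             aggregate="exact")
        one = sf.superpose(tiny_model(), ExcitationSpec(), 0.0, self.GRID,
                           aggregate="exact")
        # cancellation is exact up to floating roundoff of the summands
        assert np.max(np.abs(frame.E_real)) < 1e-12 * np.max(np.abs(one.E_real))

    def test_linear_in_sources(self):
        two = tiny_model(phases=(0.0, 1.0), offsets=((0, 0, 0), (0, 500.0, 0)))
        one_a = tiny_model(phases=(0.0,), offsets=((0, 0, 0),))
        one_b = tiny_model(phases=(1.0,), offsets=((0, 500.0, 0),))
        exc = ExcitationSpec()
        f_two = sf.superpose(two, exc, 1e-12, self.GRID, aggregate="exact")
        f_a = sf.superpose(one_a, exc, 1e-12, self.GRID, aggregate="exact")
        f_b = sf.superpose(one_b, exc, 1e-12, self.GRID, aggregate="exact")
        assert np.allclose(f_two.E_real, f_a.E_real + f_b.E_real, rtol=1e-12)

    def test_kernel_matches_numpy_reference(self, mini_free):
        exc = ExcitationSpec()
        sf.assign_phases(mini_free, exc)
        grid = sf.points_grid(np.random.default_rng(0).uniform(
            -1500, 1500, size=(40, 3)))
        exact = sf.superpose(mini_free, exc, 0.0, grid, aggregate="exact")
        auto = sf.superpose(mini_free, exc, 0.0, grid, aggregate="auto")
        ring = sf.superpose(mini_free, exc, 0.0, grid, aggregate="ring")
        ok = ~exact.clamped_mask
        rel = np.abs(auto.magnitude[ok] - exact.magnitude[ok]) / exact.magnitude[ok]
        assert rel.max() < 1e-2
        rel_ring = np.abs(ring.magnitude[ok] - exact.magnitude[ok]) / exact.magnitude[ok]
        assert np.median(rel_ring) < 1e-2

    def test_free_ends_beat_fixed_ends_in_equatorial_plane(self, mini_free,
                                                           mini_fixed):
        exc = ExcitationSpec()
        grid = sf.plane_grid(axis=0, offset=0.0, half_span=2000.0, pitch=100.0)
        sf.assign_phases(mini_free, exc)
        sf.assign_phases(mini_fixed, exc)
        f_free = sf.superpose(mini_free, exc, 0.0, grid)
        f_fixed = sf.superpose(mini_fixed, exc, 0.0, grid)
        assert f_free.magnitude.mean() > f_fixed.magnitude.mean()


class TestTimeSeries:
    def test_default_sampling_count(self, mini_free):
        exc = ExcitationSpec()
        sf.assign_phases(mini_free, exc)
        grid = sf.points_grid([[0.0, 500.0, 0.0]])
        frames = sf.time_series(mini_free, exc, grid)
        assert len(frames) == 300
        nu = mini_free.frequencies()
        assert frames[1].time == pytest.approx(5 / nu.min() / 300)

    def test_single_mt_periodicity(self):
        model = tiny_model()
        exc = ExcitationSpec()
        grid = sf.points_grid([[80.0, 60.0, 0.0]])
        nu = model.frequencies()[0]
        f0 = sf.superpose(model, exc, 0.2 / nu, grid, aggregate="exact")
        f1 = sf.superpose(model, exc, 1.2 / nu, grid, aggregate="exact")
        assert np.allclose(f0.E_real, f1.E_real, rtol=1e-6)

    def test_damped_pulse_period_peaks_decay(self):
        model = tiny_model()
        exc = ExcitationSpec(damped=True, Q=5.0)
        grid = sf.points_grid([[100.0, 80.0, 0.0]])
        frames = sf.time_series(model, exc, grid, n_periods=5, n_samples=300)
        mags = np.array([f.magnitude[0] for f in frames])
        per_period = mags.reshape(5, 60).max(axis=1)
        assert np.all(np.diff(per_period) < 0)

    def test_clamp_reporting(self):
        model = tiny_model()
        d = model.microtubules[0].dipoles()
        near = d.position[0] + [0.0, 1.0, 0.0]  # 1 nm from a dipole
        far = [0.0, 2000.0, 0.0]
        frame = sf.superpose(model, ExcitationSpec(), 0.0,
                             sf.points_grid([near, far]), aggregate="exact",
                             r_min=4.0)
        assert frame.clamped_mask[0]
        assert not frame.clamped_mask[1]
        assert frame.n_clamped == 1
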