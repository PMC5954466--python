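import numpy as np
import pytest

from surfdrift.particle_advection import (
    rk4_step,
    sample_velocity,
    track,
    track_batch,
)
from surfdrift.synthetic_data import SynthConfig, synth_currents
from surfdrift.velocity_field import CM_S_TO_KM_H

from .conftest import make_rotation_field, make_uniform_field


class TestSampleVelocity:
    def test_uniform_field_anywhere(self, demo_domain):
        f = make_uniform_field(demo_domain, 10.0, 0.0)
        vel, ok = sample_velocity(f, [[17.3, 12.9]], 5.25)
        assert ok.all()
        assert vel[0] == pytest.approx([10 * CM_S_TO_KM_H, 0.0])

    def test_bilinear_mean_at_corner_midpoint(self, demo_domain):
        f = make_uniform_field(demo_domain, 0.0, 0.0)
        f.u[:, 15, 10] = 0.0
        f.u[:, 15, 11] = 0.0
        f.u[:, 16, 10] = 20.0
        f.u[:, 16, 11] = 20.0
        # midpoint of the 4 nodes (10.5..11.5, 15.5..16.5) -> mean u = 10
        vel, ok = sample_velocity(f, [[11.0, 16.0]], 0.0)
        assert vel[0, 0] == pytest.approx(10 * CM_S_TO_KM_H)

    def test_linear_in_time(self, demo_domain):
        f = make_uniform_field(demo_domain, 0.0, 0.0, n_hours=4)
        f.u[0] = 0.0
        f.u[1] = 20.0
        vel, _ = sample_velocity(f, [[25.0, 15.0]], 0.5)
        assert vel[0, 0] == pytest.approx(10 * CM_S_TO_KM_H)

    def test_gap_renormalization(self, demo_domain):
        f = make_uniform_field(demo_domain, 10.0, 0.0)
        f.mask[:, 15, 10] = False  # one of the 4 neighbours missing
        vel, ok = sample_velocity(f, [[11.0, 16.0]], 0.0)
        assert ok.all()
        assert vel[0, 0] == pytest.approx(10 * CM_S_TO_KM_H)

    def test_all_neighbours_invalid_signals_no_data(self, demo_domain):
        f = make_uniform_field(demo_domain, 10.0, 0.0)
        f.mask[:, 14:18, 9:13] = False
        vel, ok = sample_velocity(f, [[11.0, 16.0]], 0.0)
        assert not ok.any()

    def test_time_outside_record_raises(self, demo_domain):
        f = make_uniform_field(demo_domain, 10.0, 0.0, n_hours=5)
        with pytest.raises(ValueError, match="outside"):
            sample_velocity(f, [[25.0, 15.0]], 10.0)


class TestRK4:
    def test_uniform_displacement_exact(self, demo_domain):
        f = make_uniform_field(demo_domain, 10.0, 0.0)
        new, ok = rk4_step(f, [[20.0, 15.0]], 0.0, 1.0)
        assert new[0] == pytest.approx([20.36, 15.0])

    def test_zero_field_no_motion(self, demo_domain):
        f = make_uniform_field(demo_domain, 0.0, 0.0)
        new, _ = rk4_step(f, [[20.0, 15.0]], 0.0, 1.0)
        assert new[0] == pytest.approx([20.0, 15.0])

    def test_rotation_radius_preserved(self, demo_domain):
        f = make_rotation_field(demo_domain, period_h=12.0)
        p = np.array([[30.0, 15.0]])  # radius 5 about (25, 15)
        for k in range(120):
            p, ok = rk4_step(f, p, k * 0.1, 0.1)
        r = np.hypot(p[0, 0] - 25.0, p[0, 1] - 15.0)
        assert abs(r - 5.0) < 1e-3  # < 1 m over one full period

    def test_fourth_order_convergence(self, demo_domain):
        """Halving dt shrinks the one-period position error ~16x."""
        f = make_rotation_field(demo_domain, period_h=12.0)
        start = np.array([[30.0, 15.0]])

        def end_error(dt):
            p = start.copy()
            for k in range(int(round(12.0 / dt))):
                p, _ = rk4_step(f, p, k * dt, dt)
            return np.hypot(*(p[0] - start[0]))

        e1, e2 = end_error(0.4), end_error(0.2)
        assert 8.0 < e1 / e2 < 32.0


class TestTrack:
    def test_uniform_flow_exit_time_hand_integrated(self, demo_domain):
        # 36 cm/s = 1.296 km/h east, release 6.5 km from the east edge:
        # first hourly log past the edge is hour 6 (6 x 1.296 = 7.78 km)
        f = make_uniform_field(demo_domain, 36.0, 0.0)
        traj = track(f, (43.5, 15.0), "2015-01-01")
        assert traj.exit_time_h == 6.0
        assert traj.exit_reason == "left_footprint"

    def test_interior_orbit_censored(self, demo_domain):
        f = make_rotation_field(demo_domain, period_h=12.0, n_hours=48)
        traj = track(f, (30.0, 15.0), "2015-01-01", horizon_h=48)
        assert traj.censored
        assert traj.exit_reason == "record_end"

    def test_edge_release_exits_first_hour(self, demo_domain):
        f = make_uniform_field(demo_domain, 36.0, 0.0)
        traj = track(f, (49.5, 15.0), "2015-01-01")
        assert traj.exit_time_h == 1.0

    def test_release_outside_footprint_rejected(self, demo_domain):
        f = make_uniform_field(demo_domain, 10.0, 0.0)
        with pytest.raises(ValueError, match="outside footprint"):
            track(f, (60.0, 15.0), "2015-01-01")

    def test_persistent_gap_terminates_particle(self, demo_domain):
        f = make_uniform_field(demo_domain, 0.0, 0.0)
        f.mask[:, 12:19, 12:19] = False  # static hole in coverage
        traj = track(f, (15.5, 15.5), "2015-01-01", max_gap_hours=3)
        assert traj.exit_reason == "entered_persistent_gap"
        assert traj.exit_time_h == 4.0  # first hour past the 3 h tolerance

    def test_sub_hour_excursion_is_not_an_exit(self, demo_domain):
        """Exit is checked at hourly logs only; a particle that pokes out
        and returns between logs stays in."""
        f = make_uniform_field(demo_domain, 0.0, 0.0, n_hours=4)
        # eastward burst in the first half-hour, then westward
        f.u[0] = 100.0
        f.u[1] = -100.0
        traj = track(f, (49.4, 15.0), "2015-01-01", horizon_h=2)
        assert traj.positions[1, 0] < 50.0

    def test_rerun_is_identical(self, small_domain):
        cfg = SynthConfig(duration_days=3.0, seed=13)
        f = synth_currents(cfg, small_domain)
        rel = np.vstack([r.release_points for r in small_domain.subregions])
        a = track_batch(f, rel, "2015-01-01", horizon_h=48)
        b = track_batch(f, rel, "2015-01-01", horizon_h=48)
        assert np.array_equal(a["exit_time_h"], b["exit_time_h"], equal_nan=True)
        assert np.array_equal(a["positions"], b["positions"], equal_nan=True)

    def test_fast_kernel_matches_reference_path(self, small_domain):
        cfg = SynthConfig(duration_days=3.0, seed=13)
        f = synth_currents(cfg, small_domain)
        rel = np.vstack([r.release_points for r in small_domain.subregions])
        fast = track_batch(f, rel, "2015-01-01", horizon_h=36, use_fast_kernel=True)
        ref = track_batch(f, rel, "2015-01-01", horizon_h=36, use_fast_kernel=False)
        assert np.array_equal(fast["exit_time_h"], ref["exit_time_h"], equal_nan=True)
        assert np.allclose(fast["positions"], ref["positions"], atol=1e-9, equal_nan=True)

    def test_area_conserved_in_smooth_nondivergent_field(self, demo_domain):
        """A small particle quadrilateral keeps its area within 1% over 24 h
        in a non-divergent eddy field resolved well by the grid."""
        cfg = SynthConfig(
            duration_days=2.0,
            mean_current_cms=(0.0, 0.0),
            tidal_amplitudes={},
            tidal_phases_deg={},
            wind_coupling=0.0,
            eddy_rms_cms=6.0,
            eddy_length_km=25.0,
            gap_fraction=0.0,
            seed=7,
        )
        f = synth_currents(cfg, demo_domain)
        sq = np.array([[24.0, 14.0], [26.0, 14.0], [26.0, 16.0], [24.0, 16.0]])
        batch = track_batch(f, sq, "2015-01-01", dt=0.1, horizon_h=24)
        p = batch["positions"][24]
        x, y = p[:, 0], p[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert area == pytest.approx(4.0, rel=0.01)
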