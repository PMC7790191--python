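"""Slender-body solver: geometry, kernels, torques, screening."""

import numpy as np
import pytest

from cilialign import sbt

FAST = sbt.StokesDiscretization(segments_per_rod=12)
MID = sbt.StokesDiscretization(segments_per_rod=16)


class TestPlaceRods:
    def test_single_rod_at_origin(self):
        cfg = sbt.RodArrayConfig(n_rows=1, n_cols=1)
        geom = sbt.place_rods(cfg, FAST)
        assert geom.bases.shape == (1, 3)
        np.testing.assert_allclose(geom.bases[0], [0, 0, 0.05], atol=1e-12)
        elev = np.degrees(np.arcsin(geom.axis[2]))
        assert elev == pytest.approx(53.0)

    def test_lattice_theta_zero_beats_along_flow(self):
        cfg = sbt.RodArrayConfig(n_rows=3, n_cols=3, d_perp=0.08, theta=0.0)
        geom = sbt.place_rods(cfg, FAST)
        assert geom.bases.shape == (9, 3)
        np.testing.assert_allclose(geom.e_hat, [0, 1, 0], atol=1e-12)
        # nearest-neighbour gap perpendicular to the beating direction
        xs = np.unique(np.round(geom.bases[:, 0], 9))
        assert np.min(np.diff(xs)) == pytest.approx(0.08)

    def test_theta_pi_half_rotates_axes_off_y(self):
        cfg = sbt.RodArrayConfig(n_rows=2, n_cols=2, d_perp=0.2, theta=np.pi / 2)
        geom = sbt.place_rods(cfg, FAST)
        assert abs(geom.axis[1]) < 1e-12
        # explicit rotation of the theta = 0 construction by 90 degrees
        geom0 = sbt.place_rods(
            sbt.RodArrayConfig(n_rows=2, n_cols=2, d_perp=0.2, theta=0.0), FAST
        )
        rot = np.array([[0, 1, 0], [-1, 0, 0], [0, 0, 1.0]])
        np.testing.assert_allclose(geom.axis, rot @ geom0.axis, atol=1e-12)

    def test_spacing_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="two-body-width"):
            sbt.RodArrayConfig(n_rows=1, n_cols=2, d_perp=0.05)
        with pytest.raises(ValueError, match="stroke-extent"):
            sbt.RodArrayConfig(n_rows=2, n_cols=1, d_par=1.0)


class TestAmbientShear:
    def test_no_slip_on_wall(self):
        np.testing.assert_allclose(sbt.ambient_shear([0.3, -1.0, 0.0]), 0.0)

    def test_linear_profile(self):
        np.testing.assert_allclose(sbt.ambient_shear([0, 0, 1.0]), [0, 1, 0])
        np.testing.assert_allclose(
            sbt.ambient_shear([0, 0, 0.55], shear_rate=2.0), [0, 1.1, 0]
        )

    def test_below_wall_rejected(self):
        with pytest.raises(ValueError):
            sbt.ambient_shear([0, 0, -0.1])


class TestSolve:
    def test_zero_shear_gives_zero_forces(self):
        cfg = sbt.RodArrayConfig(n_rows=1, n_cols=1)
        disc = sbt.StokesDiscretization(segments_per_rod=12, shear_rate=0.0)
        geom = sbt.place_rods(cfg, disc)
        sol = sbt.solve_force_density(geom, disc)
        np.testing.assert_allclose(sol.force_density, 0.0, atol=1e-14)

    def test_uniform_perpendicular_flow_matches_rft_closed_form(self):
        # vertical rod, free space, uniform flow perpendicular to the axis;
        # resistive-force oracle: f = C_perp * U, C_perp = 4 pi / (ln(2/eps) + 1/2)
        cfg = sbt.RodArrayConfig(n_rows=1, n_cols=1, tilt_alpha=90.0, wall_gap=0.5)
        disc = sbt.StokesDiscretization(segments_per_rod=24)
        geom = sbt.place_rods(cfg, disc, wall=False)
        a_mat = sbt._assemble_matrix(geom, disc)
        u = np.tile([1.0, 0.0, 0.0], geom.segments_per_rod)
        f = np.linalg.solve(a_mat, -8 * np.pi * u).reshape(-1, 3)
        eps = cfg.radius / cfg.rod_length
        c_perp = 4 * np.pi / (np.log(2 / eps) + 0.5)
        mid = geom.segments_per_rod // 2
        assert -f[mid, 0] == pytest.approx(c_perp, rel=0.2)
        assert np.abs(f[:, 1:]).max() < 1e-10

    def test_torque_self_convergence_in_node_count(self):
        t16 = sbt.isolated_rod_torque(discretization=MID)
        t32 = sbt.isolated_rod_torque(
            discretization=sbt.StokesDiscretization(segments_per_rod=32)
        )
        assert abs(t32 - t16) / abs(t32) < 0.02

    def test_residual_is_reported(self):
        geom = sbt.place_rods(sbt.RodArrayConfig(n_rows=1, n_cols=1), FAST)
        sol = sbt.solve_force_density(geom, FAST)
        assert sol.residual < 1e-10


class TestTorque:
    def test_flow_along_beating_direction_gives_no_torque(self):
        tq = sbt.isolated_rod_torque(theta=0.0, discretization=FAST)
        assert abs(tq) < 1e-10

    def test_mirror_flow_flips_torque_sign(self):
        cfg = sbt.RodArrayConfig(n_rows=1, n_cols=1, theta=np.pi / 2)
        geom = sbt.place_rods(cfg, FAST)
        plus = sbt.rod_torque_z(
            sbt.solve_force_density(geom, FAST, flow_direction=(0, 1, 0)),
            aligning_sign=False,
        ).mean_torque
        minus = sbt.rod_torque_z(
            sbt.solve_force_density(geom, FAST, flow_direction=(0, -1, 0)),
            aligning_sign=False,
        ).mean_torque
        assert minus == pytest.approx(-plus, rel=1e-10)

    @pytest.mark.parametrize("gammadot", [2.0, 5.0])
    def test_torque_linear_in_shear_rate(self, gammadot):
        base = sbt.isolated_rod_torque(discretization=FAST)
        disc = sbt.StokesDiscretization(segments_per_rod=12, shear_rate=gammadot)
        cfg = sbt.RodArrayConfig(n_rows=1, n_cols=1)
        geom = sbt.place_rods(cfg, disc)
        raw = sbt.rod_torque_z(sbt.solve_force_density(geom, disc)).per_rod_torque_z
        # rod_torque_z reports the non-dimensional torque: invariant in gammadot
        assert raw[0] == pytest.approx(base, rel=1e-10)
        # and the dimensional torque scales linearly
        dimensional = raw[0] * gammadot
        assert dimensional == pytest.approx(base * gammadot, rel=1e-10)

    def test_wall_images_enforce_no_slip(self):
        cfg = sbt.RodArrayConfig(n_rows=1, n_cols=2, d_perp=0.2)
        geom = sbt.place_rods(cfg, FAST)
        sol = sbt.solve_force_density(geom, FAST)
        rng = np.random.default_rng(0)
        pts = np.column_stack(
            [rng.uniform(-2, 2, 20), rng.uniform(-2, 2, 20), np.zeros(20)]
        )
        u = sbt.evaluate_velocity(pts, sol)
        assert np.abs(u).max() < 1e-6

    def test_flow_suppressed_next_to_rod(self):
        geom = sbt.place_rods(sbt.RodArrayConfig(n_rows=1, n_cols=1), FAST)
        sol = sbt.solve_force_density(geom, FAST)
        # a small standoff where the point-quadrature far field is resolved
        probe = geom.nodes[0, 6] + np.array([0.0, 0.05, 0.0])
        u = sbt.evaluate_velocity(probe, sol)
        ambient = sbt.ambient_shear(probe, 1.0)
        assert np.linalg.norm(u) < 0.2 * np.linalg.norm(ambient)


@pytest.fixture(scope="module")
def small_table():
    cfg = sbt.RodArrayConfig(n_rows=3, n_cols=3)
    return sbt.screening_sweep(
        [0.08, 0.16, 0.40], [0.0, np.pi / 4, np.pi / 2], cfg, FAST
    )


class TestScreening:
    def test_theta_zero_row_vanishes(self, small_table):
        np.testing.assert_allclose(small_table.normalized_torque[0], 0.0, atol=1e-8)

    def test_screening_never_amplifies(self, small_table):
        assert np.all(small_table.normalized_torque <= 1.0 + 1e-9)
        assert np.all(small_table.normalized_torque >= -1e-9)

    def test_torque_decreases_with_density(self, small_table):
        # rho grid is decreasing in d_perp, so torque increases along columns
        row = small_table.normalized_torque[-1]
        assert np.all(np.diff(row) > 0)

    def test_isolated_limit_recovers_unity(self):
        cfg = sbt.RodArrayConfig(n_rows=1, n_cols=1)
        tab = sbt.screening_sweep([5.0], [np.pi / 2], cfg, FAST)
        assert tab.normalized_torque[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_parallel_spacing_insensitivity(self):
        # widening d_par beyond its minimum barely changes the torque
        disc = FAST
        torques = []
        for dpar in (sbt.DEFAULT_D_PAR_MIN, 1.5 * sbt.DEFAULT_D_PAR_MIN):
            cfg = sbt.RodArrayConfig(n_rows=3, n_cols=1, d_par=dpar)
            geom = sbt.place_rods(cfg, disc)
            sol = sbt.solve_force_density(geom, disc)
            torques.append(sbt.rod_torque_z(sol).mean_torque)
        assert abs(torques[1] - torques[0]) / abs(torques[0]) < 0.05

    def test_table_roundtrip(self, small_table, tmp_path):
        path = tmp_path / "table.json"
        small_table.to_json(path)
        back = sbt.ScreeningTable.from_json(path)
        np.testing.assert_allclose(
            back.normalized_torque, small_table.normalized_torque
        )
        assert back.t0 == pytest.approx(small_table.t0)
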