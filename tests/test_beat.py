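"""Beat-waveform geometry: centerline reconstruction, mean tangent, footprint."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from cilialign.beat import (
    BeatPattern,
    mean_tangent_angle,
    min_parallel_spacing,
    reconstruct_centerline,
    swept_summary,
)
from cilialign.synthetic import beat_pattern_with_extremes, make_beat_pattern


def _constant_pattern(angle_rad, n_s=41, n_t=8):
    s = np.linspace(0, 1, n_s)
    t = np.arange(n_t) / n_t
    return BeatPattern(s, t, np.full((n_s, n_t), angle_rad))


class TestCenterline:
    def test_straight_rod_along_beating_direction(self):
        beat = _constant_pattern(0.0)
        pts = reconstruct_centerline(beat, 0.0)
        assert pts[0] == pytest.approx([0.0, 0.0])
        assert pts[-1] == pytest.approx([1.0, 0.0])

    def test_vertical_rod(self):
        beat = _constant_pattern(np.pi / 2)
        tip = reconstruct_centerline(beat, 0.0)[-1]
        assert tip == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_curved_rod_against_quadrature_oracle(self):
        # psi(s) = pi/2 - 0.8 s; oracle: trapezoid quadrature at 1e5 nodes
        s_fine = np.linspace(0, 1, 100_001)
        psi_fine = np.pi / 2 - 0.8 * s_fine
        y_oracle = np.trapezoid(np.cos(psi_fine), s_fine)
        z_oracle = np.trapezoid(np.sin(psi_fine), s_fine)

        n_s = 2001
        s = np.linspace(0, 1, n_s)
        beat = BeatPattern(s, np.array([0.0]), (np.pi / 2 - 0.8 * s)[:, None])
        tip = reconstruct_centerline(beat, 0.0)[-1]
        assert tip[0] == pytest.approx(y_oracle, abs=1e-6)
        assert tip[1] == pytest.approx(z_oracle, abs=1e-6)

    @pytest.mark.parametrize("amplitude,wave", [(0.3, 0.0), (0.9, 0.4), (1.2, 1.0)])
    def test_contour_length_is_one(self, amplitude, wave):
        beat = make_beat_pattern(amplitude, 0.1, n_s=401, wave=wave)
        for phase in (0.0, 0.3, 0.7):
            pts = reconstruct_centerline(beat, phase)
            seg = np.diff(pts, axis=0)
            length = np.sum(np.hypot(seg[:, 0], seg[:, 1]))
            assert length == pytest.approx(1.0, rel=2e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        amplitude=hs.floats(0.0, 1.2),
        asymmetry=hs.floats(-0.3, 0.3),
        wave=hs.floats(0.0, 1.0),
        phase=hs.floats(0.0, 0.999),
    )
    def test_contour_length_invariant_for_any_waveform(
        self, amplitude, asymmetry, wave, phase
    ):
        if amplitude + abs(asymmetry) >= np.pi / 2:
            return
        beat = make_beat_pattern(amplitude, asymmetry, n_s=201, wave=wave)
        pts = reconstruct_centerline(beat, phase)
        seg = np.diff(pts, axis=0)
        assert np.sum(np.hypot(seg[:, 0], seg[:, 1])) == pytest.approx(1.0, rel=2e-3)

    def test_phase_out_of_range_rejected(self):
        beat = _constant_pattern(0.3)
        with pytest.raises(ValueError, match="phase"):
            reconstruct_centerline(beat, 1.0)

    def test_non_monotone_s_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            BeatPattern(np.array([0.0, 0.6, 0.4, 1.0]), np.array([0.0]),
                        np.zeros((4, 1)))


class TestMeanTangent:
    def test_constant_tilt_is_identity(self):
        beat = _constant_pattern(np.radians(53.0))
        assert mean_tangent_angle(beat) == pytest.approx(53.0, abs=1e-10)

    def test_traveling_wave_against_dense_grid_oracle(self):
        # psi(s,t) = pi/2 - a s (1 + b sin 2 pi t)
        a, b = 0.8, 0.3

        def psi(s, t):
            return np.pi / 2 - a * s * (1 + b * np.sin(2 * np.pi * t))

        # oracle: uniform-measure vector average on a very dense grid
        s_f = np.linspace(0, 1, 4001)
        t_f = (np.arange(8192) + 0.5) / 8192
        psi_f = psi(s_f[:, None], t_f[None, :])
        vy = np.trapezoid(np.cos(psi_f), s_f, axis=0).mean()
        vz = np.trapezoid(np.sin(psi_f), s_f, axis=0).mean()
        oracle_deg = np.degrees(np.arctan2(vz, vy))

        s = np.linspace(0, 1, 201)
        t = np.arange(256) / 256
        beat = BeatPattern(s, t, psi(s[:, None], t[None, :]))
        assert mean_tangent_angle(beat) == pytest.approx(oracle_deg, abs=0.05)

    def test_invariant_under_phase_shift_and_time_reversal(self):
        beat = make_beat_pattern(0.9, 0.2, n_s=61, n_t=64, wave=0.3)
        base = mean_tangent_angle(beat)
        rolled = BeatPattern(beat.s_grid, beat.t_grid,
                             np.roll(beat.psi, 17, axis=1))
        reversed_ = BeatPattern(beat.s_grid, beat.t_grid, beat.psi[:, ::-1])
        assert mean_tangent_angle(rolled) == pytest.approx(base, abs=1e-9)
        assert mean_tangent_angle(reversed_) == pytest.approx(base, abs=1e-9)

    def test_single_sample_degenerate_grid(self):
        beat = BeatPattern(np.array([0.0]), np.array([0.0]),
                           np.array([[np.radians(40.0)]]))
        assert mean_tangent_angle(beat) == pytest.approx(40.0)

    def test_angle_average_mode(self):
        beat = _constant_pattern(np.radians(30.0))
        assert mean_tangent_angle(beat, average="angle") == pytest.approx(30.0)


class TestSweptSummary:
    def test_static_tilted_rod(self):
        beat = _constant_pattern(np.radians(53.0))
        summ = swept_summary(beat)
        assert summ.forward_angle == pytest.approx(53.0, abs=1e-9)
        assert summ.backward_angle == pytest.approx(53.0, abs=1e-9)
        assert summ.a_top == pytest.approx(np.cos(np.radians(53.0)) * 0.04, rel=1e-9)

    def test_prescribed_stroke_extremes(self):
        beat = beat_pattern_with_extremes(23.0, 18.0)
        summ = swept_summary(beat)
        assert summ.forward_angle == pytest.approx(23.0, abs=0.1)
        assert summ.backward_angle == pytest.approx(18.0, abs=0.1)
        expected = (np.cos(np.radians(23)) + np.cos(np.radians(18))) * 0.04
        assert summ.a_top == pytest.approx(expected, rel=1e-3)

    def test_vertical_rod_has_zero_footprint(self):
        beat = _constant_pattern(np.pi / 2)
        assert swept_summary(beat).a_top == pytest.approx(0.0, abs=1e-12)

    def test_footprint_monotone_in_sweep_amplitude(self):
        areas = [
            swept_summary(make_beat_pattern(a, 0.0, n_t=64)).a_top
            for a in (0.1, 0.4, 0.8, 1.2)
        ]
        assert np.all(np.diff(areas) > 0)

    def test_min_parallel_spacing_matches_reaches(self):
        expected = np.cos(np.radians(23)) + np.cos(np.radians(18))
        assert min_parallel_spacing(23, 18) == pytest.approx(expected)


class TestSerialization:
    def test_csv_roundtrip(self, tmp_path):
        beat = make_beat_pattern(0.7, 0.1, n_s=11, n_t=12, wave=0.2)
        path = tmp_path / "beat.csv"
        beat.to_csv(path)
        back = BeatPattern.from_csv(path)
        np.testing.assert_allclose(back.psi, beat.psi, atol=1e-12)

    def test_json_roundtrip(self, tmp_path):
        beat = make_beat_pattern(0.5, 0.0, n_s=9, n_t=8)
        path = tmp_path / "beat.json"
        beat.to_json(path)
        back = BeatPattern.from_json(path)
        np.testing.assert_allclose(back.psi, beat.psi)

    def test_surface_penetration_rejected(self):
        s = np.linspace(0, 1, 21)
        psi = np.full((21, 1), -np.radians(30.0))  # digs below the surface
        with pytest.raises(ValueError, match="penetrates"):
            BeatPattern(s, np.array([0.0]), psi)
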