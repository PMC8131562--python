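"""Recording I/O, smoothing, centroids, differentiation, exposure points."""

import numpy as np
import pytest

import mriemf as m
from mriemf.kinematics import FormatError, fill_gaps

from conftest import rigid_translation_recording

RNG = np.random.default_rng(11)


def toy_recording(n=50, rate=100.0, labels=("M1", "M2")):
    return m.Recording(
        rate=rate,
        markers={lab: RNG.normal(size=(n, 3)) for lab in labels},
    )


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        rec = toy_recording(n=5)
        path = tmp_path / "rec.csv"
        m.write_recording_csv(rec, path)
        again = m.read_recording(path)
        assert again.rate == pytest.approx(rec.rate)
        for lab in rec.markers:
            np.testing.assert_allclose(again.markers[lab], rec.markers[lab], atol=1e-9)

    def test_trc_units_are_millimetres(self, tmp_path):
        # hand-written 2-frame TRC with a marker at 1000 mm -> 1 m
        path = tmp_path / "tiny.trc"
        path.write_text(
            "PathFileType\t4\t(X/Y/Z)\ttiny.trc\n"
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
            "100\t100\t2\t1\tmm\t100\t1\t2\n"
            "Frame#\tTime\tM1\n"
            "\t\tX1\tY1\tZ1\n"
            "1\t0.00000\t1000.0\t2000.0\t-500.0\n"
            "2\t0.01000\t1010.0\t2000.0\t-500.0\n"
        )
        rec = m.read_recording(path)
        np.testing.assert_allclose(rec.markers["M1"][0], [1.0, 2.0, -0.5])
        np.testing.assert_allclose(rec.markers["M1"][1], [1.01, 2.0, -0.5])

    def test_trc_round_trip(self, tmp_path):
        rec = toy_recording(n=20)
        path = tmp_path / "rec.trc"
        m.write_recording_trc(rec, path)
        again = m.read_recording(path)
        for lab in rec.markers:
            np.testing.assert_allclose(
                again.markers[lab], rec.markers[lab], atol=1e-7
            )

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "rec.xyz"
        path.write_text("junk")
        with pytest.raises(FormatError):
            m.read_recording(path)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            m.read_recording("/nonexistent/rec.csv")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            m.Recording(
                rate=100.0,
                markers={"A": np.zeros((5, 3)), "B": np.zeros((6, 3))},
            )


class TestSmoothing:
    def test_constant_series_unchanged(self):
        series = np.tile([1.0, -2.0, 0.5], (40, 1))
        out = m.smooth(series, rate=100.0)
        np.testing.assert_allclose(out, series, atol=1e-9)

    def test_passband_tone_preserved(self):
        # 1 Hz sinusoid through a 6 Hz low-pass: attenuation < 1%
        t = np.arange(500) / 100.0
        series = np.column_stack([np.sin(2 * np.pi * t), np.zeros_like(t), np.zeros_like(t)])
        out = m.smooth(series, rate=100.0)
        core = slice(50, -50)
        ratio = np.abs(out[core, 0]).max() / np.abs(series[core, 0]).max()
        assert 0.99 < ratio <= 1.001

    def test_high_frequency_noise_suppressed(self):
        # 1 Hz signal + 30 Hz noise: residual RMS reduced at least 5x
        t = np.arange(1000) / 100.0
        clean = np.sin(2 * np.pi * t)
        noisy = clean + 0.3 * np.sin(2 * np.pi * 30 * t)
        series = np.column_stack([noisy, np.zeros_like(t), np.zeros_like(t)])
        out = m.smooth(series, rate=100.0)
        rms_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_after = np.sqrt(np.mean((out[:, 0] - clean) ** 2))
        assert rms_after < rms_before / 5.0

    def test_zero_phase(self):
        # peak of a smoothed slow pulse is not shifted in time
        t = np.arange(300) / 100.0
        pulse = np.exp(-((t - 1.5) ** 2) / 0.08)
        series = np.column_stack([pulse, pulse, pulse])
        out = m.smooth(series, rate=100.0)
        assert abs(int(out[:, 0].argmax()) - int(pulse.argmax())) <= 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            m.smooth(np.zeros((4, 3)), rate=100.0)

    def test_spline_mode_smooths(self):
        t = np.arange(200) / 100.0
        series = np.column_stack([np.sin(2 * np.pi * t)] * 3)
        noisy = series + RNG.normal(0, 0.01, series.shape)
        out = m.smooth(noisy, rate=100.0, method="spline")
        assert np.sqrt(np.mean((out - series) ** 2)) < np.sqrt(
            np.mean((noisy - series) ** 2)
        )


class TestGaps:
    def test_short_gap_interpolated(self):
        series = np.linspace(0, 1, 20)[:, None] * np.ones(3)
        series[5:8] = np.nan
        filled = fill_gaps(series)
        np.testing.assert_allclose(filled, np.linspace(0, 1, 20)[:, None] * np.ones(3))

    def test_long_gap_rejected(self):
        series = np.zeros((30, 3))
        series[5:17] = np.nan
        with pytest.raises(ValueError, match="gap"):
            fill_gaps(series)


class TestCentroid:
    def test_coincident_markers(self):
        p = np.tile([0.3, 0.4, 1.1], (10, 1))
        rec = m.Recording(rate=100.0, markers={"A": p, "B": p, "C": p})
        np.testing.assert_allclose(m.cluster_centroid(rec, ["A", "B", "C"]), p)

    def test_tetrahedron_centroid(self):
        pts = {
            "A": [0.0, 0.0, 0.0],
            "B": [1.0, 0.0, 0.0],
            "C": [0.0, 1.0, 0.0],
            "D": [0.0, 0.0, 1.0],
        }
        rec = m.Recording(
            rate=100.0,
            markers={k: np.tile(v, (6, 1)) for k, v in pts.items()},
        )
        c = m.cluster_centroid(rec, list(pts))
        np.testing.assert_allclose(c, np.tile([0.25, 0.25, 0.25], (6, 1)))

    def test_matches_per_coordinate_loop(self):
        rec = toy_recording(n=30, labels=("A", "B", "C", "D", "E"))
        c = m.cluster_centroid(rec, rec.labels)
        for t in range(30):
            for k in range(3):
                expected = sum(rec.markers[lab][t, k] for lab in rec.labels) / 5
                assert c[t, k] == pytest.approx(expected, abs=1e-12)

    def test_translation_linearity(self):
        rec = toy_recording(n=15, labels=("A", "B", "C"))
        shift = np.array([0.5, -1.0, 2.0])
        shifted = m.Recording(
            rate=rec.rate,
            markers={lab: arr + shift for lab, arr in rec.markers.items()},
        )
        np.testing.assert_allclose(
            m.cluster_centroid(shifted, rec.labels),
            m.cluster_centroid(rec, rec.labels) + shift,
            atol=1e-12,
        )

    def test_small_cluster_rejected(self):
        rec = toy_recording(labels=("A", "B"))
        with pytest.raises(ValueError):
            m.cluster_centroid(rec, ["A", "B"])


class TestDifferentiate:
    def test_static_series(self):
        v = m.differentiate(np.tile([1.0, 2.0, 3.0], (20, 1)), rate=100.0)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_uniform_motion_exact_interior(self):
        t = np.arange(50) / 100.0
        series = np.column_stack([0.5 * t, np.zeros_like(t), np.zeros_like(t)])
        v = m.differentiate(series, rate=100.0)
        np.testing.assert_allclose(v[:, 0], 0.5, atol=1e-12)
        np.testing.assert_allclose(v[:, 1:], 0.0, atol=1e-12)

    def test_sinusoid_against_analytic_derivative(self):
        # central differences of sin(wt) carry a truncation error of
        # w^3 h^2 / 6 at peak; at 1 Hz / 100 Hz that is 4.13e-3 m/s
        t = np.arange(300) / 100.0
        series = np.column_stack([np.sin(2 * np.pi * t), np.zeros_like(t), np.zeros_like(t)])
        v = m.differentiate(series, rate=100.0)
        analytic = 2 * np.pi * np.cos(2 * np.pi * t)
        bound = (2 * np.pi) ** 3 * 0.01**2 / 6.0
        assert np.abs(v[1:-1, 0] - analytic[1:-1]).max() < 1.05 * bound

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            m.differentiate(np.zeros((2, 3)), rate=100.0)


class TestExposurePoints:
    def test_static_posture_speeds_vanish(self, standstill_recording):
        kin = m.extract_exposure_points(standstill_recording)
        assert kin.positions.shape[1] == 23
        assert kin.speeds.max() < 1e-6

    def test_rigid_translation_speeds(self):
        kin = m.extract_exposure_points(rigid_translation_recording(speed=1.0))
        # zero-phase filtering leaves a small transient at the record edges
        interior = kin.speeds[20:-20]
        assert interior.min() > 0.99 and interior.max() < 1.01
        assert kin.speeds.min() > 0.98 and kin.speeds.max() < 1.02

    def test_point_count_and_head_subset(self, n1_kinematics):
        assert n1_kinematics.positions.shape[1] == 23
        assert len(n1_kinematics.point_set.head_indices) == 5
        # head subset is points 1, 12, 13, 14, 15 (0-based 0, 11..14)
        np.testing.assert_array_equal(
            n1_kinematics.point_set.head_indices, [0, 11, 12, 13, 14]
        )

    def test_speed_rotation_invariance(self):
        rec = rigid_translation_recording(speed=0.8, n=120)
        theta = 0.83
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = m.Recording(
            rate=rec.rate,
            markers={lab: arr @ R.T for lab, arr in rec.markers.items()},
        )
        s1 = m.extract_exposure_points(rec).speeds
        s2 = m.extract_exposure_points(rotated).speeds
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_smoothed_derivative_tracks_band_limited_signal(self):
        # <= 3 Hz content: pipeline derivative within 2% RMS of analytic
        rec = rigid_translation_recording(speed=0.0, n=600)
        t = np.arange(600) / 100.0
        wobble = 0.05 * np.sin(2 * np.pi * 2.5 * t)
        markers = {
            lab: arr + np.column_stack([wobble, 0 * t, 0 * t])
            for lab, arr in rec.markers.items()
        }
        kin = m.extract_exposure_points(m.Recording(rate=100.0, markers=markers))
        v_analytic = 0.05 * 2 * np.pi * 2.5 * np.cos(2 * np.pi * 2.5 * t)
        core = slice(50, -50)
        err = kin.velocities[core, 0, 0] - v_analytic[core]
        rms_rel = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(v_analytic[core] ** 2))
        assert rms_rel < 0.02

    def test_missing_marker_names_the_point(self, standstill_recording):
        markers = dict(standstill_recording.markers)
        markers.pop("RASI")
        rec = m.Recording(rate=100.0, markers=markers)
        with pytest.raises(KeyError, match="pelvis|RASI|20"):
            m.extract_exposure_points(rec)
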