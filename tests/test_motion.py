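"""Jenkinson displacement metric, realignment parsing, motion summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinmotion.motion import (
    AffineTransform,
    MotionParseError,
    MotionSummarizer,
    RigidMotionSeries,
    framewise_series,
    gross_motion_flag,
    jenkinson_displacement,
    params_to_affine,
    read_realignment_series,
    reference_series,
    summarize_cohort,
    summarize_subject_motion,
    write_realignment_series,
)

I4 = AffineTransform(np.eye(4))

angles = st.floats(-0.4, 0.4)
shifts = st.floats(-5, 5)


def rigid(t, r):
    return params_to_affine(t, r)


class TestAffine:
    def test_identity(self):
        T = params_to_affine((0, 0, 0), (0, 0, 0))
        assert np.allclose(T.matrix, np.eye(4))

    def test_pure_translation(self):
        T = params_to_affine((3, 0, 0), (0, 0, 0))
        assert np.allclose(T.rotation, np.eye(3))
        assert np.allclose(T.translation, [3, 0, 0])

    def test_z_rotation_against_independent_composition(self):
        # oracle: direct 2-D rotation of the x unit vector by +90 degrees
        T = params_to_affine((0, 0, 0), (0, 0, math.pi / 2))
        assert np.allclose(T.rotation @ np.array([1.0, 0, 0]), [0, 1, 0], atol=1e-12)

    @given(tx=shifts, ty=shifts, tz=shifts, rx=angles, ry=angles, rz=angles)
    @settings(max_examples=40, deadline=None)
    def test_rotation_block_orthonormal(self, tx, ty, tz, rx, ry, rz):
        T = params_to_affine((tx, ty, tz), (rx, ry, rz))
        assert np.allclose(T.rotation @ T.rotation.T, np.eye(3), atol=1e-10)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            params_to_affine((np.nan, 0, 0), (0, 0, 0))


class TestJenkinson:
    def test_equal_transforms_zero(self):
        T = rigid((1, 2, 3), (0.01, -0.02, 0.03))
        assert jenkinson_displacement(T, T) == pytest.approx(0.0, abs=1e-10)

    def test_pure_translation_is_euclidean_norm_exactly(self):
        T2 = rigid((3, 0, 0), (0, 0, 0))
        assert jenkinson_displacement(I4, T2) == 3.0
        T2 = rigid((1, 2, 2), (0, 0, 0))
        assert jenkinson_displacement(I4, T2) == pytest.approx(3.0, abs=1e-12)

    def test_two_degree_rotation_closed_form(self):
        # sqrt((1/5) R^2 * 4 (1 - cos 2deg)) for a rotation through the centre
        th = math.radians(2.0)
        T2 = rigid((0, 0, 0), (0, 0, th))
        expected = math.sqrt(0.2 * 80.0**2 * 4.0 * (1 - math.cos(th)))
        assert jenkinson_displacement(I4, T2) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.766, abs=5e-4)

    @given(
        tx=shifts, ty=shifts, rz=angles, rx=angles,
        cx=st.floats(-20, 20), cy=st.floats(-20, 20),
    )
    @settings(max_examples=25, deadline=None)
    def test_monte_carlo_rms_oracle(self, tx, ty, rz, rx, cx, cy):
        """The metric equals the RMS displacement of points uniform in the
        radius-80 ball centred at x_c, within MC error."""
        T2 = rigid((tx, ty, 0.0), (rx, 0.0, rz))
        center = np.array([cx, cy, 0.0])
        d = jenkinson_displacement(I4, T2, radius=80.0, center=center)
        rng = np.random.default_rng(1234)
        pts = rng.normal(size=(120_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= 80.0 * rng.random(120_000)[:, None] ** (1 / 3)
        pts += center
        hom = np.hstack([pts, np.ones((len(pts), 1))])
        disp = hom @ T2.matrix.T - hom
        rms = float(np.sqrt(np.mean(np.sum(disp[:, :3] ** 2, axis=1))))
        assert d == pytest.approx(rms, rel=0.01)

    @given(tx=shifts, rz=angles, sx=st.floats(-30, 30))
    @settings(max_examples=25, deadline=None)
    def test_world_shift_invariance(self, tx, rz, sx):
        """Expressing both frames in a shifted world frame while shifting
        x_c consistently leaves the metric unchanged."""
        T1, T2 = I4, rigid((tx, 0, 0), (0, 0, rz))
        shift = np.eye(4)
        shift[:3, 3] = [sx, 0, 0]
        S = AffineTransform(shift)
        Sinv = AffineTransform(np.linalg.inv(shift))
        T1s = AffineTransform(S.matrix @ T1.matrix @ Sinv.matrix)
        T2s = AffineTransform(S.matrix @ T2.matrix @ Sinv.matrix)
        d0 = jenkinson_displacement(T1, T2, center=(1.0, 2.0, 3.0))
        d1 = jenkinson_displacement(T1s, T2s, center=(1.0 + sx, 2.0, 3.0))
        assert d0 == pytest.approx(d1, abs=1e-8)

    def test_nonnegative_and_zero_iff_identity(self):
        T2 = rigid((1e-3, 0, 0), (0, 1e-4, 0))
        assert jenkinson_displacement(I4, T2) > 0


def make_series(params, dialect="spm"):
    arr = np.asarray(params, dtype=float)
    return RigidMotionSeries("s", arr[:, :3], arr[:, 3:], dialect=dialect)


class TestFramewise:
    def test_all_zero_series(self):
        s = make_series(np.zeros((150, 6)))
        fw = framewise_series(s)
        assert fw.shape == (149,)
        assert np.allclose(fw, 0.0)

    def test_single_spike_two_transitions(self):
        params = np.zeros((10, 6))
        params[4, 0] = 3.0
        fw = framewise_series(make_series(params))
        nz = np.nonzero(fw > 1e-12)[0]
        assert list(nz) == [3, 4]
        assert fw[3] == pytest.approx(3.0, abs=1e-10)
        assert fw[4] == pytest.approx(3.0, abs=1e-10)

    def test_monotone_drift_constant_increments(self):
        params = np.zeros((20, 6))
        params[:, 0] = 0.1 * np.arange(20)
        fw = framewise_series(make_series(params))
        assert np.allclose(fw, 0.1, atol=1e-12)

    def test_reference_series_alternative(self):
        params = np.zeros((5, 6))
        params[:, 0] = [0, 1, 2, 3, 4]
        rs = reference_series(make_series(params))
        assert np.allclose(rs, [1, 2, 3, 4])


class TestFlagsAndSummary:
    def test_gross_motion_threshold_strict(self):
        params = np.zeros((5, 6))
        params[2, 4] = math.radians(2.0)  # exactly 2 degrees: not flagged
        assert not gross_motion_flag(make_series(params))
        params[2, 4] = math.radians(2.001)
        assert gross_motion_flag(make_series(params))

    def test_gross_motion_translation(self):
        params = np.zeros((5, 6))
        params[3, 1] = 3.1
        assert gross_motion_flag(make_series(params))
        params[3, 1] = 3.0
        assert not gross_motion_flag(make_series(params))

    def test_summary_constant_series(self):
        params = np.zeros((11, 6))
        params[:, 0] = 0.1 * np.arange(11)
        s = summarize_subject_motion(make_series(params))
        assert s.mean_displacement == pytest.approx(0.1, abs=1e-12)
        assert s.log_displacement == pytest.approx(math.log(0.1), abs=1e-10)
        assert not s.gross_motion

    def test_sd_outlier_rule(self):
        params = np.zeros((11, 6))
        params[:, 0] = np.linspace(0, 1, 11)
        rng = np.random.default_rng(0)
        cohort = -2.59 + 0.35 * rng.standard_normal(500)
        subj = summarize_subject_motion(make_series(params), cohort_log_values=cohort)
        # a subject 5.4 cohort sds out is flagged, but flagged-only
        target = cohort.mean() + 5.4 * cohort.std(ddof=1)
        params2 = np.zeros((11, 6))
        params2[:, 0] = math.exp(target) * np.arange(11)
        subj2 = summarize_subject_motion(make_series(params2), cohort_log_values=cohort)
        assert subj2.sd_outlier
        assert not subj.sd_outlier

    def test_gross_motion_subject_still_summarised(self):
        params = np.zeros((5, 6))
        params[2, 0] = 5.0
        s = summarize_subject_motion(make_series(params))
        assert s.gross_motion and s.mean_displacement > 0

    def test_zero_motion_floor_warns(self):
        with pytest.warns(UserWarning, match="floor"):
            s = summarize_subject_motion(make_series(np.zeros((5, 6))))
        assert s.log_displacement == pytest.approx(math.log(1e-6))


class TestIO:
    def test_spm_column_mapping(self, tmp_path):
        f = tmp_path / "rp_sub1.txt"
        f.write_text("0 0 0 0 0 0\n3 0 0 0 0 0\n")
        s = read_realignment_series(f, dialect="spm")
        assert s.subject_id == "sub1"
        assert np.allclose(s.translations[1], [3, 0, 0])
        assert np.allclose(s.rotations[1], 0)

    def test_fsl_column_mapping_warns_on_implausible_rotation(self, tmp_path):
        f = tmp_path / "sub2.par"
        f.write_text("0 0 0 0 0 0\n3 0 0 0 0 0\n")
        with pytest.warns(UserWarning, match="rotation"):
            s = read_realignment_series(f, dialect="fsl")
        assert np.allclose(s.rotations[1], [3, 0, 0])
        assert np.allclose(s.translations[1], 0)

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "rp_bad.txt"
        f.write_text("0 0 0 0 0 0\n1 2 3 4 5\n")
        with pytest.raises(MotionParseError, match="line 2"):
            read_realignment_series(f)

    def test_too_few_frames(self, tmp_path):
        f = tmp_path / "rp_one.txt"
        f.write_text("0 0 0 0 0 0\n")
        with pytest.raises(MotionParseError, match="at least 2"):
            read_realignment_series(f)

    @pytest.mark.parametrize("dialect", ["spm", "fsl"])
    def test_round_trip_bitwise_summary(self, tmp_path, dialect):
        rng = np.random.default_rng(3)
        params = np.zeros((30, 6))
        params[1:, :3] = np.cumsum(rng.normal(0, 0.05, (29, 3)), axis=0)
        params[1:, 3:] = np.cumsum(rng.normal(0, 0.001, (29, 3)), axis=0)
        s = RigidMotionSeries("x", params[:, :3], params[:, 3:], dialect=dialect)
        f = tmp_path / ("rp_x.txt" if dialect == "spm" else "x.par")
        write_realignment_series(s, f)
        s2 = read_realignment_series(f, dialect=dialect)
        a = summarize_subject_motion(s)
        b = summarize_subject_motion(s2)
        assert a.mean_displacement == b.mean_displacement
        assert a.log_displacement == b.log_displacement


class TestSummarizer:
    def test_transform_table_and_params(self):
        rng = np.random.default_rng(0)
        series = []
        for i in range(4):
            params = np.zeros((20, 6))
            params[1:, 0] = np.cumsum(rng.normal(0, 0.05, 19))
            series.append(RigidMotionSeries(f"s{i}", params[:, :3], params[:, 3:]))
        tr = MotionSummarizer(statistic="median")
        out = tr.fit_transform(series)
        assert list(out["subject_id"]) == ["s0", "s1", "s2", "s3"]
        assert (out["mean_displacement_mm"] >= 0).all()
        assert tr.get_params()["statistic"] == "median"
        tr.set_params(radius=50.0)
        out2 = tr.transform(series)
        assert (out2["mean_displacement_mm"] <= out["mean_displacement_mm"] + 1e-12).all()

    def test_cohort_table_columns(self):
        params = np.zeros((5, 6))
        params[2, 0] = 1.0
        out = summarize_cohort([make_series(params)])
        assert {
            "subject_id", "n_frames", "mean_displacement_mm", "log_displacement",
            "max_abs_translation_mm", "max_abs_rotation_deg", "gross_motion", "sd_outlier",
        } <= set(out.columns)
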