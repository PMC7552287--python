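"""Cardiac geometry: closed forms, voxel oracle, automated diameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemopulse import (
    HeartGeometry,
    cardiac_output,
    compute_metrics,
    ejection_fraction,
    ellipsoid_volume,
    fractional_shortening,
    stroke_volume,
)


def voxel_ellipsoid_volume(dl: float, ds: float, h: float = 0.5) -> float:
    """Independent oracle: count h-um voxels whose centre lies inside the
    prolate spheroid with long diameter dl and short diameters ds."""
    a, b = dl / 2.0, ds / 2.0
    x = np.arange(h / 2, a + h, h)
    y = np.arange(h / 2, b + h, h)
    z = np.arange(h / 2, b + h, h)
    inside = ((x[:, None] / a) ** 2 + (y[None, :] / b) ** 2)[:, :, None] + (
        z[None, None, :] / b
    ) ** 2 <= 1.0
    return 8.0 * inside.sum() * h**3  # octant symmetry


class TestFractionalShortening:
    def test_no_contraction_is_zero(self):
        assert fractional_shortening(100.0, 100.0, "paper") == 0.0
        assert fractional_shortening(100.0, 100.0, "standard") == 0.0

    def test_hand_arithmetic(self):
        assert fractional_shortening(110.0, 100.0, "paper") == pytest.approx(10.0)
        assert fractional_shortening(110.0, 100.0, "standard") == pytest.approx(100.0 / 11)

    def test_systolic_denominator_convention(self):
        assert fractional_shortening(120.0, 80.0, "paper") == pytest.approx(50.0)
        assert fractional_shortening(120.0, 80.0, "standard") == pytest.approx(100.0 / 3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fractional_shortening(0.0, 100.0)


class TestEllipsoidVolume:
    def test_closed_form_small(self):
        assert ellipsoid_volume(2.0, 1.0) == pytest.approx(np.pi / 3)
        assert ellipsoid_volume(2.0, 1.0, include_pi=False) == pytest.approx(1.0 / 3)

    def test_sphere_limit(self):
        d = 7.0
        assert ellipsoid_volume(d, d) == pytest.approx(np.pi / 6 * d**3)

    def test_voxel_oracle(self):
        v = ellipsoid_volume(300.0, 150.0)
        oracle = voxel_ellipsoid_volume(300.0, 150.0)
        assert v == pytest.approx(oracle, rel=0.01)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.floats(min_value=50, max_value=400),
        st.floats(min_value=20, max_value=300),
        st.floats(min_value=1.01, max_value=3.0),
    )
    def test_monotone_and_cubic_scaling(self, dl, ds, k):
        v = ellipsoid_volume(dl, ds)
        assert ellipsoid_volume(k * dl, ds) > v
        assert ellipsoid_volume(dl, k * ds) > v
        assert ellipsoid_volume(k * dl, k * ds) == pytest.approx(k**3 * v, rel=1e-12)


class TestVolumesAndOutput:
    def test_stroke_volume_trivial(self):
        assert stroke_volume(100.0, 100.0) == 0.0
        assert stroke_volume(100.0, 40.0) == 60.0

    def test_negative_sv_flagged_not_raised(self):
        with pytest.warns(UserWarning, match="negative stroke volume"):
            assert stroke_volume(40.0, 100.0) == -60.0

    def test_sv_composes_with_volumes(self):
        edv = ellipsoid_volume(300.0, 150.0)
        esv = ellipsoid_volume(280.0, 120.0)
        assert stroke_volume(edv, esv) == pytest.approx(edv - esv)

    def test_ejection_fraction(self):
        assert ejection_fraction(100.0, 100.0) == 100.0
        assert ejection_fraction(40.0, 100.0) == 40.0
        with pytest.raises(ValueError):
            ejection_fraction(10.0, 0.0)

    def test_ef_bounded_when_esv_within_edv(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            edv = rng.uniform(1e5, 1e7)
            esv = rng.uniform(0, edv)
            ef = ejection_fraction(stroke_volume(edv, esv), edv)
            assert 0.0 <= ef <= 100.0

    def test_cardiac_output_units(self):
        """0.5 nL per beat at 600 bpm is 300 nL/min."""
        assert cardiac_output(5e5, 600.0) == pytest.approx(3e8)
        assert cardiac_output(0.0, 999.0) == 0.0
        assert cardiac_output(5e5, 300.0) == pytest.approx(cardiac_output(5e5, 600.0) / 2)


class TestHeartGeometryType:
    def test_systolic_larger_than_diastolic_warns(self):
        with pytest.warns(UserWarning, match="exceeds diastolic"):
            HeartGeometry(dl_d=300, ds_d=120, dl_s=280, ds_s=150)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="ds_s"):
            HeartGeometry(dl_d=300, ds_d=150, dl_s=280, ds_s=0)


class TestMeasureDiameters:
    def test_recovers_programmed_axes(self, heart_600):
        from hemopulse import RectROI, detect_beats, extract_trace, measure_diameters
        from conftest import full_roi

        stack, truth = heart_600
        roi = full_roi(stack)
        beats = detect_beats(extract_trace(stack, roi))
        geom = measure_diameters(stack, roi, beats)
        assert geom.dl_d == pytest.approx(300.0, rel=0.05)
        assert geom.ds_d == pytest.approx(150.0, rel=0.05)
        assert geom.dl_s == pytest.approx(280.0, rel=0.05)
        assert geom.ds_s == pytest.approx(120.0, rel=0.05)

    def test_static_heart_not_beating(self):
        """A non-contracting chamber gives FS ~ 0 regardless of beat labels."""
        from hemopulse import (
            BeatSeries,
            FrameStack,
            HeartSimParams,
            RectROI,
            measure_diameters,
            simulate_heart,
        )

        params = HeartSimParams(
            rate_bpm=600.0, duration_s=2.0, dl_s=300.0, ds_s=150.0, seed=41
        )  # systolic axes equal diastolic -> no motion
        stack, _ = simulate_heart(params)
        h, w = stack.frame_shape
        beats = BeatSeries(beat_times=np.arange(5) * 0.1 + 0.05)
        geom = measure_diameters(stack, RectROI(0, 0, w, h), beats)
        assert geom.dl_d == pytest.approx(geom.dl_s, rel=0.01)
        fs = fractional_shortening(geom.ds_d, geom.ds_s)
        assert abs(fs) < 2.0

    def test_empty_roi_not_segmentable(self):
        from hemopulse import BeatSeries, FrameStack, RectROI, measure_diameters

        frames = np.full((20, 40, 40), 200, dtype=np.uint16)
        stack = FrameStack(frames, fps=200, pixel_size_um=1.0)
        beats = BeatSeries(beat_times=np.array([0.02, 0.05, 0.08]))
        with pytest.raises(ValueError, match="not segmentable"):
            measure_diameters(stack, RectROI(0, 0, 40, 40), beats)


class TestFullPipeline:
    def test_cardiac_output_matches_programmed(self, heart_600):
        """CO from video-measured geometry and detected rate agrees with the
        generator's programmed stroke volume x rate within 10%."""
        from hemopulse import detect_beats, extract_trace, heart_rate, measure_diameters
        from conftest import full_roi

        stack, truth = heart_600
        roi = full_roi(stack)
        beats = detect_beats(extract_trace(stack, roi))
        geom = measure_diameters(stack, roi, beats)
        metrics = compute_metrics(geom, heart_rate(beats))
        co_true = truth.sv_um3 * truth.rate_bpm
        assert metrics.co_um3_min == pytest.approx(co_true, rel=0.10)
        assert metrics.sv_um3 == pytest.approx(truth.sv_um3, rel=0.10)
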