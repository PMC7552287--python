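"""LoG spot detection, track linking, and velocity summaries."""

import numpy as np
import pytest

from hemopulse import (
    Spot,
    Track,
    TrackSet,
    detect_spots,
    link_tracks,
    summarize_velocity,
)


def render_blobs(centers, shape=(100, 100), sigma=2.0, amp=100.0, bg=200.0, dark=True):
    """Gaussian blobs at sub-pixel centres (x, y) on a flat background."""
    Y, X = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, bg, dtype=float)
    for cx, cy in centers:
        g = amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))
        img = img - g if dark else img + g
    return img


class TestDetectSpots:
    def test_blank_frame_empty(self):
        assert detect_spots(np.full((50, 50), 100.0), sigma_px=2.0, threshold=1.0) == []

    def test_single_blob_subpixel_localization(self):
        """A matched-scale blob at (50.3, 40.7) is found within 0.5 px."""
        img = render_blobs([(50.3, 40.7)], sigma=2.0)
        spots = detect_spots(img, sigma_px=2.0, polarity="dark")
        assert len(spots) == 1
        assert abs(spots[0].x - 50.3) <= 0.5
        assert abs(spots[0].y - 40.7) <= 0.5
        assert spots[0].radius_px == pytest.approx(np.sqrt(2) * 2.0)

    def test_two_blobs_not_merged(self):
        img = render_blobs([(30.0, 50.0), (50.0, 50.0)], sigma=2.0)
        spots = detect_spots(img, sigma_px=2.0, polarity="dark")
        assert len(spots) == 2

    def test_bright_polarity(self):
        img = render_blobs([(25.0, 25.0)], dark=False)
        assert len(detect_spots(img, sigma_px=2.0, polarity="bright")) == 1
        # wrong polarity finds nothing at the blob
        wrong = detect_spots(img, sigma_px=2.0, polarity="dark")
        assert all(np.hypot(s.x - 25, s.y - 25) > 3 for s in wrong)

    def test_background_offset_invariance(self):
        """Adding a constant background leaves the detection count unchanged."""
        img = render_blobs([(30.0, 30.0), (70.0, 60.0)])
        a = detect_spots(img, sigma_px=2.0, polarity="dark")
        b = detect_spots(img + 500.0, sigma_px=2.0, polarity="dark")
        assert len(a) == len(b) == 2

    def test_response_maximal_at_matched_scale_centre(self):
        from hemopulse.flowtrack import _log_response

        img = render_blobs([(50.0, 50.0)], sigma=2.0)
        resp = _log_response(img, 2.0, "dark")
        y, x = np.unravel_index(np.argmax(resp), resp.shape)
        assert (x, y) == (50, 50)

    def test_sigma_too_small_rejected(self):
        with pytest.raises(ValueError, match="sigma_px"):
            detect_spots(np.zeros((10, 10)), sigma_px=0.2)


def spots_from_positions(frames_positions):
    """Build per-frame Spot lists from {frame: [(x, y), ...]} input."""
    out = []
    for k, positions in enumerate(frames_positions):
        out.append(
            [Spot(frame=k, x=x, y=y, response=1.0, radius_px=3.0) for x, y in positions]
        )
    return out


class TestLinkTracks:
    def test_two_constant_velocity_particles(self):
        frames = [[(10.0 + 2 * k, 20.0), (10.0 + 2 * k, 50.0)] for k in range(6)]
        ts = link_tracks(spots_from_positions(frames), max_disp_px=5, min_track_len=3)
        assert ts.n_tracks == 2
        for tr in ts.tracks:
            steps = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
            np.testing.assert_allclose(steps, 2.0)

    def test_gap_bridging(self):
        """A particle dark for one frame stays a single track with max_gap=1."""
        frames = []
        for k in range(7):
            if k == 3:
                frames.append([])
            else:
                frames.append([(10.0 + 2 * k, 20.0)])
        ts = link_tracks(spots_from_positions(frames), max_disp_px=5, max_gap=1)
        assert ts.n_tracks == 1
        assert ts.tracks[0].n_spots == 6

    def test_no_bridge_beyond_max_gap(self):
        frames = []
        for k in range(9):
            if k in (3, 4):
                frames.append([])
            else:
                frames.append([(10.0 + 2 * k, 20.0)])
        ts = link_tracks(spots_from_positions(frames), max_disp_px=5, max_gap=1,
                         min_track_len=3)
        assert ts.n_tracks == 2

    def test_crossing_particles_terminate_not_swap(self):
        """With a gate below the approach distance, tracks end rather than jump."""
        # two particles converge to the same point then diverge; gate < jump
        frames = []
        for k in range(8):
            xa = 10.0 + 8 * k
            xb = 66.0 - 8 * k
            frames.append([(xa, 20.0), (xb, 20.0)] if xa != xb else [(xa, 20.0)])
        ts = link_tracks(spots_from_positions(frames), max_disp_px=9, max_gap=0,
                         min_track_len=2)
        # every step within every recovered track stays within the gate
        for tr in ts.tracks:
            steps = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
            assert (steps <= 9.0).all()

    def test_min_track_len_filters(self):
        frames = [[(10.0, 10.0)], [(12.0, 10.0)], [], [], []]
        ts = link_tracks(spots_from_positions(frames), max_disp_px=5, max_gap=0,
                         min_track_len=3)
        assert ts.n_tracks == 0


class TestSummarizeVelocity:
    def test_constant_speed_closed_form(self):
        """2 px/frame at 1 um/px and 200 fps is exactly 400 um/s."""
        frames = [[(10.0 + 2 * k, 20.0)] for k in range(5)]
        ts = link_tracks(spots_from_positions(frames), max_disp_px=5)
        s = summarize_velocity(ts, pixel_size_um=1.0, fps=200.0)
        assert s.v_max == pytest.approx(400.0)
        assert s.v_mean == pytest.approx(400.0)
        assert s.v_min == pytest.approx(400.0)
        assert s.n_steps == 4

    def test_calibration_linearity(self):
        frames = [[(10.0 + 1.5 * k, 20.0)] for k in range(5)]
        ts = link_tracks(spots_from_positions(frames), max_disp_px=5)
        s1 = summarize_velocity(ts, pixel_size_um=1.0, fps=200.0)
        s2 = summarize_velocity(ts, pixel_size_um=2.0, fps=200.0)
        assert s2.v_mean == pytest.approx(2 * s1.v_mean)
        assert s2.v_max == pytest.approx(2 * s1.v_max)

    def test_ordering_invariant(self, flow_pulsatile):
        from hemopulse import detect_spots_stack

        stack, _ = flow_pulsatile
        spots = detect_spots_stack(stack.frames[:40], sigma_px=2.5, polarity="dark")
        ts = link_tracks(spots, max_disp_px=15)
        s = summarize_velocity(ts, stack.pixel_size_um, stack.fps)
        assert 0 <= s.v_min <= s.v_mean <= s.v_max

    def test_no_tracks_rejected(self):
        with pytest.raises(ValueError, match="no trackable"):
            summarize_velocity(TrackSet(tracks=[]), 1.0, 200.0)


class TestTrackingRecovery:
    @pytest.mark.parametrize("n_cells", [5, 20])
    def test_identity_and_speed_recovery(self, n_cells):
        """Well-separated corridors: every track matches one truth cell and
        per-step speeds agree with the generator's within 5%."""
        from hemopulse import FlowSimParams, detect_spots_stack, simulate_flow

        stack, truth = simulate_flow(
            FlowSimParams(n_cells=n_cells, mean_speed_um_s=800.0, duration_s=0.4, seed=31)
        )
        spots = detect_spots_stack(stack.frames, sigma_px=2.5, polarity="dark")
        ts = link_tracks(spots, max_disp_px=15)
        assert ts.n_tracks == n_cells
        for tr in ts.tracks:
            ids = set()
            for f, p in zip(tr.frames, tr.positions):
                d = np.linalg.norm(truth.positions_px[f] - p, axis=1)
                ids.add(int(np.argmin(d)))
                assert d.min() < 1.0
            assert len(ids) == 1  # identity preserved along the whole track
            cell = ids.pop()
            est = tr.step_speeds(stack.pixel_size_um, stack.fps)
            true = truth.step_speeds_um_s[tr.frames[:-1], cell]
            np.testing.assert_allclose(est, true, rtol=0.05, atol=20.0)
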