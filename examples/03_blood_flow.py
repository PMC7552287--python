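"""Measure blood-flow velocity by tracking hemocytes.

Renders a thorax corridor with 12 hemocytes advecting at a pulsatile speed
(mean 1000 um/s, fully modulated by the heartbeat, so instantaneous speed
swings between ~0 and ~2000 um/s), detects them per frame with a
Laplacian-of-Gaussian filter, links detections into tracks, and reports the
pooled max/mean/min step speed — the per-animal summary.
"""

from hemopulse import (
    FlowSimParams,
    detect_spots_stack,
    link_tracks,
    simulate_flow,
    summarize_velocity,
)

params = FlowSimParams(
    n_cells=12, mean_speed_um_s=1000.0, pulsatility_frac=1.0, duration_s=1.0, seed=4
)
stack, truth = simulate_flow(params)

spots = detect_spots_stack(stack.frames, sigma_px=2.5, polarity="dark")
tracks = link_tracks(spots, max_disp_px=15, max_gap=1, min_track_len=3)
summary = summarize_velocity(tracks, stack.pixel_size_um, stack.fps)

pool = truth.pooled_speeds
print(f"tracks recovered: {summary.n_tracks} of {params.n_cells} cells "
      f"({summary.n_steps} steps pooled)")
print(f"v_max  {summary.v_max:7.1f} um/s   (truth {pool.max():7.1f})")
print(f"v_mean {summary.v_mean:7.1f} um/s   (truth {pool.mean():7.1f})")
print(f"v_min  {summary.v_min:7.1f} um/s   (truth {pool.min():7.1f})")
# v_max ~ 2x mean and v_min ~ 0 reflect the fully pulsatile drive; the
# estimates track the generator's frame-differenced truth to within a few
# percent (sub-pixel localization error times the frame rate).
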