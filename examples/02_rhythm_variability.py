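"""Quantify heart-rhythm regularity: Poincaré dispersion and STFT.

Two synthetic hearts at 600 bpm — one metronomic, one with 15 ms
beat-to-beat jitter (the kind of irregularity a cardiotoxic exposure
induces) — are compared on sdnn/sd1/sd2 and on the dominant spectral
frequency of the intensity trace.
"""

from hemopulse import (
    HeartSimParams,
    RectROI,
    detect_beats,
    extract_trace,
    regularity_report,
    simulate_heart,
    stft,
)


def analyze(label, interval_sd_s, seed):
    stack, _ = simulate_heart(
        HeartSimParams(rate_bpm=600.0, interval_sd_s=interval_sd_s, seed=seed)
    )
    h, w = stack.frame_shape
    trace = extract_trace(stack, RectROI(0, 0, w, h))
    beats = detect_beats(trace)
    rep = regularity_report(beats)
    spec = stft(trace, window_s=1.0, overlap_frac=0.75)
    print(f"{label}:")
    print(f"  sdnn {rep['sdnn_s']*1000:6.2f} ms   sd1 {rep['sd1_s']*1000:6.2f} ms   "
          f"sd2 {rep['sd2_s']*1000:6.2f} ms   CV {rep['cv_intervals']:.4f}")
    print(f"  dominant beat frequency: {spec.dominant_freq:.1f} Hz")


analyze("regular rhythm   (0 ms jitter)", 0.000, seed=2)
analyze("irregular rhythm (15 ms jitter)", 0.015, seed=3)
# Larger sdnn/sd1 mean a less regular rhythm; the dominant frequency stays
# at the programmed 10 Hz because jitter perturbs timing, not the rate.
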