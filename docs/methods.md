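# Methods

This note documents the measurement models behind `hemopulse`, the
parameters that matter, the synthetic scenes used for validation, and the
numerical choices made where the design was open.

## Signal model: heartbeat from dynamic pixel change

The daphnid heart is a single myogenic chamber. In transmitted light the
chamber region darkens as it fills (diastole) and brightens as hemocytes
are expelled (systole), so the mean intensity of a user-drawn heart ROI is
a periodic signal whose maxima mark systolic contractions.

`detect_beats` processes the trace in four steps:

1. **Linear detrend** — removes illumination drift over the 10 s record.
2. **Low-pass smoothing** — Gaussian, σ = 1/8 of the minimum admissible
   beat period (i.e. `60/max_rate_bpm/8` seconds; 6.25 ms at the default
   1200 bpm ceiling). This suppresses sample-to-sample noise while
   attenuating a 10 Hz beat by under 10%.
3. **Polarity normalization** — if the detrended trace's third moment is
   negative (sharp troughs rather than sharp peaks), the trace is negated,
   so systole-bright and systole-dark recordings behave identically.
4. **Prominence-gated peak picking** — local maxima with prominence ≥
   `prominence_frac` (default 0.25) of the robust signal range (2.5th–97.5th
   percentile span), separated by at least the refractory period
   `60/max_rate_bpm`. Peak times are refined by a 3-point parabolic fit,
   because at 200 fps the 5 ms frame quantum is 5% of a 0.1 s beat.

Defaults `min_rate_bpm=60`, `max_rate_bpm=1200` bracket reported cladoceran
rates (roughly 260–600 bpm across species and temperatures) with twofold
headroom; a detected rate outside the band attaches a warning rather than
failing, since the band is a plausibility check, not a constraint.

Two summary-rate estimators are exposed and never conflated: the mean of
per-beat rates `mean(60/I)` (default) and the reciprocal of the mean
interval `60/mean(I)`. By Jensen's inequality the former is ≥ the latter,
with equality only for a metronomic rhythm; published daphnid rates are
consistent with per-beat averaging, which is why it is the default.

**Known bias.** When the rhythm is strongly irregular, the intensity peak
of a beat is pulled slightly toward its longer neighboring interval (the
contraction waveform is wider there), and beats closer together than the
refractory period are merged. Both effects shrink the estimated interval
dispersion; at 20 ms programmed jitter on a 100 ms beat the recovered SDNN
runs ~10–15% low. This is a property of intensity-peak timing itself, not
of the implementation.

## Rhythm variability

Poincaré descriptors use population (1/N) normalization and the standard
variance decomposition: `SD1 = SD((I_{n+1}−I_n)/√2)`, `SDNN = SD(I)`, and
`SD2 = √(2·SDNN² − SD1²)`, so `SD1² + SD2² = 2·SDNN²` holds exactly. For
short, strongly anti-correlated sequences the SD2 argument can dip
marginally below zero and is clamped at 0. SDNN and SD1 are invariant to
adding a constant to all intervals and scale linearly with the intervals;
SDNN is order-free while SD1 responds to beat ordering.

The STFT uses a 1 s Hann window with 75% overlap by default, resolving the
4–10 Hz beat band at 200 Hz sampling with 1 Hz bins. Power is normalized
one-sided so that the per-segment bin sum equals the windowed-segment
energy exactly (Parseval; residual exposed on the result). It operates on
the intensity trace by default; `stft_intervals` offers a tachogram mode
(interval series resampled at 8 Hz) that targets slow rate modulation
instead of the beat frequency — the two answer different questions and are
kept separate deliberately. A trace with no measurable AC power is flagged
`dc_only` with `dominant_freq = NaN` rather than returning an arbitrary
bin.

## Blood flow: LoG detection and LAP linking

Hemocytes are blob-like and, in transmitted light, darker than the
translucent background (default `polarity='dark'`). Detection computes the
scale-normalized Laplacian-of-Gaussian response `σ²·∇²(G_σ∗I)` (sign chosen
by polarity), subtracts the response median — the discrete LoG kernel does
not sum exactly to zero, so a constant background otherwise leaves a
constant offset — and keeps local maxima above threshold with sub-pixel
centres from separable 3-point quadratic fits. The default threshold is 5×
the robust noise SD (1.4826·MAD) of the response, with a small floor so
noiseless synthetic frames never admit background plateaus. Default
`sigma_px=2.5` matches cells of radius ~3.5 px.

Linking solves, per frame, the bipartite assignment between open track
ends and new detections that minimizes total squared displacement
(`scipy.optimize.linear_sum_assignment`), admitting pairs within a gate
that grows linearly with the bridged gap (`max_disp_px` per elapsed frame,
≤ `max_gap=1` dark frames). Optimal assignment rather than greedy nearest
neighbor makes linking deterministic and order-independent. Defaults
`max_disp_px=15`, `min_track_len=3` cover flows up to ~2800 µm/s at
typical 1–2 µm/px calibrations and 200 fps.

Velocity summaries pool step speeds (`euclidean displacement × pixel size
× fps / frame gap`) across all of an animal's tracks, reporting the pooled
max/mean/min — one record per animal; a per-track mode exists. Absolute
velocities require the user's µm/pixel calibration: camera files do not
carry it reliably, so it is a required input everywhere, never guessed.

## Cardiac geometry

The chamber is modeled as a prolate spheroid: volume `π/6·D_L·D_S²`. A
literal mode computes `1/6·D_L·D_S²`, reproducing a published protocol's
printed prefactor without π; the default includes π because it is the
physically correct spheroid volume. Similarly, fractional shortening
defaults to the systolic-denominator form `(D_SD−D_SS)/D_SS×100` used by
that protocol, with the conventional echocardiographic diastolic
denominator behind `convention='standard'`. Ejection fraction is `SV/EDV ×
100` (bounded by 100 whenever ESV ≤ EDV). Volumes are reported in µm³ and
nL (1 nL = 10⁶ µm³).

`measure_diameters` automates the manual calliper step: systolic frames
are those nearest detected beat peaks; diastolic frames sit at inter-beat
midpoints, the maximally relaxed phase under any contraction waveform that
is symmetric about the beat. Each selected ROI frame is Otsu-thresholded,
the largest connected component kept (≥ 25 px, else "heart not
segmentable"), and an ellipse fitted by second moments — the same
estimator as ImageJ's ellipse fit. Averaging axes over each frame set
suppresses per-frame segmentation noise. Systolic exceeding diastolic
short diameter warns (phase assignment is suspect) but does not error,
matching how a technician would treat a noisy measurement.

## Synthetic scenes

The generators define the validation conditions; their defaults mirror the
source recording setup and are not tuned per test.

**Heart** (`simulate_heart`): 200 fps, 10 s, 2 µm/px; a dark ellipse
(diastolic 300 × 150 µm, systolic 280 × 120 µm, contrast 80 counts on a
200-count background, Gaussian pixel noise SD 2) whose axes follow a
raised-cosine contraction pulse occupying 30% of each cycle, centred on
the beat time — brief systole, long diastolic plateau, as in a myogenic
heart. Mean ROI intensity therefore peaks at systole. Beat intervals are
truncated Gaussian `max(0.02 s, N(60/rate, interval_sd_s))`. Edges are
logistic with a 1 px band (band-limited rendering keeps sub-pixel
localization meaningful). Truth records the exact beat schedule, per-frame
axes, and the programmed stroke volume.

**Flow** (`simulate_flow`): cells in parallel lanes 12 px apart advect
rightward with shared speed `s(t) = mean·(1 + pulsatility·sin(2πf t))`
(default f = 5 Hz), rendered as dark Gaussian blobs (σ = radius/√2); the
corridor is sized so no cell leaves the frame. Truth positions are exact;
truth step speeds are frame-differenced from them — the same
discretization a tracker sees — so tracker and truth are directly
comparable.

Neither scene includes limb-motion occlusion, carapace texture, focus
drift or illumination flicker; passing tests demonstrate correctness of
the measurement chain on clean geometry, not robustness to every live-
imaging artifact.

## Problem sizes and runtime

Validation runs use full-scale recordings where the measurement depends on
record length (10 s / 2000 frames for rate and variability recovery, ~100
beats) and shorter scenes where it does not (1 s corridors for tracking,
0.4 s for linking unit tests). The voxel oracle for the spheroid volume
uses 0.5 µm voxels with octant symmetry. The whole suite runs in well
under a minute of CPU.

## Statistics

Group summaries report mean ± SEM (sample SD, n−1); a single-value group
reports SEM as NaN. `compare_groups` is a two-sided Mann–Whitney U via
`scipy.stats.mannwhitneyu`: the exact null distribution for groups ≤ 8
without ties, otherwise the normal approximation with tie correction and
no continuity correction (keeping the approximation symmetric in U).
Relative-to-control normalization divides by the control-group mean, so
control maps to 1 exactly. No multiple-comparison adjustment is applied by
default; a Bonferroni factor is the caller's choice.

## Limitations

* Heart and flow ROIs are user-supplied; there is no automatic ROI
  discovery.
* Interval-dispersion estimates are biased low on strongly irregular
  rhythms (see above).
* AVI input is 8-bit and decode-dependent; TIFF is the lossless reference
  format.
* The spheroid model assumes rotational symmetry about the long axis; a
  flattened (scalene) chamber would need a third diameter the video does
  not provide.
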