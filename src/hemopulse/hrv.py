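"""Heart-rate-variability descriptors: Poincaré-plot dispersion and STFT.

A Poincaré plot scatters each inter-beat interval against the next; its
dispersion along and across the line of identity (SD2, SD1) separates
long-term from beat-to-beat variability. SDNN is the overall interval
standard deviation. All three use population (1/N) normalization and obey
``sd1^2 + sd2^2 = 2 * sdnn^2`` exactly.

The short-time Fourier transform of the heart-ROI intensity trace shows the
beat frequency band over time; the dominant frequency is the bin with the
largest total power. An interval-series mode exists for analyzing the
tachogram instead of the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heartbeat import BeatSeries, IntensityTrace

__all__ = ["PoincareSummary", "SpectrogramResult", "poincare", "stft", "regularity_report"]


@dataclass(frozen=True)
class PoincareSummary:
    """Poincaré-plot dispersion of an inter-beat-interval series (seconds)."""

    sd1: float  # short-axis: beat-to-beat dispersion
    sd2: float  # long-axis: dispersion along the line of identity
    sdnn: float  # overall interval SD
    n_pairs: int


def poincare(intervals: np.ndarray) -> PoincareSummary:
    """Poincaré descriptors of an interval sequence.

    With successive pairs ``(I_n, I_{n+1})``:

    * ``sd1 = SD((I_{n+1} - I_n) / sqrt(2))`` — dispersion perpendicular to
      the identity line;
    * ``sdnn`` — population SD of the interval series itself (order-free);
    * ``sd2 = sqrt(2 * sdnn^2 - sd1^2)`` — dispersion along the identity
      line, defined through the variance decomposition so that
      ``sd1^2 + sd2^2 = 2 * sdnn^2`` holds exactly.

    All SDs use population (1/N) normalization. For short, strongly
    anti-correlated sequences the decomposition argument ``2*sdnn^2 -
    sd1^2`` can dip marginally below zero; sd2 is clamped at 0 (a
    dispersion cannot be negative), in which case the identity holds as
    ``sd1^2 >= 2*sdnn^2`` up to that margin.
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.ndim != 1 or len(iv) < 2:
        raise ValueError(f"need >= 2 intervals, got {iv.shape}")
    x, y = iv[:-1], iv[1:]
    sd1 = float(np.std((y - x) / np.sqrt(2.0)))  # population SD
    sdnn = float(np.std(iv))
    sd2 = float(np.sqrt(max(0.0, 2.0 * sdnn**2 - sd1**2)))
    return PoincareSummary(sd1=sd1, sd2=sd2, sdnn=sdnn, n_pairs=len(x))


@dataclass
class SpectrogramResult:
    """Hann-windowed magnitude-squared spectrogram of a physiological signal.

    ``power[k, j]`` is normalized so that ``power[:, j].sum()`` equals the
    energy of windowed segment ``j`` (Parseval bookkeeping);
    ``dominant_freq`` is the frequency bin maximizing power summed over
    time, or NaN (with ``dc_only=True``) when the signal carries no
    measurable AC power.
    """

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    dominant_freq: float
    dc_only: bool = False
    segment_energies: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def parseval_residual(self) -> float:
        """Max relative mismatch between spectral and time-domain segment energy."""
        spectral = self.power.sum(axis=0)
        denom = np.maximum(self.segment_energies, np.finfo(float).tiny)
        return float(np.max(np.abs(spectral - self.segment_energies) / denom))


def stft(
    trace: IntensityTrace,
    window_s: float = 1.0,
    overlap_frac: float = 0.75,
) -> SpectrogramResult:
    """Short-time Fourier transform of the mean-subtracted intensity trace.

    Parameters
    ----------
    trace
        Uniformly sampled signal.
    window_s
        Hann window length in seconds. The default 1 s resolves a 4-10 Hz
        beat band at 200 Hz sampling with 1 Hz bins.
    overlap_frac
        Fractional overlap between consecutive windows, in [0, 1).
    """
    if not (0 <= overlap_frac < 1):
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    fs = trace.fs
    nperseg = int(round(window_s * fs))
    n = len(trace.v)
    if nperseg > n:
        raise ValueError(
            f"window of {nperseg} samples ({window_s} s) exceeds trace length {n}"
        )
    if nperseg < 4:
        raise ValueError(f"window too short: {nperseg} samples")
    hop = max(1, int(round(nperseg * (1.0 - overlap_frac))))

    x = trace.v - trace.v.mean()
    win = np.hanning(nperseg)

    starts = np.arange(0, n - nperseg + 1, hop)
    segs = np.stack([x[s : s + nperseg] * win for s in starts])
    X = np.fft.rfft(segs, axis=1)
    # One-sided |X|^2 scaled so the bin sum equals the windowed-segment energy.
    coef = np.full(X.shape[1], 2.0)
    coef[0] = 1.0
    if nperseg % 2 == 0:
        coef[-1] = 1.0
    power = (coef * np.abs(X) ** 2 / nperseg).T  # (freq, time)

    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    times = (starts + nperseg / 2.0) / fs + trace.t[0]
    seg_energy = (segs**2).sum(axis=1)

    total_by_freq = power.sum(axis=1)
    total_ac = total_by_freq[1:].sum()
    # Flag signals with essentially no AC content relative to float precision
    # of the raw signal energy.
    floor = (trace.v**2).sum() * len(starts) * 1e-12
    if total_ac <= floor:
        dominant = float("nan")
        dc_only = True
    else:
        dominant = float(freqs[1:][np.argmax(total_by_freq[1:])])
        dc_only = False
    return SpectrogramResult(
        freqs=freqs,
        times=times,
        power=power,
        dominant_freq=dominant,
        dc_only=dc_only,
        segment_energies=seg_energy,
    )


def stft_intervals(
    beats: BeatSeries, resample_hz: float = 8.0, window_s: float = 8.0, overlap_frac: float = 0.75
) -> SpectrogramResult:
    """STFT of the inter-beat-interval series (tachogram mode).

    The irregularly spaced intervals are linearly resampled at
    ``resample_hz`` before windowing. This mode targets slow modulation of
    the beat period rather than the beat frequency itself, and is not the
    default analysis.
    """
    iv = beats.intervals
    if len(iv) < 4:
        raise ValueError("need >= 4 intervals for a tachogram spectrum")
    t_mid = 0.5 * (beats.beat_times[:-1] + beats.beat_times[1:])
    t_uniform = np.arange(t_mid[0], t_mid[-1], 1.0 / resample_hz)
    if len(t_uniform) < 8:
        raise ValueError("interval record too short for tachogram resampling")
    v = np.interp(t_uniform, t_mid, iv)
    window_s = min(window_s, len(t_uniform) / resample_hz)
    return stft(IntensityTrace(t=t_uniform, v=v), window_s=window_s, overlap_frac=overlap_frac)


def regularity_report(beats: BeatSeries) -> dict[str, float]:
    """Bundle rhythm-regularity statistics; larger values mean less regular.

    Returns sdnn, sd1, sd2 (seconds), the coefficient of variation of the
    intervals, and counts.
    """
    iv = beats.intervals
    if len(iv) < 2:
        raise ValueError("need >= 2 intervals for a regularity report")
    p = poincare(iv)
    mean_iv = float(np.mean(iv))
    return {
        "n_beats": float(beats.n_beats),
        "n_intervals": float(len(iv)),
        "mean_interval_s": mean_iv,
        "sdnn_s": p.sdnn,
        "sd1_s": p.sd1,
        "sd2_s": p.sd2,
        "cv_intervals": float(np.std(iv) / mean_iv) if mean_iv > 0 else float("nan"),
    }
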