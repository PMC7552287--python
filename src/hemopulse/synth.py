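"""Ground-truthed synthetic videos of a beating heart and flowing hemocytes.

Every analysis module in this package is testable without animals: the
generators here render grayscale frame stacks that mimic transmitted-light
recordings of a mounted water flea — a dark, periodically contracting
elliptical heart chamber, and dark point-like hemocytes advecting along a
thorax corridor with optionally pulsatile speed — together with exact truth
records (beat times, per-frame axes, per-frame cell positions and speeds).

What the scenes emulate, and what they do not: defaults follow the source
recording conditions (200 fps for 10 s, heart long axis ~300 um, flow
speeds up to ~2800 um/s, beat rates 260-600 bpm). Rendering is band-limited
(logistic edges, Gaussian blobs) so sub-pixel localization is meaningful.
They do not emulate limb-motion occlusion, carapace texture, or focus
drift; passing tests demonstrate algorithmic correctness on clean
geometry, not robustness to every artifact of live imaging.

All randomness flows through one ``numpy.random.default_rng(seed)``;
identical parameters and seed give bit-identical frames and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_video import FrameStack

__all__ = [
    "HeartSimParams",
    "FlowSimParams",
    "HeartTruth",
    "FlowTruth",
    "simulate_heart",
    "simulate_flow",
]

MIN_INTERVAL_S = 0.02  # floor on truncated-Gaussian beat intervals


@dataclass(frozen=True)
class HeartSimParams:
    """Scene parameters for the beating-heart generator.

    Beat intervals are truncated-Gaussian: ``max(0.02 s, N(60/rate_bpm,
    interval_sd_s))``. The chamber is a dark ellipse on a bright field whose
    axes swing between the diastolic (``dl_d``/``ds_d``) and systolic
    (``dl_s``/``ds_s``) diameters; contraction occupies ``systole_frac`` of
    each cycle, centred on the beat time, so mean ROI intensity peaks at
    systole and the fully relaxed phase sits at the interval midpoint.
    """

    fps: float = 200.0
    duration_s: float = 10.0
    rate_bpm: float = 600.0
    interval_sd_s: float = 0.0
    dl_d: float = 300.0  # um, long axis at diastole
    ds_d: float = 150.0
    dl_s: float = 280.0
    ds_s: float = 120.0
    pixel_size_um: float = 2.0
    background: float = 200.0
    contrast: float = 80.0
    noise_sd: float = 2.0
    systole_frac: float = 0.3
    edge_px: float = 1.0
    margin_px: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rate_bpm > 0:
            raise ValueError("rate_bpm must be > 0")
        if self.interval_sd_s < 0:
            raise ValueError("interval_sd_s must be >= 0")
        for name in ("dl_d", "ds_d", "dl_s", "ds_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class HeartTruth:
    """Exact ground truth for one simulated heart recording."""

    beat_times: np.ndarray  # s, beats within [0, duration)
    dl_um: np.ndarray  # per-frame long axis
    ds_um: np.ndarray  # per-frame short axis
    rate_bpm: float
    sv_um3: float  # programmed stroke volume, pi/6*(dl_d*ds_d^2 - dl_s*ds_s^2)
    edv_um3: float
    esv_um3: float

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)


def _beat_schedule(params: HeartSimParams, rng: np.random.Generator) -> np.ndarray:
    """Beat times covering [-T, duration+T] so edge frames have a defined phase."""
    mean_iv = 60.0 / params.rate_bpm
    times = [-mean_iv / 2.0]
    while times[-1] < params.duration_s + mean_iv:
        iv = max(MIN_INTERVAL_S, rng.normal(mean_iv, params.interval_sd_s))
        times.append(times[-1] + iv)
    return np.array(times)


def _contraction(t: np.ndarray, beat_times: np.ndarray, systole_frac: float) -> np.ndarray:
    """Contraction level in [0, 1]: 1 at each beat time, 0 at interval midpoints.

    Within each interval the waveform is a raised-cosine pulse of fractional
    half-width ``systole_frac`` at both ends and a relaxed plateau between —
    an asymmetric cycle (brief systole, long diastole) like a real
    myogenic heartbeat.
    """
    idx = np.clip(np.searchsorted(beat_times, t, side="right") - 1, 0, len(beat_times) - 2)
    t0 = beat_times[idx]
    t1 = beat_times[idx + 1]
    u = (t - t0) / (t1 - t0)
    d = np.minimum(u, 1.0 - u)  # fractional distance to the nearest beat
    c = np.zeros_like(d)
    inside = d < systole_frac
    c[inside] = np.cos(np.pi * d[inside] / (2.0 * systole_frac)) ** 2
    return c


def simulate_heart(params: HeartSimParams) -> tuple[FrameStack, HeartTruth]:
    """Render a beating-heart stack plus exact truth.

    Returns a :class:`FrameStack` of uint16 frames and a :class:`HeartTruth`
    with the beat schedule, per-frame axes and the programmed stroke volume.
    """
    rng = np.random.default_rng(params.seed)
    schedule = _beat_schedule(params, rng)

    n_frames = int(round(params.duration_s * params.fps))
    t = np.arange(n_frames) / params.fps
    c = _contraction(t, schedule, params.systole_frac)
    dl = params.dl_d + (params.dl_s - params.dl_d) * c  # um
    ds = params.ds_d + (params.ds_s - params.ds_d) * c

    # frame large enough for the fully relaxed chamber
    dl_max = max(params.dl_d, params.dl_s) / params.pixel_size_um
    ds_max = max(params.ds_d, params.ds_s) / params.pixel_size_um
    width = int(np.ceil(dl_max)) + 2 * params.margin_px
    height = int(np.ceil(ds_max)) + 2 * params.margin_px
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    Y, X = np.mgrid[0:height, 0:width]
    dxg = X - cx
    dyg = Y - cy

    frames = np.empty((n_frames, height, width), dtype=np.uint16)
    for k in range(n_frames):
        a = dl[k] / params.pixel_size_um / 2.0  # semi-axes in px
        b = ds[k] / params.pixel_size_um / 2.0
        r = np.sqrt((dxg / a) ** 2 + (dyg / b) ** 2)
        dist_px = (r - 1.0) * b  # approx signed distance near the boundary
        mask = expit(-dist_px / params.edge_px)
        img = params.background - params.contrast * mask
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
        frames[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    beats = schedule[(schedule >= 0.0) & (schedule < params.duration_s)]
    edv = np.pi / 6.0 * params.dl_d * params.ds_d**2
    esv = np.pi / 6.0 * params.dl_s * params.ds_s**2
    truth = HeartTruth(
        beat_times=beats,
        dl_um=dl,
        ds_um=ds,
        rate_bpm=params.rate_bpm,
        sv_um3=edv - esv,
        edv_um3=edv,
        esv_um3=esv,
    )
    stack = FrameStack(frames=frames, fps=params.fps, pixel_size_um=params.pixel_size_um)
    return stack, truth


@dataclass(frozen=True)
class FlowSimParams:
    """Scene parameters for the hemocyte-corridor generator.

    Cells advect rightward along parallel lanes with the shared speed
    ``s(t) = mean_speed_um_s * (1 + pulsatility_frac * sin(2*pi*beat_freq_hz*t))``
    and are rendered as dark Gaussian blobs (sigma = cell_radius_px /
    sqrt(2), so the matched LoG detection scale equals ``cell_radius_px /
    sqrt(2)``). The corridor is sized so no cell leaves the frame.
    """

    n_cells: int = 20
    mean_speed_um_s: float = 1000.0
    pulsatility_frac: float = 0.0
    beat_freq_hz: float = 5.0
    cell_radius_px: float = 3.5
    lane_spacing_px: float = 12.0
    fps: float = 200.0
    duration_s: float = 1.0
    pixel_size_um: float = 2.0
    background: float = 200.0
    amplitude: float = 100.0
    noise_sd: float = 2.0
    start_span_px: float = 30.0
    margin_px: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.mean_speed_um_s < 0:
            raise ValueError("mean_speed_um_s must be >= 0")
        if not (0.0 <= self.pulsatility_frac <= 1.0):
            raise ValueError("pulsatility_frac must be in [0, 1]")


@dataclass
class FlowTruth:
    """Exact ground truth for one simulated flow recording."""

    positions_px: np.ndarray  # (n_frames, n_cells, 2): (x, y)
    step_speeds_um_s: np.ndarray  # (n_frames - 1, n_cells), frame-differenced
    mean_speed_um_s: float

    @property
    def pooled_speeds(self) -> np.ndarray:
        return self.step_speeds_um_s.ravel()


def _travel_px(t: np.ndarray, p: FlowSimParams) -> np.ndarray:
    """Closed-form distance travelled by a cell up to each time, in pixels."""
    s0 = p.mean_speed_um_s / p.pixel_size_um  # px/s
    if p.pulsatility_frac == 0.0 or p.beat_freq_hz == 0.0:
        return s0 * t
    w = 2.0 * np.pi * p.beat_freq_hz
    return s0 * (t + p.pulsatility_frac * (1.0 - np.cos(w * t)) / w)


def simulate_flow(params: FlowSimParams) -> tuple[FrameStack, FlowTruth]:
    """Render a hemocyte-corridor stack plus exact per-frame truth.

    Truth step speeds are frame-differenced from the exact positions —
    the same discretization a tracker sees — so they are directly
    comparable with linked-track step speeds.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    n_frames = int(round(p.duration_s * p.fps))
    t = np.arange(n_frames) / p.fps
    travel = _travel_px(t, p)  # shared by all cells

    x0 = p.margin_px + (np.arange(p.n_cells) * 7.3) % p.start_span_px
    y = p.margin_px + np.arange(p.n_cells) * p.lane_spacing_px

    xs = x0[None, :] + travel[:, None]  # (n_frames, n_cells)
    ys = np.broadcast_to(y[None, :], xs.shape)

    width = int(np.ceil(xs.max())) + p.margin_px + 1
    height = int(np.ceil(y.max())) + p.margin_px + 1

    sigma = p.cell_radius_px / np.sqrt(2.0)
    half = int(np.ceil(4.0 * sigma))
    frames = np.empty((n_frames, height, width), dtype=np.uint16)
    for k in range(n_frames):
        img = np.full((height, width), p.background, dtype=float)
        for i in range(p.n_cells):
            cx, cy = xs[k, i], ys[k, i]
            x_lo, x_hi = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
            y_lo, y_hi = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
            x_lo, y_lo = max(0, x_lo), max(0, y_lo)
            x_hi, y_hi = min(width, x_hi), min(height, y_hi)
            yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
            img[y_lo:y_hi, x_lo:x_hi] -= p.amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
            )
        img = img + rng.normal(0.0, p.noise_sd, img.shape)
        frames[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    positions = np.stack([xs, ys], axis=-1)
    disp_px = np.linalg.norm(np.diff(positions, axis=0), axis=-1)
    step_speeds = disp_px * p.pixel_size_um * p.fps
    truth = FlowTruth(
        positions_px=positions,
        step_speeds_um_s=step_speeds,
        mean_speed_um_s=p.mean_speed_um_s,
    )
    stack = FrameStack(frames=frames, fps=p.fps, pixel_size_um=p.pixel_size_um)
    return stack, truth
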