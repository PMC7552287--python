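"""Hemocyte detection and tracking for blood-flow velocimetry.

Water fleas have an open circulatory system: hemocytes drift through the
hemocoel and are visible through the transparent carapace. In a thorax ROI
they move along a roughly linear corridor, so blob detection plus
frame-to-frame linking yields per-cell trajectories, and step displacements
divided by the frame interval give flow speeds in um/s.

Detection is scale-normalized Laplacian-of-Gaussian (LoG) filtering: the
response ``sigma^2 * laplacian(G_sigma * I)`` peaks at the centre of a blob
of matched scale (radius ~ sqrt(2)*sigma). Linking is per-frame-pair optimal
bipartite assignment on squared displacement, with short gap bridging —
the LAP style used by standard single-particle trackers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Spot",
    "Track",
    "TrackSet",
    "VelocitySummary",
    "detect_spots",
    "link_tracks",
    "summarize_velocity",
]


@dataclass(frozen=True)
class Spot:
    """A detected particle: frame index, sub-pixel centre, LoG response, scale."""

    frame: int
    x: float
    y: float
    response: float
    radius_px: float


@dataclass
class Track:
    """One particle followed over time; frames strictly increasing, gaps allowed."""

    spots: list[Spot]

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) pixel coordinates."""
        return np.array([(s.x, s.y) for s in self.spots])

    def step_speeds(self, pixel_size_um: float, fps: float) -> np.ndarray:
        """Per-step speeds in um/s: displacement * pixel size * fps / frame gap."""
        pos = self.positions
        gaps = np.diff(self.frames).astype(float)
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        return disp * pixel_size_um * fps / gaps


@dataclass
class TrackSet:
    """All linked trajectories from one recording."""

    tracks: list[Track]

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


@dataclass(frozen=True)
class VelocitySummary:
    """Pooled step-speed statistics in um/s (one record per animal)."""

    v_max: float
    v_mean: float
    v_min: float
    n_tracks: int
    n_steps: int


def _log_response(frame: np.ndarray, sigma_px: float, polarity: str) -> np.ndarray:
    """Scale-normalized LoG response, positive at blob centres of the given polarity."""
    img = np.asarray(frame, dtype=float)
    resp = sigma_px**2 * ndimage.gaussian_laplace(img, sigma=sigma_px)
    if polarity == "bright":
        return -resp  # LoG of a bright blob is negative at its centre
    if polarity == "dark":
        return resp
    raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")


def _quadratic_subpixel(resp: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Refine a local maximum via separable 3-point parabolic fits."""
    dx = dy = 0.0
    denom_x = resp[y, x - 1] - 2.0 * resp[y, x] + resp[y, x + 1]
    if denom_x < 0:
        dx = float(np.clip(0.5 * (resp[y, x - 1] - resp[y, x + 1]) / denom_x, -0.5, 0.5))
    denom_y = resp[y - 1, x] - 2.0 * resp[y, x] + resp[y + 1, x]
    if denom_y < 0:
        dy = float(np.clip(0.5 * (resp[y - 1, x] - resp[y + 1, x]) / denom_y, -0.5, 0.5))
    return x + dx, y + dy


def robust_noise_sd(response: np.ndarray) -> float:
    """Noise scale of a response image: 1.4826 * median absolute deviation."""
    med = np.median(response)
    return float(1.4826 * np.median(np.abs(response - med)))


def detect_spots(
    frame: np.ndarray,
    sigma_px: float = 2.5,
    threshold: float | None = None,
    polarity: str = "dark",
    frame_index: int = 0,
) -> list[Spot]:
    """Detect blob-like particles in one frame by scale-normalized LoG filtering.

    Parameters
    ----------
    frame
        2-D intensity array.
    sigma_px
        Detection scale; matched blobs have radius ~ sqrt(2)*sigma. Must be
        >= 0.5.
    threshold
        Minimum LoG response. ``None`` uses 5x the robust noise SD of the
        response image.
    polarity
        ``'dark'`` (default — hemocytes are darker than the translucent
        background in transmitted light) or ``'bright'``.
    frame_index
        Stored on the returned spots for later linking.

    Returns
    -------
    list of Spot, possibly empty, with sub-pixel centres from separable
    3-point quadratic fits.
    """
    if sigma_px < 0.5:
        raise ValueError(f"sigma_px must be >= 0.5, got {sigma_px}")
    resp = _log_response(frame, sigma_px, polarity)
    # the discrete LoG kernel does not sum exactly to zero, so a constant
    # background leaves a constant response offset; remove it
    resp = resp - np.median(resp)
    if threshold is None:
        threshold = 5.0 * robust_noise_sd(resp)
    # noiseless images have zero noise SD; keep a floor so background
    # plateaus never qualify
    threshold = max(threshold, 1e-6 * float(resp.max()) if resp.max() > 0 else 1e-12)

    # local maxima over a neighbourhood comparable to the blob radius
    size = max(3, 2 * int(np.ceil(sigma_px)) + 1)
    maxf = ndimage.maximum_filter(resp, size=size, mode="nearest")
    peaks = (resp == maxf) & (resp > threshold)
    # exclude the 1-px border: no room for the quadratic fit there
    peaks[0, :] = peaks[-1, :] = False
    peaks[:, 0] = peaks[:, -1] = False

    spots = []
    for y, x in zip(*np.nonzero(peaks)):
        sx, sy = _quadratic_subpixel(resp, y, x)
        spots.append(
            Spot(
                frame=frame_index,
                x=sx,
                y=sy,
                response=float(resp[y, x]),
                radius_px=float(np.sqrt(2.0) * sigma_px),
            )
        )
    return spots


def detect_spots_stack(
    frames: np.ndarray,
    sigma_px: float = 2.5,
    threshold: float | None = None,
    polarity: str = "dark",
) -> list[list[Spot]]:
    """Run :func:`detect_spots` on every frame of a stack.

    When ``threshold`` is None it is estimated once, from the first frame's
    response, so all frames share a single cutoff.
    """
    frames = np.asarray(frames)
    if threshold is None:
        resp0 = _log_response(frames[0], sigma_px, polarity)
        resp0 = resp0 - np.median(resp0)
        threshold = 5.0 * robust_noise_sd(resp0)
        threshold = max(threshold, 1e-6 * float(resp0.max()) if resp0.max() > 0 else 1e-12)
    return [
        detect_spots(f, sigma_px=sigma_px, threshold=threshold, polarity=polarity, frame_index=k)
        for k, f in enumerate(frames)
    ]


def link_tracks(
    spots_by_frame: list[list[Spot]],
    max_disp_px: float = 15.0,
    max_gap: int = 1,
    min_track_len: int = 3,
) -> TrackSet:
    """Link per-frame detections into trajectories by optimal assignment.

    For each frame, open track ends are matched to the new spots by solving
    the bipartite assignment that minimizes total squared displacement,
    admitting only pairs within the gate ``max_disp_px * (gap + 1)`` where
    ``gap`` is the number of frames the track has been dark. Unmatched spots
    seed new tracks; tracks dark for more than ``max_gap`` frames are
    closed; tracks with fewer than ``min_track_len`` spots are discarded.
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    active: list[Track] = []
    finished: list[Track] = []

    for frame_idx, spots in enumerate(spots_by_frame):
        # retire tracks whose last spot is too old to bridge
        still = []
        for tr in active:
            if frame_idx - tr.spots[-1].frame > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        if not spots:
            continue
        if not active:
            active = [Track(spots=[s]) for s in spots]
            continue

        ends = np.array([(t.spots[-1].x, t.spots[-1].y) for t in active])
        gaps = np.array([frame_idx - t.spots[-1].frame for t in active])  # >= 1
        news = np.array([(s.x, s.y) for s in spots])
        d2 = ((ends[:, None, :] - news[None, :, :]) ** 2).sum(axis=2)
        gate = (max_disp_px * gaps) ** 2  # gate scales with (gap+1)-1 .. i.e. gap frames
        # gap g means the spot is g frames after the track end; allowed
        # displacement grows linearly with that span.
        allowed = d2 <= gate[:, None]

        BIG = 1e12
        cost = np.where(allowed, d2, BIG)
        rows, cols = linear_sum_assignment(cost)
        matched_tracks = set()
        matched_spots = set()
        for r, c in zip(rows, cols):
            if allowed[r, c]:
                active[r].spots.append(spots[c])
                matched_tracks.add(r)
                matched_spots.add(c)
        for c, s in enumerate(spots):
            if c not in matched_spots:
                active.append(Track(spots=[s]))

    finished.extend(active)
    kept = [t for t in finished if t.n_spots >= min_track_len]
    return TrackSet(tracks=kept)


def summarize_velocity(
    tracks: TrackSet, pixel_size_um: float, fps: float
) -> VelocitySummary:
    """Pool step speeds over all tracks and report max / mean / min in um/s.

    One summary per animal: the per-step speeds of every trajectory are
    pooled, and the extremes and mean of the pool are reported.
    """
    if tracks.n_tracks == 0:
        raise ValueError("no trackable cells")
    speeds = np.concatenate(
        [t.step_speeds(pixel_size_um, fps) for t in tracks.tracks if t.n_spots >= 2]
    )
    if len(speeds) == 0:
        raise ValueError("no trackable cells")
    return VelocitySummary(
        v_max=float(speeds.max()),
        v_mean=float(speeds.mean()),
        v_min=float(speeds.min()),
        n_tracks=tracks.n_tracks,
        n_steps=int(len(speeds)),
    )


def summarize_velocity_per_track(
    tracks: TrackSet, pixel_size_um: float, fps: float
) -> list[VelocitySummary]:
    """Per-track velocity summaries (one record per trajectory)."""
    out = []
    for t in tracks.tracks:
        sp = t.step_speeds(pixel_size_um, fps)
        if len(sp) == 0:
            continue
        out.append(
            VelocitySummary(
                v_max=float(sp.max()),
                v_mean=float(sp.mean()),
                v_min=float(sp.min()),
                n_tracks=1,
                n_steps=int(len(sp)),
            )
        )
    return out
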