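"""Frame-stack I/O, region-of-interest handling, and unit conventions.

All modules share one coordinate convention, fixed here:

* ``x`` is the column index (rightward), ``y`` the row index (downward);
* indices are 0-based; ROIs are half-open, ``[x0, x0+width) x [y0, y0+height)``;
* frames are 2-D ``(height, width)`` arrays in acquisition order;
* time of frame ``k`` is ``k / fps`` seconds;
* physical scale enters only through ``pixel_size_um`` (micrometres per pixel).

Acquisition metadata (frame rate, pixel size) is never guessed from file
headers: consumer microscopy files rarely carry it reliably, so both are
required arguments everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import tifffile

__all__ = ["FrameStack", "RectROI", "read_stack", "write_stack", "crop", "parse_roi"]


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular region of interest.

    ``x0``/``y0`` are the top-left pixel (0-based column/row); the region
    covers the half-open box ``[x0, x0+width) x [y0, y0+height)``.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"ROI width/height must be >= 1, got {self.width}x{self.height}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.x0}, {self.y0})")

    def validate_within(self, shape: tuple[int, int]) -> None:
        """Raise ValueError naming the offending coordinate if the ROI exceeds ``shape``."""
        h, w = shape
        if self.x0 + self.width > w:
            raise ValueError(
                f"ROI right edge x={self.x0 + self.width} exceeds frame width {w}"
            )
        if self.y0 + self.height > h:
            raise ValueError(
                f"ROI bottom edge y={self.y0 + self.height} exceeds frame height {h}"
            )

    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the ROI from a frame array."""
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )


@dataclass
class FrameStack:
    """An ordered grayscale video: frames plus acquisition metadata.

    Parameters
    ----------
    frames
        3-D array ``(n_frames, height, width)`` of intensities (any integer
        or floating dtype; units are arbitrary camera counts).
    fps
        Acquisition rate in frames per second, > 0.
    pixel_size_um
        Physical size of one pixel in micrometres, > 0.
    """

    frames: np.ndarray
    fps: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (n, h, w) array, got ndim={self.frames.ndim}"
            )
        if len(self.frames) < 2:
            raise ValueError(f"need >= 2 frames, got {len(self.frames)}")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        """Record length in seconds (n_frames / fps)."""
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Per-frame acquisition times in seconds (frame k at k / fps)."""
        return np.arange(self.n_frames) / self.fps


def _to_grayscale(frames: np.ndarray) -> np.ndarray:
    # Color input -> luminance by channel mean (deterministic, documented).
    if frames.ndim == 4:
        return frames.mean(axis=-1)
    return frames


def read_stack(
    path: Union[str, Path], fps: float, pixel_size_um: float
) -> FrameStack:
    """Read a multi-page TIFF or AVI video into a :class:`FrameStack`.

    TIFF intensities are preserved losslessly; AVI is decoded as 8-bit.
    Color frames are converted to luminance by averaging channels.
    ``fps`` and ``pixel_size_um`` must be supplied by the caller — they are
    not read from the file.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        frames = tifffile.imread(str(path))
    elif suffix == ".avi":
        import imageio.v3 as iio

        frames = np.stack(list(iio.imiter(str(path))))
    else:
        raise ValueError(f"unsupported video format: {path.name} (use TIFF or AVI)")

    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError("need >= 2 frames, got a single frame")
    frames = _to_grayscale(frames)
    if frames.ndim != 3:
        raise ValueError(f"cannot interpret {path.name} as a grayscale frame stack")
    return FrameStack(frames=frames, fps=fps, pixel_size_um=pixel_size_um)


def write_stack(stack: FrameStack, path: Union[str, Path]) -> None:
    """Write a stack as a multi-page grayscale TIFF (lossless round-trip)."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError(f"write_stack only writes TIFF, got {path.name}")
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack")


def crop(stack: FrameStack, roi: RectROI) -> FrameStack:
    """Return the sub-stack inside ``roi``; fps and pixel size are unchanged."""
    roi.validate_within(stack.frame_shape)
    rs, cs = roi.slices()
    return FrameStack(
        frames=stack.frames[:, rs, cs],
        fps=stack.fps,
        pixel_size_um=stack.pixel_size_um,
    )


def parse_roi(text: str) -> RectROI:
    """Parse an ``"x0,y0,width,height"`` string into a :class:`RectROI`."""
    parts = text.split(",")
    if len(parts) != 4:
        raise ValueError(f"ROI must be 'x0,y0,width,height', got {text!r}")
    x0, y0, w, h = (int(p.strip()) for p in parts)
    return RectROI(x0=x0, y0=y0, width=w, height=h)
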