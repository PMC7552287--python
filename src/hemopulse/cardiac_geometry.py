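"""Cardiac geometry: fractional shortening, volumes, stroke volume, EF, CO.

The daphnid heart is a single chamber well approximated by a prolate
spheroid, so two diameters — long axis D_L and short axis D_S — measured at
end-diastole and end-systole give the whole standard echocardiographic
panel:

* fractional shortening  FS = (D_SD - D_SS) / D_SS x 100  (source
  convention: systolic denominator; the conventional diastolic-denominator
  form is available as ``convention='standard'``);
* chamber volume         V = pi/6 * D_L * D_S^2 (prolate spheroid; a
  literal mode drops the pi, reproducing the 1/6 prefactor some protocols
  print);
* stroke volume          SV  = EDV - ESV;
* ejection fraction      EF  = SV / EDV x 100;
* cardiac output         CO  = SV x HR.

Volumes are in um^3; 1 nL = 1e6 um^3. ``measure_diameters`` automates the
manual calliper step: it segments the heart in systolic frames (at detected
beat peaks) and diastolic frames (at inter-beat midpoints) and fits an
ellipse by second moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .heartbeat import BeatSeries
from .io_video import FrameStack, RectROI, crop

__all__ = [
    "HeartGeometry",
    "CardiacMetrics",
    "fractional_shortening",
    "ellipsoid_volume",
    "stroke_volume",
    "ejection_fraction",
    "cardiac_output",
    "measure_diameters",
    "compute_metrics",
]

UM3_PER_NL = 1e6


@dataclass(frozen=True)
class HeartGeometry:
    """Heart diameters (um) at both phases.

    ``dl_d``/``ds_d``: long/short axis at diastole; ``dl_s``/``ds_s``: at
    systole. A systolic short axis larger than the diastolic one is a
    measurement inconsistency and triggers a warning, not an error.
    """

    dl_d: float
    ds_d: float
    dl_s: float
    ds_s: float

    def __post_init__(self) -> None:
        for name in ("dl_d", "ds_d", "dl_s", "ds_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.ds_s > self.ds_d:
            warnings.warn(
                f"systolic short diameter ({self.ds_s:.1f} um) exceeds diastolic "
                f"({self.ds_d:.1f} um); check phase assignment",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CardiacMetrics:
    """Derived cardiac performance panel (volumes in um^3, CO per minute)."""

    fs_pct: float
    edv_um3: float
    esv_um3: float
    sv_um3: float
    ef_pct: float
    co_um3_min: float
    hr_bpm: float

    @property
    def edv_nl(self) -> float:
        return self.edv_um3 / UM3_PER_NL

    @property
    def esv_nl(self) -> float:
        return self.esv_um3 / UM3_PER_NL

    @property
    def sv_nl(self) -> float:
        return self.sv_um3 / UM3_PER_NL

    @property
    def co_nl_min(self) -> float:
        return self.co_um3_min / UM3_PER_NL


def fractional_shortening(ds_d: float, ds_s: float, convention: str = "paper") -> float:
    """Percent loss of the short diameter from diastole to systole.

    ``convention='paper'`` (default) divides by the systolic diameter, as
    the source protocol prints; ``'standard'`` divides by the diastolic
    diameter (conventional echocardiographic FS).
    """
    if not (ds_d > 0 and ds_s > 0):
        raise ValueError(f"diameters must be > 0, got ds_d={ds_d}, ds_s={ds_s}")
    if convention == "paper":
        return (ds_d - ds_s) / ds_s * 100.0
    if convention == "standard":
        return (ds_d - ds_s) / ds_d * 100.0
    raise ValueError(f"convention must be 'paper' or 'standard', got {convention!r}")


def ellipsoid_volume(dl: float, ds: float, include_pi: bool = True) -> float:
    """Prolate-spheroid chamber volume from long and short diameters (um -> um^3).

    Default: ``pi/6 * dl * ds^2`` — the volume of an ellipsoid with one
    long axis ``dl`` and two equal short axes ``ds``. ``include_pi=False``
    computes the literal ``1/6 * dl * ds^2`` prefactor used by some
    published protocols.
    """
    if not (dl > 0 and ds > 0):
        raise ValueError(f"diameters must be > 0, got dl={dl}, ds={ds}")
    factor = np.pi / 6.0 if include_pi else 1.0 / 6.0
    return factor * dl * ds**2


def stroke_volume(edv: float, esv: float) -> float:
    """SV = EDV - ESV (um^3). A negative result is allowed but flagged."""
    if edv < 0 or esv < 0:
        raise ValueError("volumes must be >= 0")
    sv = edv - esv
    if sv < 0:
        warnings.warn(
            f"negative stroke volume ({sv:.3g} um^3): ESV exceeds EDV, check "
            "phase assignment or segmentation",
            stacklevel=2,
        )
    return sv


def ejection_fraction(sv: float, edv: float) -> float:
    """EF = SV / EDV x 100 (%)."""
    if edv <= 0:
        raise ValueError(f"edv must be > 0, got {edv}")
    return sv / edv * 100.0


def cardiac_output(sv: float, hr_bpm: float) -> float:
    """CO = SV x HR, in um^3 per minute."""
    if hr_bpm < 0:
        raise ValueError(f"hr must be >= 0, got {hr_bpm}")
    return sv * hr_bpm


def _segment_axes(
    roi_frame: np.ndarray, pixel_size_um: float, dark_heart: bool, min_area_px: int
) -> tuple[float, float]:
    """Otsu-threshold one ROI frame and return (major, minor) axis in um.

    The largest connected component of the heart-side class is kept and an
    ellipse fitted by second moments (same estimator as ImageJ's fit
    ellipse).
    """
    img = np.asarray(roi_frame, dtype=float)
    if img.max() == img.min():
        raise ValueError("heart not segmentable: uniform region of interest")
    thr = threshold_otsu(img)
    mask = img < thr if dark_heart else img > thr
    lab = label(mask)
    if lab.max() == 0:
        raise ValueError("heart not segmentable: empty threshold mask")
    props = regionprops(lab)
    best = max(props, key=lambda p: p.area)
    if best.area < min_area_px:
        raise ValueError(
            f"heart not segmentable: largest component {best.area} px < {min_area_px} px"
        )
    return (
        best.axis_major_length * pixel_size_um,
        best.axis_minor_length * pixel_size_um,
    )


def measure_diameters(
    stack: FrameStack,
    heart_roi: RectROI,
    beats: BeatSeries,
    dark_heart: bool = True,
    min_area_px: int = 25,
) -> HeartGeometry:
    """Automated heart-diameter measurement from a beating-heart video.

    Systolic frames are those nearest each detected beat peak; diastolic
    frames sit at the midpoints between consecutive beats (the maximally
    relaxed phase). Each selected frame is Otsu-thresholded inside the ROI,
    the largest connected component kept, and an ellipse fitted by second
    moments; the long/short diameters are the mean major/minor axes over
    each frame set, in um.

    ``dark_heart=True`` (default) segments a chamber darker than its
    surround, the usual transmitted-light appearance.
    """
    sub = crop(stack, heart_roi)
    fps = stack.fps

    sys_times = beats.beat_times
    dia_times = 0.5 * (sys_times[:-1] + sys_times[1:])
    if len(dia_times) == 0:
        raise ValueError("need >= 2 beats to place diastolic frames")

    def frames_at(times: np.ndarray) -> np.ndarray:
        idx = np.clip(np.round(times * fps).astype(int), 0, sub.n_frames - 1)
        return np.unique(idx)

    def mean_axes(frame_idx: np.ndarray) -> tuple[float, float]:
        majors, minors = [], []
        for k in frame_idx:
            maj, mino = _segment_axes(
                sub.frames[k], stack.pixel_size_um, dark_heart, min_area_px
            )
            majors.append(maj)
            minors.append(mino)
        return float(np.mean(majors)), float(np.mean(minors))

    dl_s, ds_s = mean_axes(frames_at(sys_times))
    dl_d, ds_d = mean_axes(frames_at(dia_times))
    return HeartGeometry(dl_d=dl_d, ds_d=ds_d, dl_s=dl_s, ds_s=ds_s)


def compute_metrics(
    geom: HeartGeometry,
    hr_bpm: float,
    fs_convention: str = "paper",
    include_pi: bool = True,
) -> CardiacMetrics:
    """Full cardiac panel from measured diameters and heart rate."""
    edv = ellipsoid_volume(geom.dl_d, geom.ds_d, include_pi=include_pi)
    esv = ellipsoid_volume(geom.dl_s, geom.ds_s, include_pi=include_pi)
    sv = stroke_volume(edv, esv)
    return CardiacMetrics(
        fs_pct=fractional_shortening(geom.ds_d, geom.ds_s, convention=fs_convention),
        edv_um3=edv,
        esv_um3=esv,
        sv_um3=sv,
        ef_pct=ejection_fraction(sv, edv),
        co_um3_min=cardiac_output(sv, hr_bpm),
        hr_bpm=hr_bpm,
    )
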