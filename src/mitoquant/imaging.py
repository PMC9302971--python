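"""Calibrated images, ROI geometry, and shared intensity primitives.

Every assay in this package reduces to sampling pixel intensities under some
geometry — a circle around a spindle pole, a line through both poles, a
segmented nucleus mask — on images with a known physical pixel size.  This
module holds the containers and the measurement primitives those assays share:

* :class:`CalibratedImage` / :class:`TimeLapse` — pixel grids with a μm/px
  calibration, so downstream distances can be reported in micrometres.
* :func:`roi_mean_intensity` — mean intensity inside a circular ROI.
* :func:`sample_line_profile` — bilinear line profile between two points.
* :func:`blur_background_subtract` — large-sigma Gaussian-blur background
  subtraction (the "duplicate, blur, subtract" recipe).
* :func:`background_subtracted_mean` — mean signal over a mask minus the mean
  of a cell-free background region.

Coordinate convention: 0-based pixel indices, a pixel's *center* sits at
integer coordinates ``(x, y)`` = (column, row), and all ROI geometry is
continuous in that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "CalibratedImage",
    "TimeLapse",
    "PointROI",
    "CircleROI",
    "BackgroundSubtractConfig",
    "CalibrationError",
    "read_image_stack",
    "roi_mean_intensity",
    "sample_line_profile",
    "blur_background_subtract",
    "background_subtracted_mean",
]


class CalibrationError(ValueError):
    """Raised when an image has no usable physical calibration."""


@dataclass(frozen=True)
class PointROI:
    """A continuous point in pixel coordinates (x = column, y = row)."""

    x: float
    y: float

    def distance_to(self, other: "PointROI") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


@dataclass(frozen=True)
class CircleROI:
    """Circular ROI with a physical radius in micrometres."""

    center: PointROI
    radius_um: float

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError(f"radius_um must be > 0, got {self.radius_um}")


@dataclass(frozen=True)
class BackgroundSubtractConfig:
    """Settings for Gaussian-blur background subtraction.

    ``blur_sigma_px`` is the standard deviation of the blur kernel in pixels.
    The default of 30 px is large compared with diffraction-limited features
    (poles, kinetochores), so the blurred image approximates the smooth
    background and subtracting it flattens illumination gradients while
    leaving punctate signal nearly untouched.
    """

    blur_sigma_px: float = 30.0
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if not self.blur_sigma_px > 0:
            raise ValueError("blur_sigma_px must be > 0")


@dataclass
class CalibratedImage:
    """A 2-D intensity grid with physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (arbitrary units).
    pixel_size_um
        Physical edge length of one pixel, μm/px.  Must be positive; there is
        deliberately no default — an uncalibrated image cannot silently
        pretend to be calibrated.
    channel_name
        Optional label ("dapi", "gfp", "pole", ...).
    frame_time
        Optional acquisition time of this frame (units chosen by the caller).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""
    frame_time: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D grid of at least 1x1")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise CalibrationError(
                f"pixel_size_um must be positive and finite, got {self.pixel_size_um}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_um(self, length_px: float) -> float:
        """Convert a length in pixels to micrometres."""
        return float(length_px) * self.pixel_size_um

    def to_px(self, length_um: float) -> float:
        """Convert a length in micrometres to pixels."""
        return float(length_um) / self.pixel_size_um

    def contains_point(self, p: PointROI) -> bool:
        h, w = self.pixels.shape
        return 0 <= p.x <= w - 1 and 0 <= p.y <= h - 1


@dataclass
class TimeLapse:
    """An ordered multi-channel image sequence with shared calibration.

    ``channels`` maps a channel name to its list of frames; every frame in
    every channel must share dimensions and pixel size.  ``timestamps`` are
    strictly increasing acquisition times (minutes for 1-min anaphase movies,
    seconds for 20-s pole/kinetochore movies — the caller's choice, carried
    through unchanged).
    """

    channels: dict[str, list[CalibratedImage]]
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if not self.channels:
            raise ValueError("TimeLapse needs at least one channel")
        n = len(self.timestamps)
        ref = next(iter(self.channels.values()))[0]
        for name, frames in self.channels.items():
            if len(frames) != n:
                raise ValueError(
                    f"channel {name!r} has {len(frames)} frames but {n} timestamps"
                )
            for f in frames:
                if f.shape != ref.shape:
                    raise ValueError("all frames must share dimensions")
                if f.pixel_size_um != ref.pixel_size_um:
                    raise ValueError("all frames must share pixel_size_um")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def pixel_size_um(self) -> float:
        return next(iter(self.channels.values()))[0].pixel_size_um

    @property
    def frames(self) -> list[CalibratedImage]:
        """Frames of the sole channel (error if the movie is multi-channel)."""
        if len(self.channels) != 1:
            raise ValueError("frames is only defined for single-channel movies")
        return next(iter(self.channels.values()))


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Try to recover μm/px from TIFF resolution tags or ImageJ metadata."""
    page = tf.pages[0]
    ij = tf.imagej_metadata or {}
    # ImageJ writes physical size via XResolution (px per unit) + unit tag
    unit = ij.get("unit", "")
    tags = page.tags
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        if num and den:
            px_per_unit = num / den
            if px_per_unit > 0:
                size = den / num
                if unit in ("um", "µm", "micron", "micrometer"):
                    return float(size)
    return None


def read_image_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    timestamps: Sequence[float] | None = None,
    frame_interval: float | None = None,
    channel_name: str = "",
) -> TimeLapse:
    """Read a single- or multi-page grayscale TIFF as a single-channel movie.

    Calibration precedence: an explicit ``pixel_size_um`` argument overrides
    any calibration found in the file metadata; if neither is available a
    :class:`CalibrationError` is raised — there is no silent 1 μm/px default.

    Timestamps come from ``timestamps`` if given, else ``frame_interval``
    times the frame index, else the frame index itself.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_px = _pixel_size_from_tiff(tf)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected a grayscale (single/multi-page) TIFF, got shape {data.shape}")
    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise CalibrationError(
            f"{path.name}: no pixel size in TIFF metadata and none supplied; "
            "pass pixel_size_um explicitly"
        )
    n = data.shape[0]
    if timestamps is not None:
        ts = np.asarray(timestamps, dtype=float)
        if len(ts) != n:
            raise ValueError(f"{len(ts)} timestamps for {n} frames")
    elif frame_interval is not None:
        ts = np.arange(n) * float(frame_interval)
    else:
        ts = np.arange(n, dtype=float)
    frames = [
        CalibratedImage(frame, px, channel_name=channel_name, frame_time=t)
        for frame, t in zip(data, ts)
    ]
    return TimeLapse(channels={channel_name or "ch0": frames}, timestamps=ts)


def write_image_stack(movie: TimeLapse, path: str | Path, channel: str | None = None) -> None:
    """Write one channel of a movie as a multi-page float32 TIFF with
    ImageJ-style μm calibration so it round-trips through read_image_stack."""
    if channel is None:
        frames = movie.frames
    else:
        frames = movie.channels[channel]
    px = frames[0].pixel_size_um
    stack = np.stack([f.pixels for f in frames]).astype(np.float32)
    tifffile.imwrite(
        str(path),
        stack,
        imagej=True,
        resolution=(1.0 / px, 1.0 / px),
        metadata={"unit": "um"},
    )


def roi_mean_intensity(image: CalibratedImage, roi: CircleROI) -> float:
    """Mean intensity over pixels whose centers fall within a circular ROI.

    Membership uses the pixel-center rule: pixel (x, y) belongs to the ROI iff
    its center lies within ``radius_um`` of the ROI center.  Raises if the
    circle extends beyond the image or contains no pixel centers.
    """
    h, w = image.shape
    r_px = image.to_px(roi.radius_um)
    cx, cy = roi.center.x, roi.center.y
    if cx - r_px < -0.5 or cx + r_px > w - 0.5 or cy - r_px < -0.5 or cy + r_px > h - 0.5:
        raise ValueError("circle ROI extends beyond image bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
    if not mask.any():
        raise ValueError("circle ROI contains no pixel centers")
    return float(image.pixels[mask].mean())


def sample_line_profile(
    image: CalibratedImage,
    p1: PointROI,
    p2: PointROI,
    spacing_px: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample intensity along the segment p1→p2 with bilinear interpolation.

    Samples are evenly spaced from p1 to p2 inclusive, with spacing as close
    to ``spacing_px`` as allows both endpoints to be sample points (so the
    profile of the reversed segment is exactly the reversed profile).

    Returns
    -------
    positions : ndarray
        Distance from ``p1`` in micrometres.
    intensities : ndarray
        Bilinearly interpolated intensity at each sample.
    """
    if not spacing_px > 0:
        raise ValueError("spacing_px must be > 0")
    if p1.x == p2.x and p1.y == p2.y:
        raise ValueError("degenerate segment: p1 == p2")
    for p in (p1, p2):
        if not image.contains_point(p):
            raise ValueError(f"endpoint ({p.x}, {p.y}) outside image")
    length_px = np.hypot(p2.x - p1.x, p2.y - p1.y)
    n = max(int(round(length_px / spacing_px)), 1) + 1
    t = np.linspace(0.0, 1.0, n)
    xs = p1.x + t * (p2.x - p1.x)
    ys = p1.y + t * (p2.y - p1.y)
    vals = ndimage.map_coordinates(image.pixels, [ys, xs], order=1, mode="nearest")
    positions_um = t * image.to_um(length_px)
    return positions_um, vals


def blur_background_subtract(
    image: CalibratedImage, cfg: BackgroundSubtractConfig | None = None
) -> CalibratedImage:
    """Subtract a Gaussian-blurred copy of the image from itself.

    Large-sigma blurring estimates the smooth background (cytoplasmic haze,
    uneven illumination); subtracting it sharpens punctate markers before
    peak finding.  Negative differences are clipped to zero by default so the
    result remains a valid intensity image.
    """
    cfg = cfg or BackgroundSubtractConfig()
    blurred = ndimage.gaussian_filter(image.pixels, sigma=cfg.blur_sigma_px)
    out = image.pixels - blurred
    if cfg.clip_negative:
        out = np.clip(out, 0.0, None)
    return CalibratedImage(
        out, image.pixel_size_um, channel_name=image.channel_name, frame_time=image.frame_time
    )


def background_subtracted_mean(
    image: CalibratedImage, signal_mask: np.ndarray, background_mask: np.ndarray
) -> float:
    """Background-corrected mean intensity over a signal mask.

    Computes (integrated density over the mask − mean background × mask area)
    divided by mask area, which is algebraically the mask mean minus the
    background mean.  The two regions must be non-empty and disjoint.
    """
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if signal_mask.shape != image.shape or background_mask.shape != image.shape:
        raise ValueError("masks must match image dimensions")
    if not signal_mask.any():
        raise ValueError("empty signal mask")
    if not background_mask.any():
        raise ValueError("empty background region")
    if (signal_mask & background_mask).any():
        raise ValueError("signal mask and background region overlap")
    area = int(signal_mask.sum())
    integrated = float(image.pixels[signal_mask].sum())
    mean_bg = float(image.pixels[background_mask].mean())
    return (integrated - mean_bg * area) / area
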