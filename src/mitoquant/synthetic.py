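"""Ground-truth-labelled synthetic inputs for every assay in the pipeline.

Raw imaging from the original experiments is not distributed, so each assay
is validated against synthetic data generated with known ground truth:

* :func:`generate_monopolar` — a monopolar spindle in which the DNA stain
  forms a Gaussian ring at a known radius around the pole (the chromatin
  annulus pushed outward by polar ejection forces).
* :func:`generate_anaphase` — a bipolar anaphase movie: two Gaussian
  chromosome masses whose center-to-center separation follows a prescribed
  trajectory d(t), plus pole-marker and centromere-marker channels.
* :func:`generate_nucleus_mask` — a rasterized lobed-nucleus polygon whose
  continuous solidity is computed exactly from the generating boundary.
* :func:`generate_frap_trace` — a photobleaching trace with mobile/immobile
  pools and single-exponential recovery, sampled on the acquisition schedule
  of the bleaching experiments (5-s intervals for 25 s pre-bleach, 20-s
  intervals for 10 min post-bleach).
* :func:`generate_growth_curve` — exponential well counts N(t) = N0·b^(t/τ)
  with multiplicative noise, sampled every 4 h for 96 h.

All generators are deterministic given their seed, and every truth value is
an exact function of the spec, independent of rasterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .imaging import CalibratedImage, PointROI, TimeLapse

__all__ = [
    "MonopolarSpec",
    "AnaphaseSpec",
    "NucleusSpec",
    "FrapSpec",
    "GrowthSpec",
    "generate_monopolar",
    "generate_anaphase",
    "generate_nucleus_mask",
    "generate_frap_trace",
    "generate_growth_curve",
    "monotone_trajectory",
    "recongression_trajectory",
]


# ---------------------------------------------------------------------------
# Monopolar spindle (polar ejection force assay)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonopolarSpec:
    """A monopolar spindle image: DNA intensity ringing a single pole.

    The radial intensity profile is Gaussian about ``ring_radius_um``:
    I(r) = peak · exp(−(r − ring_radius)² / (2·ring_width²)) + noise.
    """

    image_size_px: int = 280
    pixel_size_um: float = 0.1
    pole: PointROI | None = None  # default: image center
    ring_radius_um: float = 3.7
    ring_width_um: float = 0.8
    peak_intensity: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.ring_radius_um > 0:
            raise ValueError("ring_radius_um must be > 0")


def generate_monopolar(spec: MonopolarSpec) -> tuple[CalibratedImage, float]:
    """Render a monopolar-spindle image; returns (image, true ring radius μm)."""
    n = spec.image_size_px
    pole = spec.pole or PointROI((n - 1) / 2.0, (n - 1) / 2.0)
    half_span = min(pole.x, pole.y, n - 1 - pole.x, n - 1 - pole.y) * spec.pixel_size_um
    if spec.ring_radius_um + 3 * spec.ring_width_um > half_span:
        raise ValueError("ring does not fit inside the image around the pole")
    yy, xx = np.mgrid[0:n, 0:n]
    r_um = np.hypot(xx - pole.x, yy - pole.y) * spec.pixel_size_um
    img = spec.peak_intensity * np.exp(
        -((r_um - spec.ring_radius_um) ** 2) / (2 * spec.ring_width_um**2)
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)
    image = CalibratedImage(img, spec.pixel_size_um, channel_name="dapi")
    return image, spec.ring_radius_um


# ---------------------------------------------------------------------------
# Anaphase time-lapse
# ---------------------------------------------------------------------------

def monotone_trajectory(rate_um_per_min: float = 2.1, plateau_um: float = 14.0) -> Callable[[float], float]:
    """Separation that grows linearly then plateaus, the normal-segregation shape."""
    return lambda t: min(rate_um_per_min * t, plateau_um)


def recongression_trajectory(
    rise_to_um: float = 6.0,
    rise_at_min: float = 3.0,
    dip_to_um: float = 2.0,
    dip_at_min: float = 7.0,
    resume_rate_um_per_min: float = 1.5,
) -> Callable[[float], float]:
    """Rise–dip–rise separation: masses part, recongress toward the midzone,
    then separate again."""

    def d(t: float) -> float:
        if t <= rise_at_min:
            return rise_to_um * t / rise_at_min
        if t <= dip_at_min:
            frac = (t - rise_at_min) / (dip_at_min - rise_at_min)
            return rise_to_um + (dip_to_um - rise_to_um) * frac
        return dip_to_um + resume_rate_um_per_min * (t - dip_at_min)

    return d


@dataclass(frozen=True)
class AnaphaseSpec:
    """A bipolar anaphase movie with chromosome, pole, and centromere channels.

    Chromosome masses are isotropic Gaussians of width ``mass_sigma_um``
    centered ±d(t)/2 about the spindle midpoint along the pole axis.  Pole
    markers are narrow spots at ±pole_trajectory(t)/2; centromere spots sit at
    each mass center displaced ``centromere_offset_um`` toward its pole.
    """

    separation_trajectory: Callable[[float], float] = field(default_factory=monotone_trajectory)
    pole_trajectory: Callable[[float], float] = field(default_factory=lambda: (lambda t: 20.0))
    mass_sigma_um: float = 1.5
    centromere_offset_um: float = 0.5
    frame_interval_min: float = 1.0
    n_frames: int = 11
    image_width_px: int = 260
    image_height_px: int = 80
    pixel_size_um: float = 0.1
    mass_intensity: float = 1000.0
    marker_sigma_um: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for k in range(self.n_frames):
            t = k * self.frame_interval_min
            d = self.separation_trajectory(t)
            if d < 0:
                raise ValueError(f"separation trajectory negative at t={t}")
            if self.pole_trajectory(t) <= d:
                raise ValueError(f"poles must lie outside the masses (t={t})")


def _gauss_spot(xx_um, yy_um, cx_um, cy_um, sigma_um, amp):
    return amp * np.exp(
        -((xx_um - cx_um) ** 2 + (yy_um - cy_um) ** 2) / (2 * sigma_um**2)
    )


def generate_anaphase(spec: AnaphaseSpec) -> tuple[TimeLapse, pd.DataFrame]:
    """Render an anaphase movie; returns (movie, exact truth table).

    The truth table has one row per frame with columns ``time_min``,
    ``mass_separation_um``, ``pole_separation_um``, ``cen_separation_um``,
    and the pole coordinates (``pole1_x`` ... in pixel units).
    """
    w, h = spec.image_width_px, spec.image_height_px
    px = spec.pixel_size_um
    cx_um, cy_um = (w - 1) / 2.0 * px, (h - 1) / 2.0 * px
    yy, xx = np.mgrid[0:h, 0:w]
    xx_um, yy_um = xx * px, yy * px
    rng = np.random.default_rng(spec.seed)

    chrom_frames, pole_frames, cen_frames, rows = [], [], [], []
    times = np.arange(spec.n_frames) * spec.frame_interval_min
    for t in times:
        d = float(spec.separation_trajectory(float(t)))
        pole_sep = float(spec.pole_trajectory(float(t)))
        half_span = (w - 1) / 2.0 * px
        if pole_sep / 2.0 >= half_span or d / 2.0 + 3 * spec.mass_sigma_um >= half_span:
            raise ValueError("masses or poles leave the field of view")
        mass_centers = (cx_um - d / 2.0, cx_um + d / 2.0)
        pole_pos = (cx_um - pole_sep / 2.0, cx_um + pole_sep / 2.0)
        # centromeres lead each mass toward its pole
        cen_pos = (
            mass_centers[0] - spec.centromere_offset_um,
            mass_centers[1] + spec.centromere_offset_um,
        )
        chrom = sum(
            _gauss_spot(xx_um, yy_um, mx, cy_um, spec.mass_sigma_um, spec.mass_intensity)
            for mx in mass_centers
        )
        pole_img = sum(
            _gauss_spot(xx_um, yy_um, pxu, cy_um, spec.marker_sigma_um, spec.mass_intensity)
            for pxu in pole_pos
        )
        cen_img = sum(
            _gauss_spot(xx_um, yy_um, cxu, cy_um, spec.marker_sigma_um, spec.mass_intensity)
            for cxu in cen_pos
        )
        if spec.noise_sd > 0:
            chrom = np.clip(chrom + rng.normal(0, spec.noise_sd, chrom.shape), 0, None)
            pole_img = np.clip(pole_img + rng.normal(0, spec.noise_sd, chrom.shape), 0, None)
            cen_img = np.clip(cen_img + rng.normal(0, spec.noise_sd, chrom.shape), 0, None)
        chrom_frames.append(CalibratedImage(chrom, px, "chromosome", float(t)))
        pole_frames.append(CalibratedImage(pole_img, px, "pole", float(t)))
        cen_frames.append(CalibratedImage(cen_img, px, "centromere", float(t)))
        rows.append(
            {
                "time_min": float(t),
                "mass_separation_um": d,
                "pole_separation_um": pole_sep,
                "cen_separation_um": d + 2 * spec.centromere_offset_um,
                "pole1_x_px": pole_pos[0] / px,
                "pole1_y_px": cy_um / px,
                "pole2_x_px": pole_pos[1] / px,
                "pole2_y_px": cy_um / px,
            }
        )
    movie = TimeLapse(
        channels={"chromosome": chrom_frames, "pole": pole_frames, "centromere": cen_frames},
        timestamps=times,
    )
    return movie, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lobed nucleus masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusSpec:
    """A lobed-nucleus shape with analytically known solidity.

    The boundary is a cosine-modulated ellipse radius,
    r(θ) = R(θ) · (1 − lobe_depth · max(0, cos(n_lobes·θ + φ))),
    where R(θ) is the base-ellipse radius.  ``n_lobes = 0`` or
    ``lobe_depth = 0`` gives a plain (convex) ellipse with solidity 1.
    """

    semi_axes_um: tuple[float, float] = (7.0, 5.0)
    n_lobes: int = 0
    lobe_depth: float = 0.0
    phase: float = 0.0
    pixel_size_um: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.lobe_depth < 1):
            raise ValueError("lobe_depth must be in [0, 1)")
        if self.n_lobes < 0:
            raise ValueError("n_lobes must be >= 0")
        if min(self.semi_axes_um) <= 0:
            raise ValueError("semi-axes must be positive")


def _nucleus_boundary_um(spec: NucleusSpec, n_theta: int) -> np.ndarray:
    """Dense (x, y) samples of the continuous nucleus boundary, in μm."""
    a, b = spec.semi_axes_um
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    r_ellipse = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if spec.n_lobes > 0 and spec.lobe_depth > 0:
        mod = 1.0 - spec.lobe_depth * np.maximum(
            0.0, np.cos(spec.n_lobes * theta + spec.phase)
        )
    else:
        mod = np.ones_like(theta)
    r = r_ellipse * mod
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_solidity(spec: NucleusSpec, n_theta: int = 8192) -> float:
    """Continuous ground-truth solidity: shoelace area of the generating
    polygon over the area of its convex hull."""
    pts = _nucleus_boundary_um(spec, n_theta)
    area = _polygon_area(pts)
    hull = ConvexHull(pts)
    return float(area / hull.volume)  # in 2-D, .volume is the hull area


def generate_nucleus_mask(spec: NucleusSpec) -> tuple[np.ndarray, float]:
    """Rasterize the nucleus polygon; returns (binary mask, truth solidity).

    Truth solidity is computed from the continuous boundary, not the raster,
    so the raster's measured solidity converges to it as pixel size shrinks.
    """
    from skimage.draw import polygon as draw_polygon

    pts = _nucleus_boundary_um(spec, 2048)
    px = spec.pixel_size_um
    margin = 2
    half_w = int(np.ceil(np.abs(pts[:, 0]).max() / px)) + margin
    half_h = int(np.ceil(np.abs(pts[:, 1]).max() / px)) + margin
    rows = pts[:, 1] / px + half_h
    cols = pts[:, 0] / px + half_w
    mask = np.zeros((2 * half_h + 1, 2 * half_w + 1), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    if rr.size == 0:
        raise ValueError("degenerate polygon: rasterization is empty")
    mask[rr, cc] = True
    return mask, polygon_solidity(spec)


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapSpec:
    """A photobleaching recovery trace with mobile and immobile pools.

    Post-bleach bleached-ROI signal follows
    S(t) = B + P·[d + m·(1 − d)·(1 − exp(−t/τ))], with P the pre-bleach
    signal level, d the fraction remaining immediately after the bleach,
    m the mobile fraction, and B the camera/background level.  The unbleached
    ROI stays at P + B.  Sampling: pre-bleach frames at 5-s spacing covering
    the 25 s before the bleach (−25 s … −5 s), the bleach at t = 0 with the
    first post-bleach frame captured immediately (t = 0), then post-bleach
    frames every 20 s out to 600 s.
    """

    prebleach_level: float = 1000.0
    bleach_depth: float = 0.2
    mobile_fraction: float = 1.0
    recovery_tau_s: float = 40.0
    background_level: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.bleach_depth <= 1):
            raise ValueError("bleach_depth must be in [0, 1]")
        if not (0 <= self.mobile_fraction <= 1):
            raise ValueError("mobile_fraction must be in [0, 1]")
        if not self.recovery_tau_s > 0:
            raise ValueError("recovery_tau_s must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_frap_trace(spec: FrapSpec):
    """Simulate a FRAP acquisition; returns a FrapTrace carrying the spec.

    Truth: the noiseless normalized post-bleach curve is
    d + m·(1 − d)·(1 − exp(−t/τ)), so the immediate post-bleach fraction is
    ``bleach_depth`` and the plateau is ``d + m·(1 − d)``.
    """
    from .frap import FrapTrace

    pre_times = np.arange(-25.0, -5.0 + 1e-9, 5.0)  # covers the 25 s pre-bleach window
    post_times = np.arange(0.0, 600.0 + 1e-9, 20.0)  # first frame right after the bleach
    times = np.concatenate([pre_times, post_times])
    bleach_index = len(pre_times)

    P, d, m = spec.prebleach_level, spec.bleach_depth, spec.mobile_fraction
    B, tau = spec.background_level, spec.recovery_tau_s
    recovery = d + m * (1.0 - d) * (1.0 - np.exp(-post_times / tau))
    bleached = np.concatenate([np.full(len(pre_times), P + B), B + P * recovery])
    unbleached = np.full(len(times), P + B)
    background = np.full(len(times), B)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        bleached = bleached + rng.normal(0, spec.noise_sd, bleached.shape)
        unbleached = unbleached + rng.normal(0, spec.noise_sd, unbleached.shape)
        background = background + rng.normal(0, spec.noise_sd, background.shape)
    return FrapTrace(
        times=times,
        bleached=bleached,
        unbleached=unbleached,
        background=background,
        bleach_index=bleach_index,
    )


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSpec:
    """Exponential well counts: N(t) = initial_count · b^(t/τ) · (1 + ε).

    ``b`` is the effective per-cycle multiplication factor (2 when every cell
    divides; 2 − f when a fraction f fails to divide each cycle) and ``tau``
    the doubling period in hours.  ε is i.i.d. mean-zero with coefficient of
    variation ``count_noise_cv``.  Sampling every 4 h for 96 h mirrors an
    automated-imaging proliferation assay.
    """

    b: float = 2.0
    tau_hr: float = 20.72
    t_max_hr: float = 96.0
    sample_interval_hr: float = 4.0
    initial_count: float = 15000.0
    count_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.b > 1:
            raise ValueError("b must be > 1")
        if not self.tau_hr > 0:
            raise ValueError("tau_hr must be > 0")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be >= 0")


def generate_growth_curve(spec: GrowthSpec, well_id: str = "well", condition: str = ""):
    """Simulate a proliferation-assay well; returns a GrowthCurve."""
    from .growth import GrowthCurve

    times = np.arange(0.0, spec.t_max_hr + 1e-9, spec.sample_interval_hr)
    counts = spec.initial_count * spec.b ** (times / spec.tau_hr)
    if spec.count_noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        counts = counts * (1.0 + rng.normal(0.0, spec.count_noise_cv, counts.shape))
        counts = np.clip(counts, 0.0, None)
    return GrowthCurve(times=times, counts=counts, well_id=well_id, condition=condition)
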