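"""Nuclear-morphology quantification: solidity and abnormal-shape calls.

Solidity — the ratio of a nucleus's area to the area of its convex hull — is
1 for a smoothly oval nucleus and drops below 1 as the nucleus becomes lobed
or fragmented.  The classification rule is dataset-relative: the 5th
percentile of solidity in the control population defines the threshold, and
any nucleus strictly below it is called abnormal.  Because the threshold is
a percentile of each experiment's own controls, thresholds are never
transferable between datasets; every summary therefore records the threshold
value and the number of controls behind it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .imaging import CalibratedImage

__all__ = [
    "NucleusRecord",
    "SolidityThreshold",
    "ClassificationSummary",
    "segment_nuclei",
    "solidity",
    "measure_nuclei",
    "control_threshold",
    "classify",
]

MIN_CONTROL_N = 20  # below this, a 5th percentile is not meaningful


@dataclass
class NucleusRecord:
    """One segmented nucleus with its shape measurements."""

    label: int
    area_px: int
    area_um2: float
    convex_area_px: int
    solidity: float
    touches_border: bool
    experiment_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.solidity <= 1):
            raise ValueError(f"solidity must be in (0, 1], got {self.solidity}")
        if self.convex_area_px < self.area_px:
            raise ValueError("convex area cannot be smaller than area")


@dataclass
class SolidityThreshold:
    """A control-derived solidity cut-off with its provenance."""

    value: float
    percentile: float
    control_n: int


@dataclass
class ClassificationSummary:
    """Per-condition abnormal-nucleus summary."""

    table: pd.DataFrame  # condition, n, n_abnormal, fraction_abnormal, median_solidity
    threshold: SolidityThreshold


def segment_nuclei(
    dapi: CalibratedImage,
    min_area_um2: float = 20.0,
    max_area_um2: float = 500.0,
    exclude_border: bool = True,
) -> list[np.ndarray]:
    """Segment interphase nuclei from a DNA-stain image.

    Otsu threshold → hole filling → connected components → area filter;
    objects touching the image border are truncated shapes and are excluded
    by default.  Returns one boolean mask (full image size) per nucleus.
    An empty field yields an empty list, not an error.
    """
    img = dapi.pixels
    if np.ptp(img) == 0:
        raise ValueError("constant image cannot be segmented")
    thresh = threshold_otsu(img)
    binary = ndi.binary_fill_holes(img > thresh)
    labelled = label(binary)
    px_area_um2 = dapi.pixel_size_um**2
    h, w = labelled.shape
    masks: list[np.ndarray] = []
    for region in regionprops(labelled):
        area_um2 = region.area * px_area_um2
        if not (min_area_um2 <= area_um2 <= max_area_um2):
            continue
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        if touches and exclude_border:
            continue
        masks.append(labelled == region.label)
    return masks


def solidity(mask: np.ndarray) -> float:
    """Solidity of a binary mask: pixel count over filled-convex-hull pixel count.

    The hull is the convex hull of the mask's pixel *centers*, rasterized with
    the same pixel-center rule used for ROI membership, so a convex rasterized
    shape scores 1 exactly (its own centers are the only ones inside the hull).
    Degenerate (collinear) masks are their own hull and score 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    try:
        from scipy.spatial import ConvexHull, QhullError

        hull = ConvexHull(pts)
    except QhullError:
        return 1.0
    # rasterize the hull over the bounding box with the pixel-center rule
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    normals, offsets = hull.equations[:, :2], hull.equations[:, 2]
    inside = (grid @ normals.T + offsets <= 1e-9).all(axis=1)
    return float(mask.sum() / inside.sum())


def measure_nuclei(
    masks: list[np.ndarray],
    pixel_size_um: float,
    experiment_id: str = "",
    condition: str = "",
) -> list[NucleusRecord]:
    """Turn segmented masks into NucleusRecords (area, convex area, solidity)."""
    records = []
    for i, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        area = int(mask.sum())
        s = solidity(mask)
        records.append(
            NucleusRecord(
                label=i + 1,
                area_px=area,
                area_um2=area * pixel_size_um**2,
                convex_area_px=int(round(area / s)),
                solidity=s,
                touches_border=False,
                experiment_id=experiment_id,
                condition=condition,
            )
        )
    return records


def control_threshold(
    control_solidities: np.ndarray | list[float], percentile: float = 5.0
) -> SolidityThreshold:
    """Percentile threshold from the control solidity distribution.

    Uses linear interpolation between order statistics (the spreadsheet /
    numpy default); the convention matters because reported thresholds are
    quoted to three decimals.  Requires at least 20 controls.
    """
    vals = np.asarray(control_solidities, dtype=float)
    if vals.size < MIN_CONTROL_N:
        raise ValueError(
            f"need >= {MIN_CONTROL_N} control nuclei for a stable percentile, got {vals.size}"
        )
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    value = float(np.percentile(vals, percentile, method="linear"))
    return SolidityThreshold(value=value, percentile=percentile, control_n=int(vals.size))


def classify(
    records: list[NucleusRecord], threshold: SolidityThreshold
) -> ClassificationSummary:
    """Call each nucleus normal/abnormal and summarise per condition.

    Abnormal means solidity strictly below the threshold; a nucleus exactly
    at the threshold is normal.
    """
    df = pd.DataFrame(
        {
            "condition": [r.condition for r in records],
            "experiment_id": [r.experiment_id for r in records],
            "solidity": [r.solidity for r in records],
        }
    )
    df["abnormal"] = df["solidity"] < threshold.value
    if df.empty:
        table = pd.DataFrame(
            columns=["condition", "n", "n_abnormal", "fraction_abnormal", "median_solidity"]
        )
    else:
        table = (
            df.groupby("condition", sort=False)
            .agg(
                n=("solidity", "size"),
                n_abnormal=("abnormal", "sum"),
                median_solidity=("solidity", "median"),
            )
            .reset_index()
        )
        table["fraction_abnormal"] = table["n_abnormal"] / table["n"]
        table = table[["condition", "n", "n_abnormal", "fraction_abnormal", "median_solidity"]]
    return ClassificationSummary(table=table, threshold=threshold)
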