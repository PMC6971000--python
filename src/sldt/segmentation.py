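"""Low-level segmentation operators shared by all three analyzers.

Two primitives cover every measurement in the pipeline:

* :func:`segment_area` — foreground-area segmentation of one fluorescence
  channel (smooth → threshold → close → fill → size-filter), used for the
  tracer-stained band and the loaded-cell band;
* :func:`label_nuclei` — the same mask refined by a distance-transform
  watershed so that touching nuclei are split before counting.

Blank channels are not an error: auto-thresholding a signal-free image would
binarize noise, so a contrast guard returns an empty mask with a QC flag
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation as sk_seg
from skimage.feature import peak_local_max

from .io import Calibration, px_area_to_um2

__all__ = [
    "SegmentationParams",
    "BinaryMask",
    "LabeledMask",
    "segment_area",
    "label_nuclei",
    "binary_dilate",
    "binary_erode",
    "binary_close",
]

#: QC flag names
BLANK_CHANNEL = "blank_channel"


def binary_dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean dilation via the distance transform (fast at any radius)."""
    if radius_px <= 0 or not mask.any():
        return mask
    return ndi.distance_transform_edt(~mask) <= radius_px


def binary_erode(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean erosion; the image border is treated as foreground."""
    if radius_px <= 0 or not mask.any():
        return mask
    return ndi.distance_transform_edt(mask) > radius_px


def binary_close(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean closing (dilate then erode)."""
    return binary_erode(binary_dilate(mask, radius_px), radius_px)


def _drop_small(mask: np.ndarray, min_area_px: float) -> np.ndarray:
    if min_area_px <= 1 or not mask.any():
        return mask
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[labels]


@dataclass
class SegmentationParams:
    """Tunable segmentation settings (normally read from the YAML config).

    ``method`` is one of ``"otsu"`` (default), ``"triangle"`` (better for
    images with a very small foreground fraction) or ``"fixed"`` with an
    explicit ``threshold`` in raw intensity units.
    """

    sigma_px: float = 1.0
    method: str = "otsu"
    threshold: float | None = None
    min_area_um2: float = 100.0
    fill_holes: bool = True
    closing_radius_px: int = 1
    #: auto-threshold blank guard: foreground/background mean separation must
    #: exceed this many background standard deviations.
    blank_min_contrast: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_px < 0:
            raise ValueError("sigma_px must be >= 0")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.method not in ("otsu", "triangle", "fixed"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "fixed" and self.threshold is None:
            raise ValueError("fixed threshold method requires a threshold value")


@dataclass
class BinaryMask:
    """A boolean raster plus its calibration and any QC flags raised."""

    mask: np.ndarray
    calibration: Calibration
    qc_flags: set = field(default_factory=set)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return px_area_to_um2(self.area_px, self.calibration)


@dataclass
class LabeledMask:
    """Integer-labelled objects (0 = background) with a per-object table."""

    labels: np.ndarray
    calibration: Calibration
    table: pd.DataFrame  # columns: label, area_um2, centroid_row, centroid_col
    qc_flags: set = field(default_factory=set)

    @property
    def n_objects(self) -> int:
        return int(self.table.shape[0])


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["label", "area_um2", "centroid_row", "centroid_col"])


def _threshold(smoothed: np.ndarray, raster: np.ndarray, params: SegmentationParams) -> float:
    if params.method == "fixed":
        thr = float(params.threshold)
        if np.issubdtype(raster.dtype, np.integer):
            lo, hi = 0, np.iinfo(raster.dtype).max
            if not lo <= thr <= hi:
                raise ValueError(
                    f"fixed threshold {thr} outside the {raster.dtype} range [{lo}, {hi}]"
                )
        return thr
    if params.method == "triangle":
        return float(filters.threshold_triangle(smoothed))
    return float(filters.threshold_otsu(smoothed))


def segment_area(
    raster: np.ndarray,
    params: SegmentationParams,
    calibration: Calibration,
) -> BinaryMask:
    """Segment the stained area of one channel.

    Gaussian smoothing → global threshold → morphological closing → hole
    filling → removal of objects below ``min_area_um2``. A blank image under
    an auto threshold yields an empty mask with the ``blank_channel`` flag —
    never an exception.
    """
    if raster.size == 0:
        raise ValueError("empty raster")
    img = np.asarray(raster, dtype=float)
    smoothed = ndi.gaussian_filter(img, params.sigma_px) if params.sigma_px > 0 else img

    flags: set = set()
    if np.ptp(smoothed) == 0:
        if params.method != "fixed":
            flags.add(BLANK_CHANNEL)
            return BinaryMask(np.zeros(raster.shape, bool), calibration, flags)
        # constant image with a fixed threshold: all-or-nothing is well defined
        thr = _threshold(smoothed, raster, params)
        mask = smoothed > thr
        return BinaryMask(mask, calibration, flags)

    thr = _threshold(smoothed, raster, params)
    mask = smoothed > thr

    if params.method != "fixed":
        # contrast guard: refuse to call noise "foreground"
        fg, bg = smoothed[mask], smoothed[~mask]
        if fg.size == 0 or bg.size == 0:
            flags.add(BLANK_CHANNEL)
            return BinaryMask(np.zeros(raster.shape, bool), calibration, flags)
        bg_sd = bg.std()
        if bg_sd > 0 and (fg.mean() - bg.mean()) < params.blank_min_contrast * bg_sd:
            flags.add(BLANK_CHANNEL)
            return BinaryMask(np.zeros(raster.shape, bool), calibration, flags)

    if params.closing_radius_px > 0:
        mask = binary_close(mask, params.closing_radius_px)
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    mask = _drop_small(mask, params.min_area_um2 / calibration.pixel_size_um**2)
    if not mask.any():
        flags.add(BLANK_CHANNEL)
    return BinaryMask(mask, calibration, flags)


def label_nuclei(
    raster: np.ndarray,
    params: SegmentationParams,
    calibration: Calibration,
    min_seed_separation_px: int = 5,
) -> LabeledMask:
    """Label individual nuclei, splitting touching ones by watershed.

    The foreground mask from :func:`segment_area` is refined by a watershed
    on the (smoothed) Euclidean distance transform, seeded at its local
    maxima with a minimum separation of ``min_seed_separation_px`` (nominally
    one nucleus radius). Objects below ``min_area_um2`` are dropped after
    splitting. Ties between equal maxima resolve deterministically
    (row-major order, as returned by the peak detector).
    """
    bm = segment_area(raster, params, calibration)
    if not bm.mask.any():
        return LabeledMask(np.zeros(raster.shape, int), calibration, _empty_table(), bm.qc_flags)

    dist = ndi.distance_transform_edt(bm.mask)
    dist_s = ndi.gaussian_filter(dist, 1.0)
    coords = peak_local_max(
        dist_s,
        min_distance=max(1, int(min_seed_separation_px)),
        labels=bm.mask,
        exclude_border=False,
    )
    markers = np.zeros(raster.shape, int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # mask present but no interior maximum (thin sliver)
        markers, _ = ndi.label(bm.mask)
    labels = sk_seg.watershed(-dist_s, markers, mask=bm.mask)

    min_area_px = params.min_area_um2 / calibration.pixel_size_um**2
    rows = []
    out = np.zeros(raster.shape, int)
    next_label = 1
    for prop in measure.regionprops(labels):
        if prop.area < min_area_px:
            continue
        out[labels == prop.label] = next_label
        rows.append(
            {
                "label": next_label,
                "area_um2": px_area_to_um2(prop.area, calibration),
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
            }
        )
        next_label += 1
    table = pd.DataFrame(rows) if rows else _empty_table()
    return LabeledMask(out, calibration, table, bm.qc_flags)
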