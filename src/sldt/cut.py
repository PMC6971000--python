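"""GJIC quantification for one cut region (tracer vs. loaded area).

The per-image GJIC endpoint is the *net dye-transfer area*: the area stained
by the gap-junction-permeant tracer minus the area of the initially loaded
cells along the cut, clamped at zero. The loaded-cell measurement is, by
default, restricted to the detected cut band so that scattered dead (PI+)
cells elsewhere in the monolayer do not inflate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .io import Calibration, ChannelSet
from .segmentation import (
    BinaryMask,
    SegmentationParams,
    binary_close,
    binary_dilate,
    segment_area,
)

__all__ = ["CutParams", "CutResult", "analyze_cut", "build_cut_region"]

CUT_NOT_FOUND = "cut_not_found"
CLAMPED_NEGATIVE = "clamped_negative"


def default_tracer_params() -> SegmentationParams:
    return SegmentationParams(min_area_um2=100.0)


def default_red_params() -> SegmentationParams:
    return SegmentationParams(min_area_um2=30.0)


@dataclass
class CutParams:
    """Cut-band detection settings.

    The loaded row appears as separate nuclei/cell bodies along a line;
    closing with ``band_closing_um`` merges them into one elongated
    structure, which qualifies as a cut when its major/minor axis ratio is at
    least ``min_elongation``. The accepted structure is dilated by
    ``band_dilation_um`` into the measurement band.
    """

    band_closing_um: float = 20.0
    band_dilation_um: float = 5.0
    min_elongation: float = 5.0
    #: restrict the loaded-area measurement to the detected band (default) or
    #: use the whole-image red mask.
    restrict_to_band: bool = True


@dataclass
class CutResult:
    """Per-image GJIC measurement (areas in µm²)."""

    tracer_area_um2: float
    loaded_area_um2: float
    net_transfer_area_um2: float
    qc_flags: set = field(default_factory=set)


def _band_from_mask(
    red_mask: BinaryMask, calibration: Calibration, cut_params: CutParams
) -> BinaryMask:
    flags = set(red_mask.qc_flags)
    if not red_mask.mask.any():
        flags.add(CUT_NOT_FOUND)
        return BinaryMask(np.zeros(red_mask.mask.shape, bool), calibration, flags)

    px = calibration.pixel_size_um
    closed = binary_close(red_mask.mask, cut_params.band_closing_um / px)
    labels = measure.label(closed)
    props = measure.regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    minor = max(largest.axis_minor_length, 1e-9)
    if largest.axis_major_length / minor < cut_params.min_elongation:
        flags.add(CUT_NOT_FOUND)
        return BinaryMask(np.zeros(red_mask.mask.shape, bool), calibration, flags)

    band = binary_dilate(labels == largest.label, cut_params.band_dilation_um / px)
    return BinaryMask(band, calibration, flags)


def build_cut_region(
    red_raster: np.ndarray,
    red_params: SegmentationParams | None = None,
    calibration: Calibration | None = None,
    cut_params: CutParams | None = None,
) -> BinaryMask:
    """Detect the cut as the largest elongated red-channel structure.

    Returns the band mask; when no sufficiently elongated structure exists
    (e.g. only scattered dead cells), the mask is empty and carries the
    ``cut_not_found`` flag — callers fall back to the whole-image red mask.
    """
    if calibration is None:
        raise ValueError("calibration is required")
    red_params = red_params or default_red_params()
    cut_params = cut_params or CutParams()
    red_mask = segment_area(red_raster, red_params, calibration)
    return _band_from_mask(red_mask, calibration, cut_params)


def analyze_cut(
    cs: ChannelSet,
    tracer_params: SegmentationParams | None = None,
    red_params: SegmentationParams | None = None,
    cut_params: CutParams | None = None,
) -> CutResult:
    """Measure tracer area, loaded area and net transfer for one image.

    ``net = max(0, tracer − loaded)``; a negative difference is clamped to 0
    and flagged rather than reported (negative transfer is physically
    meaningless). The tracer area covers the whole field of view — cut-end
    fields are the caller's responsibility to exclude.
    """
    tracer_params = tracer_params or default_tracer_params()
    red_params = red_params or default_red_params()
    cut_params = cut_params or CutParams()
    cal = cs.calibration

    tracer_mask = segment_area(cs.tracer, tracer_params, cal)
    red_mask = segment_area(cs.red, red_params, cal)
    band = _band_from_mask(red_mask, cal, cut_params)

    flags = set(tracer_mask.qc_flags) | set(red_mask.qc_flags) | set(band.qc_flags)

    if CUT_NOT_FOUND in band.qc_flags or not cut_params.restrict_to_band:
        loaded_px = red_mask.area_px
    else:
        loaded_px = int((red_mask.mask & band.mask).sum())

    tracer_area = tracer_mask.area_um2
    loaded_area = cal.px_area_to_um2(loaded_px)
    net = tracer_area - loaded_area
    if net < 0:
        flags.add(CLAMPED_NEGATIVE)
        net = 0.0
    return CutResult(tracer_area, loaded_area, net, flags)
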