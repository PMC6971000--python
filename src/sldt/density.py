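"""Cell-density endpoint: total nuclei outside the cut region.

The cut band (where cells were scraped or dye-loaded) plus a safety margin is
excluded, and nuclei are counted by the centroid-in-region rule — an object
contributes if and only if its centroid lies outside the exclusion zone,
which keeps boundary handling unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ChannelSet
from .segmentation import (
    BinaryMask,
    LabeledMask,
    SegmentationParams,
    binary_dilate,
    label_nuclei,
)

__all__ = ["ExclusionZone", "CountResult", "build_exclusion_zone", "count_total_cells"]

ZONE_COVERS_FOV = "zone_covers_fov"

#: margin beyond the detected cut band excluded from counting (µm); wide
#: enough to drop the loaded row and immediate neighbours, whose red signal
#: stems from loading rather than death.
DEFAULT_MARGIN_UM = 100.0


def default_nuclear_params() -> SegmentationParams:
    return SegmentationParams(min_area_um2=30.0)


@dataclass
class ExclusionZone:
    """Cut band dilated by ``margin_um``; shared by density and viability."""

    mask: BinaryMask
    margin_um: float = DEFAULT_MARGIN_UM

    def __post_init__(self) -> None:
        if self.margin_um < 0:
            raise ValueError("margin_um must be >= 0")

    @property
    def area_um2(self) -> float:
        return self.mask.area_um2


@dataclass
class CountResult:
    """An object count plus the QC flags raised while producing it."""

    count: int
    qc_flags: set = field(default_factory=set)

    def __int__(self) -> int:
        return self.count


def build_exclusion_zone(band: BinaryMask, margin_um: float = DEFAULT_MARGIN_UM) -> ExclusionZone:
    """Dilate the detected cut band by ``margin_um`` into the exclusion zone."""
    if margin_um < 0:
        raise ValueError("margin_um must be >= 0")
    mask = binary_dilate(band.mask, margin_um / band.calibration.pixel_size_um)
    return ExclusionZone(
        BinaryMask(mask, band.calibration, set(band.qc_flags)), margin_um
    )


def count_labels_outside(labeled: LabeledMask, zone: ExclusionZone) -> CountResult:
    """Count labelled objects whose centroid lies outside the zone."""
    flags = set(labeled.qc_flags) | set(zone.mask.qc_flags)
    zmask = zone.mask.mask
    if zmask.all():
        flags.add(ZONE_COVERS_FOV)
        return CountResult(0, flags)
    if labeled.n_objects == 0:
        return CountResult(0, flags)
    rows = labeled.table["centroid_row"].round().astype(int).clip(0, zmask.shape[0] - 1)
    cols = labeled.table["centroid_col"].round().astype(int).clip(0, zmask.shape[1] - 1)
    outside = ~zmask[rows.to_numpy(), cols.to_numpy()]
    return CountResult(int(outside.sum()), flags)


def count_total_cells(
    cs: ChannelSet,
    zone: ExclusionZone,
    nuc_params: SegmentationParams | None = None,
    min_seed_separation_px: int = 5,
) -> CountResult:
    """Total cell number: nuclei with centroid outside the exclusion zone."""
    if zone.mask.mask.shape != cs.shape:
        raise ValueError("exclusion zone dimensions do not match the image")
    nuc_params = nuc_params or default_nuclear_params()
    labeled = label_nuclei(cs.nuclear, nuc_params, cs.calibration, min_seed_separation_px)
    return count_labels_outside(labeled, zone)
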