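"""Viability endpoint: dead (PI+) cells outside the cut, viable cells, % dead.

Outside the cut region, propidium iodide only enters cells with a
compromised membrane, so red-channel objects there are dead cells. Viable
cells are total minus dead; % dead is the PI+/Hoechst+ ratio × 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ChannelSet
from .segmentation import SegmentationParams, label_nuclei
from .density import CountResult, ExclusionZone, count_labels_outside

__all__ = ["CellCounts", "count_dead_cells", "compute_counts"]

DEAD_EXCEEDS_TOTAL = "dead_exceeds_total"
PCT_DEAD_UNDEFINED = "pct_dead_undefined"


def default_dead_params() -> SegmentationParams:
    return SegmentationParams(min_area_um2=30.0)


@dataclass
class CellCounts:
    """Total / dead / viable cell numbers and % dead for one image."""

    total: int
    dead: int
    viable: int
    pct_dead: float
    qc_flags: set = field(default_factory=set)


def count_dead_cells(
    cs: ChannelSet,
    zone: ExclusionZone,
    red_params: SegmentationParams | None = None,
    min_seed_separation_px: int = 5,
    colocalize_with: "object | None" = None,
) -> CountResult:
    """Count red-channel objects with centroid outside the exclusion zone.

    Dead cells are counted as independent red objects, with no requirement
    of overlap with a nuclear label. For dyes or compounds that bleed into
    the red channel, pass a nuclear :class:`~sldt.segmentation.LabeledMask`
    as ``colocalize_with`` to keep only objects whose area overlaps a
    nucleus by at least 50%.
    """
    if zone.mask.mask.shape != cs.shape:
        raise ValueError("exclusion zone dimensions do not match the image")
    red_params = red_params or default_dead_params()
    labeled = label_nuclei(cs.red, red_params, cs.calibration, min_seed_separation_px)

    if colocalize_with is not None and labeled.n_objects:
        nuc_fg = colocalize_with.labels > 0
        keep = []
        for row in labeled.table.itertuples():
            obj = labeled.labels == row.label
            if (obj & nuc_fg).sum() >= 0.5 * obj.sum():
                keep.append(row.label)
        table = labeled.table[labeled.table["label"].isin(keep)].reset_index(drop=True)
        labels = np.where(np.isin(labeled.labels, keep), labeled.labels, 0)
        labeled = type(labeled)(labels, labeled.calibration, table, labeled.qc_flags)

    return count_labels_outside(labeled, zone)


def compute_counts(total: int, dead: int) -> CellCounts:
    """Derive viable count and % dead from total and dead counts.

    ``viable = total − dead``; ``pct_dead = 100 × dead / total``. If the dead
    count exceeds the total it is capped with a QC flag; a zero total makes
    % dead undefined (NaN, flagged).
    """
    if total < 0 or dead < 0:
        raise ValueError("counts must be non-negative")
    flags: set = set()
    if dead > total:
        flags.add(DEAD_EXCEEDS_TOTAL)
        dead = total
    viable = total - dead
    if total == 0:
        flags.add(PCT_DEAD_UNDEFINED)
        pct = float("nan")
    else:
        pct = 100.0 * dead / total
    return CellCounts(total, dead, viable, pct, flags)
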