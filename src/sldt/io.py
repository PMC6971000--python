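"""Calibrated image I/O, plate layouts and pixel↔micron conversions.

The scrape-loading/dye-transfer (SL-DT) assay acquires, for every cut region,
three co-registered grayscale fluorescence channels:

* ``tracer``  — the gap-junction-permeant dye (Lucifer Yellow, GFP filter);
* ``red``    — the loading / dead-cell marker (propidium iodide or
  Texas Red-dextran, rhodamine filter);
* ``nuclear`` — the pan-nuclear stain (Hoechst 33342, DAPI filter).

All downstream measurements are reported in physical units; the calibration
is a single scalar (µm per pixel, square pixels assumed). The default
corresponds to a 1936 × 1460 px field of view spanning 1396 × 1053 µm at a
10× objective.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "Calibration",
    "ChannelSet",
    "ImageMeta",
    "PlateLayout",
    "WellInfo",
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_FILENAME_PATTERN",
    "CHANNEL_CODES",
    "default_calibration",
    "load_channel_set",
    "expected_image_count",
    "px_area_to_um2",
]

#: Field-of-view width calibration: 1936 px correspond to 1396 µm.
DEFAULT_FOV_WIDTH_PX = 1936
DEFAULT_FOV_HEIGHT_PX = 1460
DEFAULT_FOV_WIDTH_UM = 1396.0

#: µm per pixel implied by the width calibration (square pixels).
DEFAULT_PIXEL_SIZE_UM = DEFAULT_FOV_WIDTH_UM / DEFAULT_FOV_WIDTH_PX  # ≈ 0.72107

#: filename convention ``<well>_<cut>_<channel>.tif`` with channel dye codes.
DEFAULT_FILENAME_PATTERN = (
    r"(?P<well>[A-Za-z0-9]+)_(?P<cut>\d+)_(?P<channel>LY|PI|HB)\.tiff?$"
)

#: dye code → channel role.
CHANNEL_CODES = {"LY": "tracer", "PI": "red", "HB": "nuclear"}

#: plate format → cuts per well/dish.
PLATE_FORMATS = {"dish35": 3, "plate24": 3, "plate48": 2, "plate96": 1}


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of an acquisition (square pixels)."""

    pixel_size_um: float
    image_width_px: int
    image_height_px: int

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def fov_width_um(self) -> float:
        return self.image_width_px * self.pixel_size_um

    @property
    def fov_height_um(self) -> float:
        return self.image_height_px * self.pixel_size_um

    @property
    def fov_area_um2(self) -> float:
        return self.fov_width_um * self.fov_height_um

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um

    def px_area_to_um2(self, area_px: float) -> float:
        return px_area_to_um2(area_px, self)


def default_calibration() -> Calibration:
    """The documented default: 1936 × 1460 px ≙ 1396 × 1053 µm."""
    return Calibration(DEFAULT_PIXEL_SIZE_UM, DEFAULT_FOV_WIDTH_PX, DEFAULT_FOV_HEIGHT_PX)


def px_area_to_um2(area_px: float, calibration: Calibration) -> float:
    """Convert a pixel count to an area in µm² (``area_px × pixel_size²``)."""
    if area_px < 0:
        raise ValueError(f"pixel area must be non-negative, got {area_px}")
    return float(area_px) * calibration.pixel_size_um**2


@dataclass
class ImageMeta:
    """Provenance of one cut-region acquisition."""

    well: str = ""
    cut_index: int = 0
    treatment: str = ""
    concentration: float = 0.0
    concentration_unit: str = ""
    is_vehicle_control: bool = False


@dataclass
class ChannelSet:
    """Three co-registered intensity rasters for one cut region.

    Rasters are kept as acquired integers (8- or 16-bit); no rescaling is
    performed at load time — thresholding decisions belong to segmentation.
    """

    tracer: np.ndarray
    red: np.ndarray
    nuclear: np.ndarray
    calibration: Calibration
    meta: ImageMeta = field(default_factory=ImageMeta)

    def __post_init__(self) -> None:
        shapes = {self.tracer.shape, self.red.shape, self.nuclear.shape}
        if len(shapes) != 1:
            raise ValueError(
                "channel dimension mismatch: "
                f"tracer {self.tracer.shape}, red {self.red.shape}, "
                f"nuclear {self.nuclear.shape}"
            )
        expected = (self.calibration.image_height_px, self.calibration.image_width_px)
        if self.tracer.shape != expected:
            raise ValueError(
                f"raster shape {self.tracer.shape} does not match calibration {expected}"
            )
        for role in ("tracer", "red", "nuclear"):
            arr = getattr(self, role)
            if arr.ndim != 2:
                raise ValueError(f"{role} channel must be a 2-D raster")
            if np.issubdtype(arr.dtype, np.signedinteger) and arr.min() < 0:
                raise ValueError(f"{role} channel contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tracer.shape


def _read_channel(path, role: str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{role} channel image not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{role} channel at {path} is not a single-plane grayscale image "
            f"(got shape {arr.shape}); RGB and multi-page TIFFs are rejected"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"{role} channel at {path} has dtype {arr.dtype}; expected 8- or 16-bit integers"
        )
    return arr


def load_channel_set(
    tracer_path,
    red_path,
    nuclear_path,
    calibration: Calibration | None = None,
    meta: ImageMeta | None = None,
    pixel_size_um: float | None = None,
) -> ChannelSet:
    """Load one cut region from three single-plane grayscale TIFFs.

    Either a full :class:`Calibration` or a scalar ``pixel_size_um`` must be
    supplied; in the latter case image dimensions are taken from the files.
    """
    tracer = _read_channel(tracer_path, "tracer")
    red = _read_channel(red_path, "red")
    nuclear = _read_channel(nuclear_path, "nuclear")
    if calibration is None:
        if pixel_size_um is None:
            raise ValueError("supply a Calibration or a pixel_size_um")
        calibration = Calibration(pixel_size_um, tracer.shape[1], tracer.shape[0])
    return ChannelSet(tracer, red, nuclear, calibration, meta or ImageMeta())


@dataclass
class WellInfo:
    treatment: str = ""
    concentration: float = 0.0
    concentration_unit: str = ""
    is_vehicle_control: bool = False


@dataclass
class PlateLayout:
    """Plate/dish layout: which wells exist and what each received.

    ``cuts_per_unit`` defaults by format: 35-mm dish → 3 cuts, 24-well → 3,
    48-well → 2, 96-well → 1.
    """

    format: str = "plate24"
    cuts_per_unit: int | None = None
    channels: tuple[str, ...] = ("LY", "PI", "HB")
    wells: dict[str, WellInfo] = field(default_factory=dict)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.format not in PLATE_FORMATS:
            raise ValueError(
                f"unknown plate format {self.format!r}; expected one of {sorted(PLATE_FORMATS)}"
            )
        if self.cuts_per_unit is None:
            self.cuts_per_unit = PLATE_FORMATS[self.format]
        if self.cuts_per_unit < 0:
            raise ValueError("cuts_per_unit must be >= 0")

    @property
    def control_wells(self) -> list[str]:
        return sorted(w for w, info in self.wells.items() if info.is_vehicle_control)

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        wells = {
            str(wid): WellInfo(
                treatment=str(w.get("treatment", "")),
                concentration=float(w.get("concentration", 0.0)),
                concentration_unit=str(w.get("concentration_unit", "")),
                is_vehicle_control=bool(w.get("is_vehicle_control", False)),
            )
            for wid, w in (doc.get("wells") or {}).items()
        }
        return cls(
            format=doc.get("format", "plate24"),
            cuts_per_unit=doc.get("cuts_per_unit"),
            channels=tuple(doc.get("channels", ("LY", "PI", "HB"))),
            wells=wells,
            pixel_size_um=float(doc.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "format": self.format,
            "cuts_per_unit": self.cuts_per_unit,
            "channels": list(self.channels),
            "pixel_size_um": self.pixel_size_um,
            "wells": {
                wid: {
                    "treatment": info.treatment,
                    "concentration": info.concentration,
                    "concentration_unit": info.concentration_unit,
                    "is_vehicle_control": info.is_vehicle_control,
                }
                for wid, info in sorted(self.wells.items())
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def expected_image_count(layout: PlateLayout) -> int:
    """Number of images an acquisition of this layout produces.

    ``|wells| × cuts_per_unit × |channels|`` — e.g. a full 24-well plate with
    3 cuts per well and 3 channels yields 216 images.
    """
    return len(layout.wells) * layout.cuts_per_unit * len(layout.channels)


def parse_image_name(name: str, pattern: str = DEFAULT_FILENAME_PATTERN):
    """Parse ``<well>_<cut>_<channel>.tif``; returns (well, cut, role) or None."""
    m = re.search(pattern, name)
    if not m:
        return None
    code = m.group("channel")
    return m.group("well"), int(m.group("cut")), CHANNEL_CODES.get(code, code)
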