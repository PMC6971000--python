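"""Synthetic scrape-loading/dye-transfer images with exact ground truth.

The generator renders the assay geometry rather than its photophysics: a
monolayer of cells on a jittered square lattice, a straight cut (wound) that
removes one row of cells, a single row of dye-loaded cells on either side of
the wound, a tracer-stained band whose half-width grows with the gap-junction
coupling ``g`` (``loaded row + g × D_max``), and a configurable fraction of
dead cells in the monolayer outside the cut region.

Channel semantics mirror the real assay:

* tracer channel — whole-cell disks of every loaded or coupled cell
  (Lucifer Yellow fills the cytoplasm and spreads junctionally);
* red channel — whole-cell disks of the loaded row (scrape-loading fills the
  cytoplasm with propidium iodide) plus nucleus-sized disks of dead cells;
* nuclear channel — nucleus disks of every cell (Hoechst is
  membrane-permeant).

Ground truth is computed from the noiseless geometric masks before any noise
is applied, so it is exact by construction and serves as the oracle for every
downstream analyzer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    Calibration,
    ChannelSet,
    ImageMeta,
    DEFAULT_PIXEL_SIZE_UM,
)
from .segmentation import BinaryMask

__all__ = ["SimConfig", "GroundTruth", "generate_assay_image", "generate_dose_series", "fourpl_curve"]


@dataclass
class SimConfig:
    """All knobs of the synthetic assay image.

    Geometry is specified in µm; the default field of view matches a 10×
    acquisition (1936 × 1460 px at ≈0.72107 µm/px → 1396 × 1053 µm). Lattice
    spacing 25 µm approximates a confluent epithelial monolayer (~1600
    cells/mm²); jitter is uniform per axis within ``± jitter × spacing / 2``.
    """

    image_height_px: int = 1460
    image_width_px: int = 1936
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    lattice_spacing_um: float = 25.0
    jitter_fraction: float = 0.2
    cell_radius_um: float = 10.0
    nucleus_radius_um: float = 5.0
    #: cut orientation: 0° → horizontal line, 90° → vertical.
    cut_angle_deg: float = 0.0
    #: perpendicular offset of the cut line from the image centre (µm).
    cut_offset_um: float = 0.0
    #: wound half-width — cells with centre distance below this are scraped away.
    cut_half_width_um: float = 12.0
    #: gap-junction coupling g ∈ [0, 1].
    coupling: float = 1.0
    #: maximal tracer spread beyond the loaded row at full coupling (µm).
    max_transfer_halfwidth_um: float = 250.0
    #: fraction of dead (PI+) cells among cells outside the exclusion zone.
    dead_fraction: float = 0.05
    #: ground-truth exclusion-zone margin beyond the loaded band (µm).
    exclusion_margin_um: float = 100.0
    foreground_level: float = 1000.0
    background_level: float = 100.0
    #: additive Gaussian noise sd; default gives SNR ≈ 10.
    noise_sd: float = 90.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling g must lie in [0, 1]")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must lie in [0, 1]")
        if self.max_transfer_halfwidth_um < 0:
            raise ValueError("max_transfer_halfwidth_um must be >= 0")
        for name in (
            "pixel_size_um",
            "lattice_spacing_um",
            "cell_radius_um",
            "nucleus_radius_um",
            "cut_half_width_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.jitter_fraction <= 1.0:
            raise ValueError("jitter_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_um, self.image_width_px, self.image_height_px)


@dataclass
class GroundTruth:
    """Exact geometric truth for one synthetic image."""

    true_transfer_area_um2: float
    true_loaded_area_um2: float
    true_tracer_area_um2: float
    true_total_cells: int
    true_dead_cells: int
    true_g: float
    #: exclusion-zone mask (cut band + margin) used for the count truths.
    exclusion_zone_mask: BinaryMask | None = None
    #: per-cell table: x_um, y_um, dist_um, kind, dead, counted.
    cell_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if min(self.true_transfer_area_um2, self.true_loaded_area_um2) < 0:
            raise ValueError("areas must be >= 0")
        if not 0 <= self.true_dead_cells <= self.true_total_cells:
            raise ValueError("0 <= dead <= total must hold")

    @property
    def true_pct_dead(self) -> float:
        if self.true_total_cells == 0:
            return float("nan")
        return 100.0 * self.true_dead_cells / self.true_total_cells


def _disk_mask(shape: tuple[int, int], centers_px: np.ndarray, radius_px: float) -> np.ndarray:
    """Union of disks; vectorised over a padded bounding box per centre."""
    mask = np.zeros(shape, bool)
    if centers_px.size == 0:
        return mask
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    stamp = (yy**2 + xx**2) <= radius_px**2
    h, w = shape
    for cy, cx in centers_px:
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(0, iy - r), min(h, iy + r + 1)
        x0, x1 = max(0, ix - r), min(w, ix + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        sy0, sy1 = y0 - (iy - r), stamp.shape[0] - ((iy + r + 1) - y1)
        sx0, sx1 = x0 - (ix - r), stamp.shape[1] - ((ix + r + 1) - x1)
        mask[y0:y1, x0:x1] |= stamp[sy0:sy1, sx0:sx1]
    return mask


def _render(
    fg_mask: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    img = np.where(fg_mask, cfg.foreground_level, cfg.background_level).astype(float)
    if cfg.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def generate_assay_image(
    config: SimConfig, meta: ImageMeta | None = None
) -> tuple[ChannelSet, GroundTruth]:
    """Render one three-channel cut-region image plus its ground truth.

    Deterministic for a fixed ``config.seed``: the same configuration yields
    bit-identical rasters and identical truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cal = cfg.calibration
    h_um = cfg.image_height_px * cfg.pixel_size_um
    w_um = cfg.image_width_px * cfg.pixel_size_um
    s = cfg.lattice_spacing_um

    # cut line through the image centre (+ offset along its normal)
    theta = math.radians(cfg.cut_angle_deg)
    nx, ny = -math.sin(theta), math.cos(theta)  # unit normal
    x0, y0 = w_um / 2.0 + nx * cfg.cut_offset_um, h_um / 2.0 + ny * cfg.cut_offset_um

    # jittered square lattice of cell centres (µm coordinates), with margin so
    # border cells are represented; for axis-aligned cuts the lattice is
    # anchored on the cut line, so the wound scrapes exactly one cell row and
    # the loaded row is the complete next row at one spacing's distance
    margin = s

    def _axis(lo: float, hi: float, anchor: float | None) -> np.ndarray:
        if anchor is None:
            return np.arange(lo, hi, s) + s / 2.0
        n_lo = math.ceil((anchor - lo) / s)
        n_hi = math.ceil((hi - anchor) / s)
        return anchor + np.arange(-n_lo, n_hi + 1) * s

    angle = cfg.cut_angle_deg % 180.0
    horizontal = math.isclose(angle, 0.0, abs_tol=1e-9)
    vertical = math.isclose(angle, 90.0, abs_tol=1e-9)
    ys = _axis(-margin, h_um + margin, y0 if horizontal else None)
    xs = _axis(-margin, w_um + margin, x0 if vertical else None)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    jit = cfg.jitter_fraction * s / 2.0
    cy = gy.ravel() + rng.uniform(-jit, jit, gy.size)
    cx = gx.ravel() + rng.uniform(-jit, jit, gx.size)

    # perpendicular distance of each centre to the cut line
    dist = np.abs((cx - x0) * nx + (cy - y0) * ny)

    wound = dist < cfg.cut_half_width_um
    loaded_outer = cfg.cut_half_width_um + s
    loaded = (~wound) & (dist < loaded_outer)
    band_outer = loaded_outer + cfg.coupling * cfg.max_transfer_halfwidth_um
    coupled = (~wound) & (~loaded) & (dist < band_outer)

    # ground-truth exclusion zone: realized outer edge of loaded cell disks
    # plus the configured margin, measured from the cut line
    if loaded.any():
        zone_halfwidth = float(dist[loaded].max()) + cfg.cell_radius_um + cfg.exclusion_margin_um
    else:
        zone_halfwidth = loaded_outer + cfg.cell_radius_um + cfg.exclusion_margin_um
    outside = (~wound) & (dist >= zone_halfwidth)

    # dead-cell assignment among cells outside the exclusion zone
    dead = np.zeros(cx.size, bool)
    dead[outside] = rng.uniform(size=int(outside.sum())) < cfg.dead_fraction

    px = cfg.pixel_size_um

    def to_px(sel: np.ndarray) -> np.ndarray:
        return np.column_stack([cy[sel] / px, cx[sel] / px])

    shape = (cfg.image_height_px, cfg.image_width_px)
    r_cell = cfg.cell_radius_um / px
    r_nuc = cfg.nucleus_radius_um / px

    loaded_mask = _disk_mask(shape, to_px(loaded), r_cell)
    tracer_mask = loaded_mask | _disk_mask(shape, to_px(coupled), r_cell)
    dead_mask = _disk_mask(shape, to_px(dead), r_nuc)
    red_mask = loaded_mask | dead_mask
    nuclear_mask = _disk_mask(shape, to_px(~wound), r_nuc)

    # exclusion-zone raster: pixels within zone_halfwidth of the cut line
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pix_dist = np.abs((xx * px + px / 2 - x0) * nx + (yy * px + px / 2 - y0) * ny)
    zone_mask = BinaryMask(pix_dist < zone_halfwidth, cal)

    # counts use the same centre-in-zone rule the analyzers apply to centroids;
    # only cells whose centre falls inside the field of view are countable
    in_fov = (cy >= 0) & (cy < h_um) & (cx >= 0) & (cx < w_um)
    countable = in_fov & outside
    true_total = int(countable.sum())
    true_dead = int((countable & dead).sum())

    area = px**2
    truth = GroundTruth(
        true_transfer_area_um2=float((tracer_mask & ~loaded_mask).sum()) * area,
        true_loaded_area_um2=float(loaded_mask.sum()) * area,
        true_tracer_area_um2=float(tracer_mask.sum()) * area,
        true_total_cells=true_total,
        true_dead_cells=true_dead,
        true_g=cfg.coupling,
        exclusion_zone_mask=zone_mask,
        cell_table=pd.DataFrame(
            {
                "x_um": cx,
                "y_um": cy,
                "dist_um": dist,
                "kind": np.select(
                    [wound, loaded, coupled], ["wound", "loaded", "coupled"], "outside"
                ),
                "dead": dead,
                "counted": countable,
            }
        ),
    )

    cs = ChannelSet(
        tracer=_render(tracer_mask, cfg, rng),
        red=_render(red_mask, cfg, rng),
        nuclear=_render(nuclear_mask, cfg, rng),
        calibration=cal,
        meta=meta or ImageMeta(),
    )
    return cs, truth


def fourpl_curve(c, bottom: float, top: float, ec50: float, hill: float):
    """4-parameter logistic: ``bottom + (top - bottom) / (1 + (c/ec50)^hill)``.

    With ``hill > 0`` the curve decreases from ``top`` (c → 0) to ``bottom``
    (c → ∞) — the inhibitor convention; ``hill < 0`` gives a stimulator.
    """
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)


def _derived_seed(master: int, index: int) -> int:
    """Per-image seed: counter-indexed SeedSequence child of the master seed."""
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0] % (2**31))


def generate_dose_series(
    base: SimConfig,
    concentrations,
    fourpl: tuple[float, float, float, float],
    n_replicates: int = 3,
    seed: int = 0,
    n_controls: int | None = None,
    treatment: str = "compound",
    concentration_unit: str = "",
) -> list[tuple[ChannelSet, GroundTruth]]:
    """Simulate a concentration–response experiment.

    For each concentration ``c`` the coupling is set on the generating curve
    ``g(c) = bottom + (top − bottom) / (1 + (c/ec50)^hill)`` and
    ``n_replicates`` images are rendered with per-replicate derived seeds.
    Vehicle controls (``n_controls``, default ``n_replicates``) are generated
    at ``g = top`` with concentration 0.
    """
    bottom, top, ec50, hill = (float(v) for v in fourpl)
    if not (0.0 <= bottom <= top <= 1.0):
        raise ValueError("4PL requires 0 <= bottom <= top <= 1 on the coupling scale")
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    concentrations = [float(c) for c in concentrations]
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be > 0 (controls are generated separately)")
    if n_controls is None:
        n_controls = n_replicates

    out: list[tuple[ChannelSet, GroundTruth]] = []
    counter = 0
    for rep in range(n_controls):
        cfg = replace(base, coupling=top, seed=_derived_seed(seed, counter))
        meta = ImageMeta(
            well=f"CTRL{rep + 1}",
            cut_index=1,
            treatment="vehicle",
            concentration=0.0,
            concentration_unit=concentration_unit,
            is_vehicle_control=True,
        )
        out.append(generate_assay_image(cfg, meta))
        counter += 1
    for ci, c in enumerate(concentrations):
        g = float(fourpl_curve(c, bottom, top, ec50, hill))
        for rep in range(n_replicates):
            cfg = replace(base, coupling=g, seed=_derived_seed(seed, counter))
            meta = ImageMeta(
                well=f"C{ci + 1:02d}R{rep + 1}",
                cut_index=1,
                treatment=treatment,
                concentration=c,
                concentration_unit=concentration_unit,
                is_vehicle_control=False,
            )
            out.append(generate_assay_image(cfg, meta))
            counter += 1
    return out
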