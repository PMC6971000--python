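"""Whole-plate orchestration: discover, analyze, normalize, test, fit, report.

A run walks an image directory named ``<well>_<cut>_<channel>.tif``
(channel ∈ LY/PI/HB), applies the three analyzers to every complete
three-channel triple, aggregates per well, normalizes endpoints to the
vehicle controls (FOC), runs the group-comparison decision tree per
concentration, and — when at least four treated concentrations are present —
fits the 4PL and summarizes the EC50. All outputs are plain CSV plus a JSON
run log; re-runs with identical inputs and configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .cut import CutParams, analyze_cut, build_cut_region, default_red_params, default_tracer_params
from .density import (
    DEFAULT_MARGIN_UM,
    build_exclusion_zone,
    count_total_cells,
    default_nuclear_params,
)
from .doseresponse import compare_groups, compute_foc, fit_4pl, summarize_ec50
from .io import (
    DEFAULT_FILENAME_PATTERN,
    CHANNEL_CODES,
    Calibration,
    ChannelSet,
    ImageMeta,
    PlateLayout,
    load_channel_set,
)
from .segmentation import SegmentationParams
from .simulate import SimConfig, fourpl_curve, generate_assay_image
from .viability import compute_counts, count_dead_cells, default_dead_params

__all__ = ["AnalysisConfig", "RunManifest", "discover_images", "run_plate", "simulate_plate"]

PER_IMAGE_COLUMNS = [
    "well", "cut", "treatment", "concentration", "is_vehicle_control",
    "tracer_area_um2", "loaded_area_um2", "net_transfer_area_um2",
    "total_cells", "dead_cells", "viable_cells", "pct_dead",
    "exclusion_zone_area_um2", "qc_flags",
]

ENDPOINT_COLUMNS = {
    "GJIC": "net_transfer_area_um2",
    "density": "total_cells",
    "viability": "viable_cells",
}


@dataclass
class AnalysisConfig:
    """Run-wide analysis settings (loadable from YAML)."""

    pixel_size_um: float | None = None  # None -> take from layout
    filename_pattern: str = DEFAULT_FILENAME_PATTERN
    tracer: SegmentationParams = field(default_factory=default_tracer_params)
    red: SegmentationParams = field(default_factory=default_red_params)
    nuclear: SegmentationParams = field(default_factory=default_nuclear_params)
    cut: CutParams = field(default_factory=CutParams)
    margin_um: float = DEFAULT_MARGIN_UM
    min_seed_separation_px: int = 5
    alpha: float = 0.05
    anchor_top: float | None = None
    experiment_id: str = "exp1"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kw = {}
        for key in (
            "pixel_size_um", "filename_pattern", "margin_um", "min_seed_separation_px",
            "alpha", "anchor_top", "experiment_id", "seed",
        ):
            if key in doc:
                kw[key] = doc[key]
        for chan in ("tracer", "red", "nuclear"):
            if chan in doc:
                kw[chan] = SegmentationParams(**doc[chan])
        if "cut" in doc:
            kw["cut"] = CutParams(**doc["cut"])
        return cls(**kw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Discovered inputs for one plate run."""

    input_dir: str
    triples: list  # (well, cut, {"tracer": path, "red": path, "nuclear": path})
    skipped: list  # human-readable log entries for incomplete/unmatched files

    @property
    def n_complete(self) -> int:
        return len(self.triples)


def discover_images(input_dir, pattern: str = DEFAULT_FILENAME_PATTERN) -> RunManifest:
    """Group TIFFs into complete (well, cut) channel triples.

    Files that do not match the naming pattern, and (well, cut) groups
    missing a channel, are logged in ``skipped`` — never silently dropped.
    """
    input_dir = Path(input_dir)
    rx = re.compile(pattern)
    groups: dict = {}
    skipped: list[str] = []
    for path in sorted(input_dir.glob("*.tif*")):
        m = rx.search(path.name)
        if not m:
            skipped.append(f"unmatched filename: {path.name}")
            continue
        role = CHANNEL_CODES.get(m.group("channel"), m.group("channel"))
        groups.setdefault((m.group("well"), int(m.group("cut"))), {})[role] = str(path)
    triples, complete_roles = [], {"tracer", "red", "nuclear"}
    for (well, cut), chans in sorted(groups.items()):
        if set(chans) >= complete_roles:
            triples.append((well, cut, chans))
        else:
            missing = sorted(complete_roles - set(chans))
            skipped.append(f"incomplete triple {well} cut {cut}: missing {', '.join(missing)}")
    return RunManifest(str(input_dir), triples, skipped)


def _analyze_one(cs: ChannelSet, config: AnalysisConfig) -> dict:
    cut_res = analyze_cut(cs, config.tracer, config.red, config.cut)
    band = build_cut_region(cs.red, config.red, cs.calibration, config.cut)
    zone = build_exclusion_zone(band, config.margin_um)
    total = count_total_cells(cs, zone, config.nuclear, config.min_seed_separation_px)
    dead = count_dead_cells(cs, zone, config.red, config.min_seed_separation_px)
    counts = compute_counts(total.count, dead.count)
    flags = sorted(cut_res.qc_flags | total.qc_flags | dead.qc_flags | counts.qc_flags)
    return {
        "well": cs.meta.well,
        "cut": cs.meta.cut_index,
        "treatment": cs.meta.treatment,
        "concentration": cs.meta.concentration,
        "is_vehicle_control": cs.meta.is_vehicle_control,
        "tracer_area_um2": cut_res.tracer_area_um2,
        "loaded_area_um2": cut_res.loaded_area_um2,
        "net_transfer_area_um2": cut_res.net_transfer_area_um2,
        "total_cells": counts.total,
        "dead_cells": counts.dead,
        "viable_cells": counts.viable,
        "pct_dead": counts.pct_dead,
        "exclusion_zone_area_um2": zone.area_um2,
        "qc_flags": ";".join(flags),
    }


def analyze_channel_sets(channel_sets, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Run all three analyzers over in-memory channel sets."""
    config = config or AnalysisConfig()
    rows = [_analyze_one(cs, config) for cs in channel_sets]
    return pd.DataFrame(rows, columns=PER_IMAGE_COLUMNS)


def _foc_tables(per_well: pd.DataFrame, config: AnalysisConfig):
    controls = per_well[per_well["is_vehicle_control"]]
    if controls.empty:
        raise ValueError("no vehicle-control wells; FOC normalization impossible")
    records = []
    for endpoint, col in ENDPOINT_COLUMNS.items():
        recs = compute_foc(
            per_well[col].to_numpy(),
            controls[col].to_numpy(),
            endpoint=endpoint,
            experiment_id=config.experiment_id,
            concentrations=per_well["concentration"].to_numpy(),
        )
        for rec, well in zip(recs, per_well["well"]):
            records.append(
                {
                    "experiment": rec.experiment_id, "well": well, "endpoint": endpoint,
                    "concentration": rec.concentration, "raw": rec.raw,
                    "control_mean": rec.control_mean, "foc": rec.foc,
                }
            )
    return pd.DataFrame(records)


def _group_stats(foc: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(config.seed)
    for endpoint, sub in foc.groupby("endpoint"):
        groups = {
            conc: g["foc"].to_numpy() for conc, g in sub.groupby("concentration")
        }
        if len(groups) < 2 or min(len(v) for v in groups.values()) < 1:
            continue
        try:
            cmp_res = compare_groups(groups, alpha=config.alpha, rng=rng)
        except ValueError:
            continue
        for conc, p in sorted(cmp_res.p_values.items()):
            rows.append(
                {
                    "endpoint": endpoint, "concentration": conc, "p_value": p,
                    "test": cmp_res.test_used, "overall_p": cmp_res.overall_p,
                    "variance_p": cmp_res.variance_p, "alpha": cmp_res.alpha,
                    "significant": p <= cmp_res.alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["endpoint", "concentration", "p_value", "test", "overall_p",
                 "variance_p", "alpha", "significant"],
    )


def _ec50_table(foc: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for endpoint, sub in foc.groupby("endpoint"):
        treated = sub[sub["concentration"] > 0]
        if treated["concentration"].nunique() < 4:
            continue
        fits = []
        for exp, g in treated.groupby("experiment"):
            try:
                fit = fit_4pl(
                    g["concentration"], g["foc"],
                    experiment_id=str(exp), anchor_top=config.anchor_top,
                )
            except ValueError:
                continue
            fits.append(fit)
            rows.append(
                {
                    "endpoint": endpoint, "experiment": exp, "level": "experiment",
                    "ec50": fit.ec50, "hill": fit.hill, "bottom": fit.bottom,
                    "top": fit.top, "converged": fit.converged,
                    "ci_low": float("nan"), "ci_high": float("nan"), "n": fit.nobs,
                }
            )
        conv = [f for f in fits if f.converged]
        if conv:
            summ = summarize_ec50(conv)
            rows.append(
                {
                    "endpoint": endpoint, "experiment": "all", "level": "geomean",
                    "ec50": summ.geomean_ec50, "hill": float("nan"),
                    "bottom": float("nan"), "top": float("nan"), "converged": True,
                    "ci_low": summ.ci_low, "ci_high": summ.ci_high,
                    "n": summ.n_experiments,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["endpoint", "experiment", "level", "ec50", "hill", "bottom", "top",
                 "converged", "ci_low", "ci_high", "n"],
    )


def run_plate(
    manifest: RunManifest,
    layout: PlateLayout,
    config: AnalysisConfig | None = None,
    out_dir=None,
) -> dict:
    """Analyze every complete triple of a plate and write the report set.

    Returns a dict of DataFrames (``per_image``, ``per_well``, ``foc``,
    ``group_stats``, ``ec50``) plus the run log. When ``out_dir`` is given,
    CSVs and ``run_log.json`` are written there with a fixed column order.
    Missing vehicle controls abort only the FOC-dependent stages; raw
    measurements are always produced.
    """
    config = config or AnalysisConfig()
    pixel_size = config.pixel_size_um or layout.pixel_size_um

    rows = []
    for well, cut, chans in manifest.triples:
        info = layout.wells.get(well)
        meta = ImageMeta(
            well=well,
            cut_index=cut,
            treatment=info.treatment if info else "",
            concentration=info.concentration if info else 0.0,
            concentration_unit=info.concentration_unit if info else "",
            is_vehicle_control=info.is_vehicle_control if info else False,
        )
        cs = load_channel_set(
            chans["tracer"], chans["red"], chans["nuclear"],
            pixel_size_um=pixel_size, meta=meta,
        )
        rows.append(_analyze_one(cs, config))
    per_image = pd.DataFrame(rows, columns=PER_IMAGE_COLUMNS)
    per_image = per_image.sort_values(["well", "cut"], kind="stable").reset_index(drop=True)

    agg = {c: "mean" for c in PER_IMAGE_COLUMNS[5:-1]}
    agg.update({"treatment": "first", "concentration": "first", "is_vehicle_control": "first"})
    if per_image.empty:
        per_well = per_image.drop(columns=["cut", "qc_flags"])
    else:
        per_well = (
            per_image.groupby("well", as_index=False).agg(agg)
            [["well"] + PER_IMAGE_COLUMNS[2:-1]]
        )

    foc = pd.DataFrame()
    group_stats = pd.DataFrame()
    ec50 = pd.DataFrame()
    foc_error = ""
    if not per_well.empty:
        try:
            foc = _foc_tables(per_well, config)
        except ValueError as exc:
            foc_error = str(exc)
    if not foc.empty:
        group_stats = _group_stats(foc, config)
        ec50 = _ec50_table(foc, config)

    qc_tally: dict = {}
    for flag_str in per_image["qc_flags"]:
        for flag in filter(None, str(flag_str).split(";")):
            qc_tally[flag] = qc_tally.get(flag, 0) + 1
    run_log = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_triples": manifest.n_complete,
        "n_skipped": len(manifest.skipped),
        "skipped": manifest.skipped,
        "qc_flag_tally": dict(sorted(qc_tally.items())),
        "foc_error": foc_error,
    }

    result = {
        "per_image": per_image, "per_well": per_well, "foc": foc,
        "group_stats": group_stats, "ec50": ec50, "run_log": run_log,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_image.to_csv(out_dir / "per_image.csv", index=False, float_format="%.6g")
        per_well.to_csv(out_dir / "per_well.csv", index=False, float_format="%.6g")
        foc.to_csv(out_dir / "foc_table.csv", index=False, float_format="%.6g")
        group_stats.to_csv(out_dir / "group_stats.csv", index=False, float_format="%.6g")
        ec50.to_csv(out_dir / "ec50_summary.csv", index=False, float_format="%.6g")
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
    return result


def simulate_plate(
    layout: PlateLayout,
    sim_config: SimConfig,
    out_dir,
    fourpl: tuple[float, float, float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a simulated plate: TIFFs per the naming convention + truth CSV.

    Each well's coupling is constant (``sim_config.coupling``) unless a
    generating 4PL ``(bottom, top, ec50, hill)`` is supplied, in which case
    ``g = fourpl(concentration)`` per well (controls at ``g = top``).
    """
    from dataclasses import replace

    from .simulate import _derived_seed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    counter = 0
    for well in sorted(layout.wells):
        info = layout.wells[well]
        if fourpl is not None:
            bottom, top, ec50, hill = fourpl
            g = top if info.is_vehicle_control else float(
                fourpl_curve(info.concentration, bottom, top, ec50, hill)
            )
        else:
            g = sim_config.coupling
        for cut in range(1, layout.cuts_per_unit + 1):
            cfg = replace(sim_config, coupling=g, seed=_derived_seed(seed, counter))
            counter += 1
            meta = ImageMeta(
                well=well, cut_index=cut, treatment=info.treatment,
                concentration=info.concentration,
                concentration_unit=info.concentration_unit,
                is_vehicle_control=info.is_vehicle_control,
            )
            cs, truth = generate_assay_image(cfg, meta)
            for code, role in CHANNEL_CODES.items():
                tifffile.imwrite(out_dir / f"{well}_{cut}_{code}.tif", getattr(cs, role))
            truth_rows.append(
                {
                    "well": well, "cut": cut, "concentration": info.concentration,
                    "is_vehicle_control": info.is_vehicle_control, "true_g": truth.true_g,
                    "true_transfer_area_um2": truth.true_transfer_area_um2,
                    "true_loaded_area_um2": truth.true_loaded_area_um2,
                    "true_total_cells": truth.true_total_cells,
                    "true_dead_cells": truth.true_dead_cells,
                }
            )
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.6g")
    layout_for_disk = PlateLayout(
        format=layout.format, cuts_per_unit=layout.cuts_per_unit,
        channels=layout.channels, wells=layout.wells,
        pixel_size_um=sim_config.pixel_size_um,
    )
    layout_for_disk.to_yaml(out_dir / "layout.yaml")
    return truth_df
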