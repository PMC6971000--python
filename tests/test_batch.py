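"""Plate-level orchestration: discovery, analysis, reports, CLI."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from sldt import (
    AnalysisConfig,
    PlateLayout,
    SimConfig,
    WellInfo,
    discover_images,
    expected_image_count,
    run_plate,
    simulate_plate,
)
from sldt.cli import main


def small_layout(n_treated=3) -> PlateLayout:
    wells = {"A1": WellInfo("vehicle", 0.0, "nM", True), "A2": WellInfo("vehicle", 0.0, "nM", True)}
    for i, c in enumerate((0.5, 2.0, 8.0, 32.0)[:n_treated]):
        wells[f"B{i + 1}"] = WellInfo("TPA", c, "nM", False)
    return PlateLayout(format="plate48", wells=wells, pixel_size_um=1.0)


def small_sim() -> SimConfig:
    return SimConfig(
        image_height_px=275, image_width_px=350, pixel_size_um=1.0,
        max_transfer_halfwidth_um=60.0, dead_fraction=0.05,
    )


def small_config() -> AnalysisConfig:
    # tight margin so the small field keeps countable cells outside the zone
    return AnalysisConfig(margin_um=40.0)


@pytest.fixture(scope="module")
def plate_dir(tmp_path_factory):
    td = tmp_path_factory.mktemp("plate")
    layout = small_layout()
    simulate_plate(layout, small_sim(), td, fourpl=(0.0, 1.0, 2.0, 1.5), seed=3)
    return td, layout


class TestDiscovery:
    def test_all_triples_found(self, plate_dir):
        td, layout = plate_dir
        man = discover_images(td)
        assert man.n_complete == len(layout.wells) * layout.cuts_per_unit
        assert len(list(Path(td).glob("*.tif"))) == expected_image_count(layout)
        assert man.skipped == []

    def test_incomplete_triple_logged_not_silent(self, plate_dir, tmp_path):
        td, _ = plate_dir
        import shutil

        for f in Path(td).glob("*.tif"):
            shutil.copy(f, tmp_path / f.name)
        (tmp_path / "A1_1_HB.tif").unlink()
        (tmp_path / "stray.txt").write_text("x")
        man = discover_images(tmp_path)
        assert any("A1 cut 1" in s and "nuclear" in s for s in man.skipped)
        full = discover_images(td)
        assert man.n_complete == full.n_complete - 1


class TestRunPlate:
    def test_row_counts_and_reports(self, plate_dir, tmp_path):
        td, layout = plate_dir
        man = discover_images(td)
        res = run_plate(man, layout, small_config(), out_dir=tmp_path)
        assert len(res["per_image"]) == man.n_complete
        assert len(res["per_well"]) == len(layout.wells)
        # controls normalize to FOC mean 1.0 per endpoint
        foc = res["foc"]
        ctrl = foc[foc["concentration"] == 0.0]
        for _, grp in ctrl.groupby("endpoint"):
            assert grp["foc"].mean() == pytest.approx(1.0, abs=1e-9)
        for name in ("per_image.csv", "per_well.csv", "foc_table.csv",
                     "group_stats.csv", "ec50_summary.csv", "run_log.json"):
            assert (tmp_path / name).exists()

    def test_rerun_is_bit_identical(self, plate_dir, tmp_path):
        td, layout = plate_dir
        man = discover_images(td)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_plate(man, layout, small_config(), out_dir=out1)
        run_plate(man, layout, small_config(), out_dir=out2)
        for name in ("per_image.csv", "per_well.csv", "foc_table.csv", "ec50_summary.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_no_controls_keeps_raw_results(self, plate_dir, tmp_path):
        td, layout = plate_dir
        wells = {w: WellInfo("TPA", 1.0, "nM", False) for w in layout.wells}
        nocontrol = PlateLayout(format="plate48", wells=wells, pixel_size_um=1.0)
        man = discover_images(td)
        res = run_plate(man, nocontrol, small_config(), out_dir=tmp_path)
        assert len(res["per_image"]) == man.n_complete
        assert res["foc"].empty
        assert "control" in res["run_log"]["foc_error"]


class TestCLI:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        layout = small_layout(n_treated=1)
        layout_path = tmp_path / "layout.yaml"
        layout.to_yaml(layout_path)
        sim_yaml = tmp_path / "sim.yaml"
        sim_yaml.write_text(
            "image_height_px: 275\nimage_width_px: 350\npixel_size_um: 1.0\n"
            "max_transfer_halfwidth_um: 60.0\n"
        )
        img_dir = tmp_path / "imgs"
        r = runner.invoke(
            main,
            ["simulate", "--layout", str(layout_path), "--sim-config", str(sim_yaml),
             "--out", str(img_dir), "--seed", "2"],
        )
        assert r.exit_code == 0, r.output
        assert (img_dir / "ground_truth.csv").exists()
        out_dir = tmp_path / "out"
        r = runner.invoke(
            main,
            ["analyze", "--images", str(img_dir), "--layout", str(layout_path),
             "--out", str(out_dir)],
        )
        assert r.exit_code == 0, r.output
        per_image = pd.read_csv(out_dir / "per_image.csv")
        assert len(per_image) == len(layout.wells) * layout.cuts_per_unit

    def test_analyze_partial_exit_code(self, tmp_path):
        runner = CliRunner()
        layout = small_layout(n_treated=1)
        layout_path = tmp_path / "layout.yaml"
        layout.to_yaml(layout_path)
        img_dir = tmp_path / "imgs"
        simulate_plate(layout, small_sim(), img_dir, seed=1)
        next(img_dir.glob("*_PI.tif")).unlink()  # break one triple
        r = runner.invoke(
            main,
            ["analyze", "--images", str(img_dir), "--layout", str(layout_path),
             "--out", str(tmp_path / "out")],
        )
        assert r.exit_code == 3
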