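"""Cell counting outside the cut: density, dead cells and derived counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sldt import (
    BinaryMask,
    ExclusionZone,
    build_cut_region,
    build_exclusion_zone,
    compute_counts,
    count_dead_cells,
    count_total_cells,
    generate_assay_image,
)
from sldt.density import ZONE_COVERS_FOV
from sldt.segmentation import BLANK_CHANNEL, SegmentationParams, label_nuclei
from sldt.viability import DEAD_EXCEEDS_TOTAL, PCT_DEAD_UNDEFINED

from conftest import make_config


def truth_zone(gt):
    return ExclusionZone(gt.exclusion_zone_mask)


class TestCountTotalCells:
    def test_exact_on_nontouching_noiseless(self, noiseless_image):
        cs, gt = noiseless_image
        res = count_total_cells(cs, truth_zone(gt))
        assert res.count == gt.true_total_cells

    def test_detected_zone_matches_truth_zone(self, noisy_image):
        cs, gt = noisy_image
        band = build_cut_region(cs.red, calibration=cs.calibration)
        zone = build_exclusion_zone(band)
        res = count_total_cells(cs, zone)
        assert res.count == pytest.approx(gt.true_total_cells, rel=0.05)

    def test_moderate_overlap_within_five_percent(self):
        cs, gt = generate_assay_image(make_config(jitter_fraction=0.7, noise_sd=0.0, seed=5))
        res = count_total_cells(cs, truth_zone(gt))
        assert res.count == pytest.approx(gt.true_total_cells, rel=0.05)

    def test_zone_covering_fov_counts_zero_with_flag(self, noiseless_image):
        cs, _ = noiseless_image
        full = ExclusionZone(BinaryMask(np.ones(cs.shape, bool), cs.calibration))
        res = count_total_cells(cs, full)
        assert res.count == 0
        assert ZONE_COVERS_FOV in res.qc_flags

    def test_empty_nuclear_channel_flags_blank(self, noiseless_image):
        cs, gt = noiseless_image
        blank = type(cs)(
            tracer=cs.tracer, red=cs.red, nuclear=np.zeros_like(cs.nuclear),
            calibration=cs.calibration, meta=cs.meta,
        )
        res = count_total_cells(blank, truth_zone(gt))
        assert res.count == 0
        assert BLANK_CHANNEL in res.qc_flags

    def test_empty_zone_equals_total_label_count(self, noiseless_image):
        cs, _ = noiseless_image
        labeled = label_nuclei(cs.nuclear, SegmentationParams(min_area_um2=30.0), cs.calibration)
        empty = ExclusionZone(BinaryMask(np.zeros(cs.shape, bool), cs.calibration), 0.0)
        res = count_total_cells(cs, empty)
        assert res.count == labeled.n_objects

    def test_count_nonincreasing_in_margin(self, noiseless_image):
        cs, _ = noiseless_image
        band = build_cut_region(cs.red, calibration=cs.calibration)
        counts = [
            count_total_cells(cs, build_exclusion_zone(band, m)).count
            for m in (0.0, 50.0, 100.0, 150.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_doubled_density_tracks_truth(self):
        sparse = generate_assay_image(
            make_config(image_height_px=675, image_width_px=900, noise_sd=0.0, seed=4)
        )
        dense = generate_assay_image(
            make_config(
                image_height_px=675, image_width_px=900, noise_sd=0.0, seed=4,
                lattice_spacing_um=25.0 / np.sqrt(2.0),
            )
        )
        for cs, gt in (sparse, dense):
            res = count_total_cells(cs, truth_zone(gt))
            assert res.count == pytest.approx(gt.true_total_cells, rel=0.05)
        ratio = dense[1].true_total_cells / sparse[1].true_total_cells
        assert 1.7 <= ratio <= 2.3


class TestCountDeadCells:
    def test_recovers_dead_count(self, noiseless_image):
        cs, gt = noiseless_image
        res = count_dead_cells(cs, truth_zone(gt))
        assert res.count == gt.true_dead_cells

    def test_zero_dead_fraction_counts_zero(self):
        cs, gt = generate_assay_image(make_config(dead_fraction=0.0, noise_sd=0.0))
        assert count_dead_cells(cs, truth_zone(gt)).count == 0

    def test_loading_signal_inside_band_not_scored_as_death(self, noiseless_image):
        # all red signal in the cut band lies inside the zone by construction
        cs, gt = generate_assay_image(make_config(dead_fraction=0.0, noise_sd=0.0))
        band = build_cut_region(cs.red, calibration=cs.calibration)
        zone = build_exclusion_zone(band)
        assert count_dead_cells(cs, zone).count == 0


class TestComputeCounts:
    @pytest.mark.parametrize(
        "total,dead,viable,pct",
        [(200, 20, 180, 10.0), (150, 0, 150, 0.0), (1, 1, 0, 100.0)],
    )
    def test_arithmetic(self, total, dead, viable, pct):
        cc = compute_counts(total, dead)
        assert (cc.viable, cc.pct_dead) == (viable, pct)

    def test_dead_capped_at_total(self):
        cc = compute_counts(5, 7)
        assert (cc.dead, cc.viable) == (5, 0)
        assert DEAD_EXCEEDS_TOTAL in cc.qc_flags

    def test_zero_total_undefined_pct(self):
        cc = compute_counts(0, 0)
        assert np.isnan(cc.pct_dead)
        assert PCT_DEAD_UNDEFINED in cc.qc_flags

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_counts(-1, 0)

    @given(total=st.integers(0, 10_000), dead=st.integers(0, 12_000))
    @settings(deadline=None, max_examples=100)
    def test_identities_always_hold(self, total, dead):
        cc = compute_counts(total, dead)
        assert cc.viable + cc.dead == cc.total
        if cc.total > 0:
            assert 0.0 <= cc.pct_dead <= 100.0
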