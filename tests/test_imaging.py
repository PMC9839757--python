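"""Imaging pipeline: segmentation fidelity, background-corrected levels,
spatial ratios and confocal volume estimation."""

import numpy as np
import pytest

from nichemech import imaging, synth
from nichemech.errors import CalibrationError

from conftest import mask_iou, match_truth
from oracles import hemisphere_stack_volume


class TestSegmentation:
    def test_isolated_cells_recovered(self, uniform_scene):
        channels, truth = uniform_scene
        records = imaging.segment_cells(channels["bf"], channels["dapi"])
        assert len(records) == 3
        for rec in records:
            gt, _ = match_truth(rec, truth)
            assert mask_iou(rec.cell_mask, gt) >= 0.9
            assert (rec.nucleus_mask & ~rec.cell_mask).sum() == 0
            assert (rec.background_annulus & rec.cell_mask).sum() == 0

    def test_blank_image_yields_empty_list(self):
        blank = np.full((128, 128), 50.0)
        assert imaging.segment_cells(blank, blank) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            imaging.segment_cells(np.zeros((10, 10)), np.zeros((12, 10)))

    def test_touching_pair_excluded(self):
        """Two touching cells share one contour; the cluster is dropped."""
        spec = synth.SceneSpec(n_cells=4, seed=4, cluster_fraction=0.5)
        channels, truth = synth.gen_cell_scene(spec)
        records = imaging.segment_cells(channels["bf"], channels["dapi"])
        clustered_ids = set(truth.cells.loc[truth.cells.clustered, "cell_id"])
        for rec in records:
            _, label = match_truth(rec, truth)
            assert label not in clustered_ids

    def test_segmentation_fidelity_across_seeds(self):
        ious = []
        for seed in range(10):
            channels, truth = synth.gen_cell_scene(
                synth.SceneSpec(n_cells=3, seed=seed))
            for rec in imaging.segment_cells(channels["bf"], channels["dapi"]):
                gt, _ = match_truth(rec, truth)
                ious.append(mask_iou(rec.cell_mask, gt))
        assert np.mean(ious) >= 0.85


class TestLevels:
    def test_uniform_cell_level(self, uniform_scene):
        channels, truth = uniform_scene
        for rec in imaging.quantify_scene(channels):
            assert rec.levels["antigen"] == pytest.approx(100.0, rel=0.05)

    def test_zero_signal_channel(self, uniform_scene):
        channels, _ = uniform_scene
        records = imaging.segment_cells(channels["bf"], channels["dapi"])
        flat = np.full_like(channels["antigen"], 30.0)
        for rec in records:
            assert imaging.measure_level(rec, flat) == pytest.approx(0.0, abs=1e-9)

    def test_linear_background_ramp_subtracted(self):
        """The annulus mean approximates the local background under a ramp."""
        spec = synth.SceneSpec(n_cells=3, seed=5, channels={
            "antigen": synth.ChannelModel(background_ramp=(0.05, 0.08))})
        channels, truth = synth.gen_cell_scene(spec)
        for rec in imaging.quantify_scene(channels):
            assert rec.levels["antigen"] == pytest.approx(100.0, rel=0.05)

    def test_global_offset_invariance(self, uniform_scene):
        channels, _ = uniform_scene
        records = imaging.segment_cells(channels["bf"], channels["dapi"])
        chan = channels["antigen"]
        for rec in records[:1]:
            base = imaging.measure_level(rec, chan)
            shifted = imaging.measure_level(rec, chan + 500.0)
            assert shifted == pytest.approx(base, abs=1e-8)
            assert imaging.edge_center_ratio(rec, chan + 500.0) == pytest.approx(
                imaging.edge_center_ratio(rec, chan), abs=1e-8)
            assert imaging.nuc_cyt_ratio(rec, chan + 500.0) == pytest.approx(
                imaging.nuc_cyt_ratio(rec, chan), abs=1e-8)

    def test_intensity_scaling_linearity(self, uniform_scene):
        channels, _ = uniform_scene
        rec = imaging.segment_cells(channels["bf"], channels["dapi"])[0]
        chan = channels["antigen"]
        assert imaging.measure_level(rec, 2.5 * chan) == pytest.approx(
            2.5 * imaging.measure_level(rec, chan), rel=1e-9)
        assert imaging.edge_center_ratio(rec, 2.5 * chan) == pytest.approx(
            imaging.edge_center_ratio(rec, chan), rel=1e-9)


class TestCutoff:
    def test_all_zero_controls(self):
        assert imaging.calibrate_cutoff(np.zeros(50)).cutoff == 0.0

    def test_gaussian_controls_match_normal_quantile(self, rng):
        levels = rng.normal(50.0, 10.0, 10000)
        cut = imaging.calibrate_cutoff(levels).cutoff
        assert cut == pytest.approx(50 + 2.326 * 10, rel=0.02)

    def test_too_few_controls(self):
        with pytest.raises(CalibrationError):
            imaging.calibrate_cutoff([1.0] * 10)

    def test_positive_fraction_recovered(self):
        """30% positives at high separation: called fraction within 3 pp."""
        pos_levels, neg_levels = [], []
        for seed in range(8):
            spec = synth.SceneSpec(n_cells=5, seed=100 + seed, positive_fraction=0.4,
                                   channels={"antigen": synth.ChannelModel()})
            channels, truth = synth.gen_cell_scene(spec)
            for rec in imaging.quantify_scene(channels):
                gt, label = match_truth(rec, truth)
                row = truth.cells[truth.cells.cell_id == label].iloc[0]
                (pos_levels if row["positive_antigen"] else neg_levels).append(
                    rec.levels["antigen"])
        cut = imaging.calibrate_cutoff(neg_levels, min_controls=10)
        called = [lvl > cut.cutoff for lvl in pos_levels + neg_levels]
        true_frac = len(pos_levels) / len(called)
        assert np.mean(called) == pytest.approx(true_frac, abs=0.03)


class TestRatios:
    def test_uniform_cell_ratios_are_unity(self, uniform_scene):
        channels, _ = uniform_scene
        for rec in imaging.quantify_scene(channels):
            assert rec.edge_center["antigen"] == pytest.approx(1.0, abs=0.01)
            assert rec.nuc_cyt["antigen"] == pytest.approx(1.0, abs=0.01)

    def test_edge_enrichment_recovered(self, edge_scene):
        channels, _ = edge_scene
        ratios = [r.edge_center["pmlc"] for r in imaging.quantify_scene(channels)]
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_nuclear_enrichment_recovered(self, nuclear_scene):
        channels, _ = nuclear_scene
        for rec in imaging.quantify_scene(channels):
            assert rec.nuc_cyt["notch"] == pytest.approx(3.0, rel=0.05)


class TestStackVolume:
    def test_single_slice(self):
        assert imaging.volume_from_stack([100.0], 0.5) == 50.0

    def test_cylinder_exact(self):
        areas, vol = synth.gen_confocal_stack("cylinder", 5.0, 0.5, height=4.0)
        assert imaging.volume_from_stack(areas, 0.5) == pytest.approx(vol, rel=1e-12)

    def test_hemisphere_against_cap_area_oracle(self):
        areas, vol = synth.gen_confocal_stack("hemisphere", 8.7, 0.5)
        est = imaging.volume_from_stack(areas, 0.5)
        assert est == pytest.approx(hemisphere_stack_volume(8.7, 0.5), rel=1e-12)
        assert est == pytest.approx(vol, rel=0.02)

    @pytest.mark.parametrize("dz", [1.0, 0.5, 0.17])
    def test_error_shrinks_with_slice_spacing(self, dz):
        areas, vol = synth.gen_confocal_stack("hemisphere", 8.7, dz)
        err = abs(imaging.volume_from_stack(areas, dz) - vol) / vol
        assert err < 0.02 * dz / 0.5 + 1e-3

    def test_rasterized_stack_end_to_end(self):
        areas, vol, stack = synth.gen_confocal_stack(
            "hemisphere", 8.7, 0.5, rasterize=True, noise_sd=3.0, seed=2)
        est = imaging.volume_from_stack(imaging.areas_from_stack(stack, 0.21), 0.5)
        assert est == pytest.approx(vol, rel=0.03)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            imaging.volume_from_stack([1.0], 0.0)
        with pytest.raises(ValueError):
            imaging.volume_from_stack([-1.0], 0.5)
        assert imaging.volume_from_stack([], 0.5) == 0.0
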