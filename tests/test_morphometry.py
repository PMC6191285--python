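"""Segmentation fidelity, enrichment, classification, counting, tracking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from granulekit.errors import (
    AmbiguousProfileError,
    NoGranuleOnProfileError,
    ParameterError,
)
from granulekit.image import ImageStack
from granulekit.morphometry import (
    GranuleRecord,
    area_to_diameter,
    classify_granule,
    colocalization_fraction,
    count_associated_nuclei,
    disk_roi,
    fold_enrichment,
    nucleoplasmic_fraction,
    profile_size,
    records_to_mask,
    segment_granules,
    track_and_detect_fusion,
)
from granulekit.simulate import (
    GranuleTruth,
    SimulationConfig,
    place_granules,
    simulate_counting_stack,
    simulate_granule_image,
)


# ---------------------------------------------------------------------------
# area <-> diameter
# ---------------------------------------------------------------------------
class TestAreaToDiameter:
    @pytest.mark.parametrize("area,expected", [(91797.0, 606.0), (44533.0, 422.1)])
    def test_published_pairs_reproduced(self, area, expected):
        """d = 2 sqrt(A) reproduces both printed (area, diameter) pairs at 1 d.p."""
        assert round(area_to_diameter(area, "paper"), 1) == expected

    def test_circular_convention_unit_circle(self):
        assert area_to_diameter(math.pi, "circular") == pytest.approx(2.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ParameterError):
            area_to_diameter(-1.0)

    @settings(derandomize=True, max_examples=25)
    @given(area=st.floats(min_value=0.0, max_value=1e8))
    def test_conventions_differ_by_sqrt_pi(self, area):
        d_paper = area_to_diameter(area, "paper")
        d_circ = area_to_diameter(area, "circular")
        assert d_paper == pytest.approx(d_circ * math.sqrt(math.pi), abs=1e-9)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------
class TestSegmentation:
    def test_recovers_granule_count_and_centroids(self, blurred_config):
        truths = place_granules(blurred_config, 23, radius_nm=400,
                                enrichment=15.0, shape=(512, 512),
                                min_separation_px=40.0)
        stack, truths = simulate_granule_image(blurred_config, truths,
                                               background_level=100.0)
        records = segment_granules(stack, threshold_k=3.0, min_area_nm2=3e4)
        assert len(records) == 23
        truth_xy = np.array([t.centroid for t in truths])
        rec_xy = np.array([(r.centroid[1], r.centroid[2]) for r in records])
        dist, _ = cKDTree(truth_xy).query(rec_xy)
        assert dist.max() < 0.5

    def test_uniform_image_yields_no_granules(self):
        stack = ImageStack(np.full((1, 1, 1, 64, 64), 7.0))
        assert segment_granules(stack) == []

    def test_nonfinite_pixels_rejected(self):
        data = np.ones((1, 1, 1, 32, 32))
        data[0, 0, 0, 3, 3] = np.nan
        with pytest.raises(ParameterError):
            segment_granules(ImageStack(data))

    def test_total_intensity_within_one_percent(self, blurred_config):
        # oracle: the generator's rendered excess photons for a lone granule
        truth = GranuleTruth((64, 64), radius_nm=600, enrichment=12.0)
        stack, _ = simulate_granule_image(blurred_config, [truth],
                                          background_level=100.0, shape=(128, 128))
        rendered_excess = float(stack.plane().sum()) - 100.0 * 128 * 128
        records = segment_granules(stack, threshold_k=3.0, measure_dilation_px=4)
        assert len(records) == 1
        rec = records[0]
        # measured total minus the background underneath the dilated footprint
        big = np.zeros((128, 128), bool)
        y0, x0, y1, x1 = rec.bbox
        big[y0:y1, x0:x1] = rec.footprint
        from scipy import ndimage
        n_dil = int(ndimage.binary_dilation(big, iterations=4).sum())
        measured_excess = rec.total_intensity - 100.0 * n_dil
        assert measured_excess == pytest.approx(rendered_excess, rel=0.01)

    def test_min_area_filters_small_components(self, clean_config):
        truths = [GranuleTruth((20, 20), radius_nm=150, enrichment=10.0),
                  GranuleTruth((44, 44), radius_nm=600, enrichment=10.0)]
        stack, _ = simulate_granule_image(clean_config, truths,
                                          background_level=100.0, shape=(64, 64))
        records = segment_granules(stack, threshold_k=3.0, min_area_nm2=3e5)
        assert len(records) == 1
        assert records[0].centroid[1] == pytest.approx(44, abs=1)


# ---------------------------------------------------------------------------
# line profiles
# ---------------------------------------------------------------------------
class TestProfileSize:
    def test_top_hat_width_in_nm(self):
        plane = np.full((50, 50), 10.0)
        plane[25, 20:30] = 100.0
        res = profile_size(plane, (25, 5), (25, 45), pixel_size_nm=100.0,
                           background=(10.0, 1.0))
        assert res.size_nm == 1000.0
        assert res.total_intensity == pytest.approx(1000.0)

    def test_all_background_profile_is_an_error(self):
        plane = np.full((20, 20), 5.0)
        with pytest.raises(NoGranuleOnProfileError):
            profile_size(plane, (10, 0), (10, 19), pixel_size_nm=100.0,
                         background=(5.0, 0.5))

    def test_two_granules_ambiguous_unless_largest_kept(self):
        plane = np.full((30, 60), 10.0)
        plane[15, 10:16] = 100.0
        plane[15, 40:52] = 100.0
        kwargs = dict(pixel_size_nm=100.0, background=(10.0, 1.0))
        with pytest.raises(AmbiguousProfileError):
            profile_size(plane, (15, 0), (15, 59), **kwargs)
        res = profile_size(plane, (15, 0), (15, 59), largest_run=True, **kwargs)
        assert res.size_nm == 1200.0

    def test_blurred_granule_size_within_one_psf_sigma(self, blurred_config):
        # half-max threshold crossing of the blurred edge sits at the true edge
        truth = GranuleTruth((64, 64), radius_nm=1000, enrichment=2.0)
        stack, _ = simulate_granule_image(blurred_config, [truth],
                                          background_level=200.0, shape=(128, 128))
        # k = 2 with sd = excess/4 puts the threshold at half of the excess
        res = profile_size(stack.plane(), (64, 34), (64, 94),
                           pixel_size_nm=100.0, background=(200.0, 50.0))
        sigma_nm = blurred_config.psf_sigma_px * 100.0
        assert abs(res.size_nm - 2000.0) <= sigma_nm


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------
class TestFoldEnrichment:
    def test_noiseless_ratio_is_exact(self, clean_config):
        truths = place_granules(clean_config, 5, radius_nm=400,
                                enrichment=21.0, shape=(256, 256))
        stack, _ = simulate_granule_image(clean_config, truths,
                                          background_level=100.0, shape=(256, 256))
        records = segment_granules(stack, threshold_k=3.0)
        occupied = records_to_mask(records, (256, 256))
        rng = np.random.default_rng(1)
        rois = []
        while len(rois) < 3:
            cy, cx = rng.uniform(6, 249, 2)
            roi = disk_roi((256, 256), (cy, cx), 5)
            if not (roi & occupied).any():
                rois.append(roi)
        res = fold_enrichment(stack, records, rois)
        assert res.fold_enrichment == pytest.approx(21.0)

    def test_identity_when_rois_coincide(self, clean_config):
        truths = [GranuleTruth((32, 32), radius_nm=400, enrichment=5.0)]
        stack, _ = simulate_granule_image(clean_config, truths,
                                          background_level=100.0, shape=(64, 64))
        roi = disk_roi((64, 64), (10, 10), 4)
        res = fold_enrichment(stack, [roi], [roi])
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_scaling_invariance(self, clean_config):
        truths = [GranuleTruth((32, 32), radius_nm=400, enrichment=8.0)]
        stack, _ = simulate_granule_image(clean_config, truths,
                                          background_level=100.0, shape=(64, 64))
        records = segment_granules(stack, threshold_k=3.0)
        roi = [disk_roi((64, 64), (10, 10), 4)]
        res1 = fold_enrichment(stack, records, roi)
        stack.data = stack.data * 3.7
        res2 = fold_enrichment(stack, records, roi)
        assert res2.fold_enrichment == pytest.approx(res1.fold_enrichment)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_poisson_noise_recovery_within_ten_percent(self, seed):
        cfg = SimulationConfig(seed=seed)  # Poisson on, PSF on
        truths = place_granules(cfg, 18, radius_nm=500, enrichment=25.0,
                                shape=(512, 512))
        stack, _ = simulate_granule_image(cfg, truths, background_level=200.0)
        records = segment_granules(stack, threshold_k=3.0, min_area_nm2=5e4)
        occupied = records_to_mask(records, (512, 512))
        rng = np.random.default_rng(seed)
        rois = []
        while len(rois) < 20:
            cy, cx = rng.uniform(8, 503, 2)
            roi = disk_roi((512, 512), (cy, cx), 6)
            if not (roi & occupied).any():
                rois.append(roi)
        res = fold_enrichment(stack, records, rois, granule_measure="peak")
        assert res.fold_enrichment == pytest.approx(25.0, rel=0.10)

    def test_zero_reference_rejected(self, clean_config):
        stack = ImageStack(np.zeros((1, 1, 1, 32, 32)))
        roi = disk_roi((32, 32), (5, 5), 3)
        granule = disk_roi((32, 32), (20, 20), 3)
        with pytest.raises(ParameterError):
            fold_enrichment(stack, [granule], [roi])


# ---------------------------------------------------------------------------
# nucleoplasmic fraction
# ---------------------------------------------------------------------------
class TestNucleoplasmicFraction:
    def _nucleus_scene(self, diffuse, granule_excess):
        """Disk nucleus with uniform diffuse signal plus two granules."""
        shape = (96, 96)
        nucleus = disk_roi(shape, (48, 48), 40)
        plane = np.where(nucleus, diffuse, 0.0)
        g1 = disk_roi(shape, (36, 40), 6)
        g2 = disk_roi(shape, (60, 56), 6)
        plane[g1] += granule_excess
        plane[g2] += granule_excess
        stack = ImageStack(plane[None, None, None])
        return stack, nucleus, g1 | g2

    def test_all_signal_in_granules_gives_zero(self):
        stack, nucleus, gmask = self._nucleus_scene(0.0, 50.0)
        # diffuse level 0: everything measurable sits inside granules
        res = nucleoplasmic_fraction(stack, nucleus, gmask)
        assert res.nucleoplasmic_percent == pytest.approx(0.0)

    def test_no_granules_gives_hundred(self):
        stack, nucleus, _ = self._nucleus_scene(10.0, 0.0)
        res = nucleoplasmic_fraction(stack, nucleus, np.zeros((96, 96), bool))
        assert res.nucleoplasmic_percent == pytest.approx(100.0)

    def test_known_photon_budget_recovered(self):
        # construction oracle: diffuse photons outside granules / total photons
        diffuse, excess = 10.0, 90.0
        stack, nucleus, gmask = self._nucleus_scene(diffuse, excess)
        n_nuc = int(nucleus.sum())
        n_g = int(gmask.sum())
        expected = 100.0 * diffuse * (n_nuc - n_g) / (diffuse * n_nuc + excess * n_g)
        res = nucleoplasmic_fraction(stack, nucleus, gmask)
        assert res.nucleoplasmic_percent == pytest.approx(expected, abs=1e-9)

    def test_partition_sums_to_hundred_exactly(self):
        stack, nucleus, gmask = self._nucleus_scene(7.0, 33.0)
        res = nucleoplasmic_fraction(stack, nucleus, gmask)
        assert res.nucleoplasmic_percent + res.granular_percent == 100.0

    def test_empty_nucleus_rejected(self):
        stack = ImageStack(np.zeros((1, 1, 1, 32, 32)))
        with pytest.raises(ParameterError):
            nucleoplasmic_fraction(stack, np.ones((32, 32), bool),
                                   np.zeros((32, 32), bool))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------
class TestClassifyGranule:
    def _segment_single(self, truth, config, background=100.0, shape=(96, 96)):
        stack, _ = simulate_granule_image(config, [truth],
                                          background_level=background, shape=shape)
        records = segment_granules(stack, threshold_k=3.0)
        assert len(records) == 1
        return records[0], stack

    def test_shell_granule_is_hollow(self, clean_config):
        truth = GranuleTruth((48, 48), radius_nm=1500, enrichment=10.0,
                             shell_fraction=0.4, interior_level=0.2)
        rec, stack = self._segment_single(truth, clean_config)
        assert classify_granule(rec, stack) == "hollow"
        assert rec.hollow_dip_ratio < 0.7

    def test_small_solid_granule(self, clean_config):
        truth = GranuleTruth((48, 48), radius_nm=300, enrichment=10.0)
        rec, stack = self._segment_single(truth, clean_config)
        assert rec.equivalent_diameter_nm < 1200.0
        assert classify_granule(rec, stack) == "small"

    def test_big_solid_granule(self, clean_config):
        truth = GranuleTruth((48, 48), radius_nm=1250, enrichment=10.0)
        rec, stack = self._segment_single(truth, clean_config)
        assert rec.equivalent_diameter_nm > 1200.0
        assert classify_granule(rec, stack) == "big_nonhollow"

    def test_tiny_granule_unclassified(self, clean_config):
        rec = GranuleRecord(0, 0, (0.0, 10.0, 10.0), 1e4, 200.0, 100.0, 1.0)
        stack = ImageStack(np.ones((1, 1, 1, 32, 32)), pixel_size_nm=100.0)
        assert classify_granule(rec, stack) == "unclassified"

    def test_deterministic_relabeling(self, clean_config):
        truth = GranuleTruth((48, 48), radius_nm=1500, enrichment=10.0,
                             shell_fraction=0.4)
        rec, stack = self._segment_single(truth, clean_config)
        assert classify_granule(rec, stack) == classify_granule(rec, stack)


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------
class TestColocalization:
    def _records_at(self, centroids):
        return [GranuleRecord(i, 0, (0.0, y, x), 1e4, 200.0, 1.0, 1.0)
                for i, (y, x) in enumerate(centroids)]

    def test_identical_sets_fully_matched(self):
        recs = self._records_at([(10, 10), (20, 30), (40, 5)])
        assert colocalization_fraction(recs, recs, 300.0, 100.0) == 100.0

    def test_disjoint_sets_unmatched(self):
        a = self._records_at([(5, 5)])
        b = self._records_at([(50, 50)])
        assert colocalization_fraction(a, b, 300.0, 100.0) == 0.0

    def test_partial_coplacement_fraction(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(10, 240, size=(20, 2))
        ch1 = self._records_at(pts)
        # 19/20 granules co-placed (small jitter), one displaced far away
        jitter = pts + rng.normal(0, 0.5, size=pts.shape)
        jitter[-1] = (400.0, 400.0)
        ch2 = self._records_at(jitter)
        got = colocalization_fraction(ch1, ch2, 300.0, 100.0)
        assert got == pytest.approx(95.0)

    def test_symmetric_when_bijective(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(10, 100, size=(8, 2))
        a = self._records_at(pts)
        b = self._records_at(pts + 0.3)
        assert (colocalization_fraction(a, b, 500.0, 100.0)
                == colocalization_fraction(b, a, 500.0, 100.0))

    def test_empty_first_channel_rejected(self):
        with pytest.raises(ParameterError):
            colocalization_fraction([], self._records_at([(1, 1)]), 100.0, 100.0)


# ---------------------------------------------------------------------------
# 3-D counting
# ---------------------------------------------------------------------------
class TestCountAssociatedNuclei:
    @pytest.mark.parametrize("n_nuclei,n_assoc", [(10, 7), (5, 0)])
    def test_recovers_truth_counts(self, n_nuclei, n_assoc):
        cfg = SimulationConfig(seed=5)
        stack, truth = simulate_counting_stack(cfg, n_nuclei, n_assoc)
        assert count_associated_nuclei(stack) == truth[1]

    def test_empty_nuclei_channel_counts_zero(self):
        stack = ImageStack(np.zeros((1, 8, 2, 32, 32)))
        assert count_associated_nuclei(stack) == 0

    def test_ablation_scale_fields(self):
        # fields sized to the reported control/mutant means (36.9 vs 22.4)
        control, truth_c = simulate_counting_stack(
            SimulationConfig(seed=6), 36, 36, shape=(16, 256, 256))
        mutant, truth_m = simulate_counting_stack(
            SimulationConfig(seed=7), 22, 22, shape=(16, 256, 256))
        assert count_associated_nuclei(control) == 36
        assert count_associated_nuclei(mutant) == 22


# ---------------------------------------------------------------------------
# tracking and fusion
# ---------------------------------------------------------------------------
class TestTracking:
    def _rec(self, rid, y, x, intensity):
        return GranuleRecord(rid, 0, (0.0, float(y), float(x)), 1e4, 200.0,
                             float(intensity), 1.0)

    def test_converging_granules_fuse_with_intensity_sum(self):
        frames = [
            [self._rec(0, 10, 10, 100), self._rec(1, 10, 20, 150)],
            [self._rec(0, 10, 12, 100), self._rec(1, 10, 18, 150)],
            [self._rec(0, 10, 15, 250)],  # merged: 100 + 150
        ]
        tracks, events = track_and_detect_fusion(frames, 500.0, 100.0)
        assert len(events) == 1
        assert events[0].frame == 2

    def test_stationary_granules_never_fuse(self):
        frames = [[self._rec(0, 10, 10, 100), self._rec(1, 30, 30, 80)]] * 4
        tracks, events = track_and_detect_fusion(frames, 500.0, 100.0)
        assert events == []
        assert sorted(len(t.items) for t in tracks) == [4, 4]

    def test_intensity_mismatch_blocks_fusion_event(self, caplog):
        frames = [
            [self._rec(0, 10, 10, 100), self._rec(1, 10, 20, 150)],
            [self._rec(0, 10, 15, 500)],  # far from 250: not a clean merge
        ]
        import logging
        with caplog.at_level(logging.WARNING, logger="granulekit.morphometry"):
            _, events = track_and_detect_fusion(frames, 800.0, 100.0)
        assert events == []
        assert any("no fusion recorded" in r.message for r in caplog.records)

    def test_single_frame_rejected(self):
        with pytest.raises(ParameterError):
            track_and_detect_fusion([[self._rec(0, 1, 1, 10)]], 100.0, 100.0)
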