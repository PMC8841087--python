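import numpy as np
import pytest
from scipy import ndimage as ndi

from granulequant import SimulationParams, generate_neuron_stack
from granulequant import segmentation as seg

from oracles import flood_fill_label, labelings_equivalent, triangle_threshold_bruteforce


class TestMaxIntensityProjection:
    def test_single_slice_is_identity(self, rng):
        stack = rng.random((1, 8, 9))
        np.testing.assert_array_equal(seg.max_intensity_projection(stack), stack[0])

    def test_all_zero(self):
        assert not seg.max_intensity_projection(np.zeros((4, 5, 5))).any()

    def test_disjoint_bright_pixels_match_bruteforce(self, rng):
        stack = rng.random((2, 16, 16))
        proj = seg.max_intensity_projection(stack)
        for y in range(16):
            for x in range(16):
                assert proj[y, x] == max(stack[0, y, x], stack[1, y, x])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            seg.max_intensity_projection(np.zeros((5, 5)))


class TestTriangleThreshold:
    def test_two_level_separation(self, rng):
        img = np.zeros((50, 50))
        bright = rng.random((50, 50)) < 0.05
        img[bright] = 100.0
        t = seg.triangle_threshold(img)
        assert 0 < t < 100
        assert np.array_equal(img > t, bright)

    def test_constant_image_degenerate(self):
        with pytest.raises(seg.DegenerateHistogramError):
            seg.triangle_threshold(np.full((10, 10), 3.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_lognormal(self, seed):
        # unimodal histogram with a long right tail
        rng = np.random.default_rng(seed)
        values = rng.lognormal(mean=2.0, sigma=0.6, size=4000)
        assert seg.triangle_threshold(values) == pytest.approx(
            triangle_threshold_bruteforce(values), abs=1e-12
        )

    def test_matches_bruteforce_16_bins(self, rng):
        values = np.concatenate([rng.normal(10, 1, 500), rng.normal(30, 4, 100)])
        assert seg.triangle_threshold(values, n_bins=16) == pytest.approx(
            triangle_threshold_bruteforce(values, n_bins=16)
        )

    def test_oracle_equivalence_many_random_histograms(self):
        """Exhaustive-bin-search oracle agreement on 100 random unimodal samples."""
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            kind = seed % 3
            if kind == 0:
                values = rng.lognormal(rng.uniform(0, 2), rng.uniform(0.3, 1.0), 2000)
            elif kind == 1:
                values = rng.gamma(rng.uniform(1.5, 6), rng.uniform(1, 10), 2000)
            else:
                values = rng.normal(0, 1, 2000) ** 2
            assert seg.triangle_threshold(values) == pytest.approx(
                triangle_threshold_bruteforce(values), abs=1e-12
            )

    def test_agrees_with_skimage_on_images(self, rng):
        """Cross-check against an established implementation (same binning)."""
        from skimage.filters import threshold_triangle

        img = rng.lognormal(3.0, 0.7, size=(64, 64))
        ours = seg.triangle_threshold(img)
        theirs = threshold_triangle(img, nbins=256)
        bin_width = (img.max() - img.min()) / 256
        assert abs(ours - theirs) <= 2 * bin_width


class TestConnectedComponents:
    @pytest.mark.parametrize("seed", range(10))
    def test_2d_labeling_matches_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((24, 24)) < 0.35
        labels, n = ndi.label(mask, structure=seg.STRUCTURE_2D)
        oracle, n_oracle = flood_fill_label(mask)
        assert n == n_oracle
        assert labelings_equivalent(labels, oracle)


class TestSegmentNuclei:
    def test_small_objects_removed(self):
        """A 19-pixel object after thresholding is absent from the mask."""
        img = np.zeros((1, 64, 64))
        img[0, 2:21, 2] = 100.0          # 19-pixel line
        img[0, 30:50, 30:50] = 100.0     # 400-pixel square survives
        nuclei = seg.segment_nuclei(img)
        assert nuclei.n_objects == 1
        assert not nuclei.footprint[2:21, 2].any()

    def test_20_pixel_object_kept(self):
        img = np.zeros((1, 64, 64))
        img[0, 2:22, 2] = 100.0          # exactly 20 pixels: "smaller than 20" only
        nuclei = seg.segment_nuclei(img)
        assert nuclei.n_objects == 1

    def test_blank_stack_degenerate_not_crash(self):
        with pytest.raises(seg.DegenerateHistogramError):
            seg.segment_nuclei(np.zeros((3, 32, 32)))

    def test_labels_contiguous_from_one(self, default_stack):
        stack, truth, params = default_stack
        nuclei = seg.segment_nuclei(stack.channels["dapi"])
        labels = np.unique(nuclei.label_map)
        assert labels[0] == 0
        np.testing.assert_array_equal(labels[1:], np.arange(1, nuclei.n_objects + 1))

    def test_recovers_three_small_nuclei(self):
        """Three well-separated ellipsoids (150-400 px) each found with IoU >= 0.7."""
        params = SimulationParams(
            image_shape=(8, 128, 128),
            n_nuclei=3,
            nucleus_radius_um=(0.7, 1.1),
            nucleus_z_radius_um=(0.6, 0.9),
            n_neurites=0,
            seed=4,
        )
        stack, truth = generate_neuron_stack(params)
        areas = [
            (truth.nucleus_label_map == lab).sum()
            for lab in range(1, truth.nucleus_label_map.max() + 1)
        ]
        assert all(100 <= a <= 450 for a in areas)
        nuclei = seg.segment_nuclei(stack.channels["dapi"])
        assert nuclei.n_objects == 3
        dilated_truth = ndi.binary_dilation(
            truth.nucleus_label_map > 0, structure=seg.STRUCTURE_2D
        )
        for lab in range(1, 4):
            obj = nuclei.label_map == lab
            # best-matching ground-truth nucleus
            best = 0.0
            for tlab in range(1, truth.nucleus_label_map.max() + 1):
                tobj = ndi.binary_dilation(
                    truth.nucleus_label_map == tlab, structure=seg.STRUCTURE_2D
                )
                iou = (obj & tobj).sum() / (obj | tobj).sum()
                best = max(best, iou)
            assert best >= 0.7

    def test_idempotent_on_clean_mask(self):
        """Re-segmenting a segmentation's own binary output only re-applies
        the single dilation; object count and topology are unchanged."""
        img = np.zeros((1, 64, 64))
        img[0, 10:30, 10:30] = 100.0
        img[0, 40:55, 40:55] = 100.0
        first = seg.segment_nuclei(img)
        second = seg.segment_nuclei(first.footprint[np.newaxis].astype(float) * 100)
        assert second.n_objects == first.n_objects
        assert (first.footprint & ~second.footprint).sum() == 0


class TestForegroundAndCytosol:
    def test_29_pixel_object_removed(self):
        img = np.zeros((1, 64, 64))
        img[0, 2:31, 2] = 100.0          # 29-pixel line
        img[0, 30:50, 30:50] = 100.0
        fg = seg.extract_foreground(img, smoothing_sigma=0.0)
        assert not fg.mask[0, 2:31, 2].any()
        assert fg.mask[0, 35:45, 35:45].all()

    def test_all_zero_stack_empty_mask(self, caplog):
        fg = seg.extract_foreground(np.zeros((3, 32, 32)))
        assert not fg.mask.any()

    def test_foreground_covers_cytosol_support(self):
        """On a noiseless render of a diffuse-signal channel, the foreground
        recovers the cytosol+nucleus support."""
        params = SimulationParams.ncdn_scenario(
            image_shape=(10, 128, 128), n_nuclei=1, n_neurites=2,
            noise_gain=0.0, read_noise_sd=0.0, seed=0,
        )
        stack, truth = generate_neuron_stack(params)
        fg = seg.extract_foreground(stack.channels["target"])
        support = truth.cytosol_mask | np.broadcast_to(
            truth.nucleus_label_map[np.newaxis] > 0, truth.cytosol_mask.shape
        )
        iou = (fg.mask & support).sum() / (fg.mask | support).sum()
        assert iou >= 0.8

    def test_cytosol_equals_foreground_minus_nuclei(self):
        fg_mask = np.zeros((2, 10, 10), dtype=bool)
        fg_mask[:, 2:8, 2:8] = True
        nuc = np.zeros((10, 10), dtype=np.int32)
        nuc[4:6, 4:6] = 1
        fg = seg.ForegroundMask(mask=fg_mask)
        nuclei = seg.NucleiMask(label_map=nuc, n_objects=1)
        cyt = seg.cytosolic_mask(fg, nuclei)
        # hand count: 36 foreground pixels per slice minus 4 nucleus pixels
        assert cyt.mask.sum() == 2 * (36 - 4)
        assert not (cyt.mask & np.broadcast_to(nuc > 0, cyt.mask.shape)).any()

    def test_identical_masks_give_empty_cytosol(self):
        mask2d = np.zeros((10, 10), dtype=bool)
        mask2d[3:7, 3:7] = True
        fg = seg.ForegroundMask(mask=np.broadcast_to(mask2d, (3, 10, 10)).copy())
        nuclei = seg.NucleiMask(label_map=mask2d.astype(np.int32), n_objects=1)
        assert not seg.cytosolic_mask(fg, nuclei).mask.any()

    def test_disjoint_masks_keep_foreground(self):
        fg_mask = np.zeros((2, 10, 10), dtype=bool)
        fg_mask[:, :3] = True
        nuc = np.zeros((10, 10), dtype=np.int32)
        nuc[8:, 8:] = 1
        fg = seg.ForegroundMask(mask=fg_mask)
        cyt = seg.cytosolic_mask(fg, seg.NucleiMask(label_map=nuc, n_objects=1))
        np.testing.assert_array_equal(cyt.mask, fg_mask)

    def test_shape_mismatch_rejected(self):
        fg = seg.ForegroundMask(mask=np.ones((2, 8, 8), dtype=bool))
        nuclei = seg.NucleiMask(label_map=np.zeros((9, 9), dtype=np.int32), n_objects=0)
        with pytest.raises(ValueError):
            seg.cytosolic_mask(fg, nuclei)


class TestCytosolicIntensity:
    def test_constant_region(self):
        channel = np.full((2, 4, 4), 7.5)
        mask = seg.CytosolicMask(mask=np.ones((2, 4, 4), dtype=bool))
        assert seg.cytosolic_intensity(channel, mask) == 7.5

    def test_median_definition(self):
        channel = np.array([[[1.0, 2.0, 3.0, 4.0, 100.0]]])
        mask = seg.CytosolicMask(mask=np.ones((1, 1, 5), dtype=bool))
        assert seg.cytosolic_intensity(channel, mask) == 3.0

    def test_empty_mask_flagged(self):
        mask = seg.CytosolicMask(mask=np.zeros((1, 4, 4), dtype=bool))
        with pytest.raises(seg.EmptyMaskError):
            seg.cytosolic_intensity(np.ones((1, 4, 4)), mask)

    def test_cytosol_effect_recovery(self, kd_effects):
        """A 0.6x cytosol knockdown is read out as a ~0.6 median ratio."""
        import dataclasses

        from granulequant import ConditionEffect

        effects = {"CTL-KD": ConditionEffect(), "KD": ConditionEffect(cytosol=0.6)}
        ratios = []
        for seed in range(12):
            meds = {}
            for cond in effects:
                params = SimulationParams.ncdn_scenario(
                    seed=seed, condition_effects=effects,
                    image_shape=(10, 160, 160), n_nuclei=2,
                )
                stack, _ = generate_neuron_stack(
                    params, condition=cond, rng=np.random.default_rng([seed, len(cond)])
                )
                nuclei = seg.segment_nuclei(stack.channels["dapi"])
                fg = seg.extract_foreground(stack.channels["target"])
                cyt = seg.cytosolic_mask(fg, nuclei)
                meds[cond] = seg.cytosolic_intensity(stack.channels["target"], cyt)
            ratios.append(meds["KD"] / meds["CTL-KD"])
        assert np.mean(ratios) == pytest.approx(0.6, abs=0.05)
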