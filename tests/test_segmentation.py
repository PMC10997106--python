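"""Connected components, gap-rule cleaning and region p-values."""

import math

import numpy as np
import pytest

from emccd_pia import (
    NoiseModel,
    SceneSpec,
    SortedCounts,
    Annulus,
    build_distribution,
    clean_mask,
    draw_counts,
    fit_background,
    gap_size_threshold,
    label_components,
    random_bead_spec,
    render_scene,
    score_regions,
    threshold_from_pvalue,
    binarize,
)
from emccd_pia.segmentation import FLIP_ALL


class TestLabelComponents:
    def test_single_pixel_region(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        regions = label_components(mask, "white")
        assert len(regions) == 1
        assert regions[0].size == 1

    def test_diagonal_pixels_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, "white", connectivity=2)) == 1
        assert len(label_components(mask, "white", connectivity=1)) == 2

    def test_checkerboard_counts_match_enumeration(self):
        mask = np.indices((4, 4)).sum(axis=0) % 2 == 0
        # 8-connectivity joins all diagonal runs into one region
        assert len(label_components(mask, "white", connectivity=2)) == 1
        # 4-connectivity isolates every pixel
        assert len(label_components(mask, "white", connectivity=1)) == 8

    def test_complementary_default_connectivities(self):
        # white ring with one-pixel hole: 4-connected black keeps the
        # hole separate from the outside background
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        mask[2, 2] = False
        blacks = label_components(mask, "black")
        assert len(blacks) == 2

    def test_labels_row_major_deterministic(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[4, 1] = True
        mask[0, 5] = True
        mask[2, 2] = True
        regions = label_components(mask, "white")
        firsts = [tuple(r.coords[0]) for r in regions]
        assert firsts == [(0, 5), (2, 2), (4, 1)]
        assert [r.label for r in regions] == [1, 2, 3]


class TestGapSizeThreshold:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ([1, 2, 3, 10, 12], 3.0),
            ([2, 3, 4], FLIP_ALL),
            ([5, 100], 5.0),
            ([7], FLIP_ALL),
        ],
    )
    def test_stated_rule(self, sizes, expected):
        result = gap_size_threshold(sizes, allowed_gap_length=1)
        if math.isinf(expected):
            assert math.isinf(result)
        else:
            assert result == expected

    def test_gap_parameter_widens_noise_cluster(self):
        sizes = [1, 3, 5, 30]
        assert gap_size_threshold(sizes, allowed_gap_length=1) == 1.0
        assert gap_size_threshold(sizes, allowed_gap_length=2) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gap_size_threshold([])


class TestCleanMask:
    def test_isolated_pixels_flipped_blob_kept(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5:15, 5:10] = True  # 50-pixel blob
        for rc in ((25, 25), (28, 3), (2, 28)):
            mask[rc] = True
        result = clean_mask(mask)
        assert result.w_white == 1.0
        assert len(result.regions) == 1
        assert result.regions[0].size == 50

    def test_all_black_mask_unchanged(self):
        mask = np.zeros((16, 16), dtype=bool)
        result = clean_mask(mask)
        assert not result.mask.any()
        assert result.regions == ()

    def test_single_object_without_noise_cluster_is_dropped(self):
        # one white region means no size gap: with no noise cluster to
        # calibrate against, the rule keeps no objects at all
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:20, 10:20] = True
        result = clean_mask(mask)
        assert not result.mask.any()
        assert math.isinf(result.w_white)

    def test_black_specks_inside_object_filled(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5:25, 5:25] = True
        mask[10, 10] = False  # 1-px hole (noise)
        result = clean_mask(mask)
        assert result.mask[10, 10]

    def test_no_surviving_region_below_the_cut(self, chip):
        spec = random_bead_spec(
            (128, 128), lam_bg=20.0, snr=3.0, radius=4.0, signal_fraction=0.10, seed=81
        )
        image, _ = render_scene(spec, chip, seed=82)
        counts = SortedCounts.from_image(image)
        fit = fit_background(counts, chip)
        n, _ = threshold_from_pvalue(0.01, NoiseModel(chip=chip, lam=fit.lam_bg))
        result = clean_mask(binarize(image, n).white, image=image)
        assert result.regions
        assert all(r.size > result.w_white for r in result.regions)

    def test_scene_jaccard_after_cleaning(self, chip):
        spec = random_bead_spec(
            (256, 256), lam_bg=20.0, snr=3.0, radius=4.0, signal_fraction=0.15, seed=83
        )
        image, truth = render_scene(spec, chip, seed=84)
        counts = SortedCounts.from_image(image)
        fit = fit_background(counts, chip)
        n, _ = threshold_from_pvalue(0.01, NoiseModel(chip=chip, lam=fit.lam_bg))
        result = clean_mask(binarize(image, n).white, image=image)
        inter = (result.mask & truth.mask).sum()
        union = (result.mask | truth.mask).sum()
        assert inter / union >= 0.9


class TestScoreRegions:
    @staticmethod
    def _as_result(mask, image):
        from emccd_pia.segmentation import SegmentationResult

        return SegmentationResult(
            mask=mask,
            regions=tuple(label_components(mask, "white", image=image)),
            w_white=0.0,
            w_black=0.0,
            allowed_gap_length=1,
        )

    def test_single_pixel_region_reduces_to_tail(self, model22, chip):
        dist = build_distribution(model22)
        image = draw_counts(22.0, chip, n=64, seed=85).reshape(8, 8)
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        result = score_regions(self._as_result(mask, image), image, model22)
        single = result.regions[0]
        count = image[4, 4]
        assert single.p_seg == pytest.approx(1.0 - dist.cdf(count - 1), abs=1e-9)

    def test_background_carved_region_pvalues_uniformish(self, model22, chip):
        # a fixed 5x5 box carved out of pure background: p_seg should be
        # spread over (0,1), not clustered near 0
        pvals = []
        for seed in range(40):
            image = draw_counts(22.0, chip, n=1024, seed=900 + seed).reshape(32, 32)
            mask = np.zeros((32, 32), dtype=bool)
            mask[10:15, 10:15] = True
            result = score_regions(self._as_result(mask, image), image, model22)
            pvals.append(result.regions[0].p_seg)
        pvals = np.asarray(pvals)
        assert pvals.min() > 1e-4
        assert 0.25 < np.mean(pvals < 0.5) < 0.85

    def test_true_beads_score_below_alpha(self, chip):
        spec = random_bead_spec(
            (256, 256), lam_bg=20.0, snr=3.0, radius=4.0, signal_fraction=0.10, seed=86
        )
        image, _ = render_scene(spec, chip, seed=87)
        counts = SortedCounts.from_image(image)
        fit = fit_background(counts, chip)
        model = NoiseModel(chip=chip, lam=fit.lam_bg)
        n, _ = threshold_from_pvalue(0.01, model)
        result = clean_mask(binarize(image, n).white, image=image)
        result = score_regions(result, image, model)
        assert result.regions
        assert all(r.p_seg < 0.01 for r in result.regions)


def test_annulus_recovered_with_hole(chip):
    """No topology assumption: a ring object keeps its hole."""
    spec = SceneSpec(
        shape=(128, 128),
        objects=(Annulus(center=(64, 64), r_outer=24, r_inner=12),),
        lam_bg=20.0,
        snr=3.0,
    )
    image, truth = render_scene(spec, chip, seed=88)
    counts = SortedCounts.from_image(image)
    fit = fit_background(counts, chip)
    n, _ = threshold_from_pvalue(0.01, NoiseModel(chip=chip, lam=fit.lam_bg))
    result = clean_mask(binarize(image, n).white, image=image)
    # ring recovered ...
    ring = truth.mask
    assert (result.mask & ring).sum() / ring.sum() > 0.8
    # ... and the hole stays background
    hole = ~truth.mask
    hole &= (np.add.outer(np.arange(128) - 64, np.zeros(128)) ** 2 +
             np.add.outer(np.zeros(128), np.arange(128) - 64) ** 2) < 10**2
    assert (result.mask & hole).sum() / hole.sum() < 0.1
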