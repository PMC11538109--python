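import numpy as np
import pytest

from mpmtools.errors import ConfigurationError, LabelError
from mpmtools.imaging_io import ZStack
from mpmtools.synthetic_fixtures import VesselFixtureSpec, make_segmentation_pairs, make_vessel_fixture
from mpmtools.vessel_seg import (
    AugmentationPolicy,
    ProbabilityMap,
    SegModelConfig,
    TilingScheme,
    augment_sample,
    component_circularity,
    dice_score,
    grid_search_segmentation,
    medial_axis_weights,
    predict_tiled,
    refine_probability_map,
    sato_vesselness_2d,
    train_segmentation_model,
)


class TestAugmentation:
    def test_deterministic_under_seed(self, rng):
        img = rng.normal(size=(96, 96))
        msk = (rng.random((96, 96)) > 0.8).astype(np.uint8)
        pol = AugmentationPolicy(crop_size=64, out_size=48)
        a1 = augment_sample(img, msk, pol, seed=5)
        a2 = augment_sample(img, msk, pol, seed=5)
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1], a2[1])

    def test_degenerate_policy_is_crop_and_resample_only(self, rng):
        img = rng.normal(size=(96, 96))
        msk = np.zeros((96, 96), np.uint8)
        pol = AugmentationPolicy(
            p_rotate=0, p_hflip=0, p_vflip=0, p_brightness_contrast=0,
            p_mult_noise=0, p_blur_noise=0, p_elastic=0, crop_size=48, out_size=48,
        )
        out_img, out_msk = augment_sample(img, msk, pol, seed=0)
        assert out_img.shape == (48, 48)
        # a 48 crop at out_size 48 needs no resampling: values come from the input
        assert np.isin(np.round(out_img, 10), np.round(img, 10)).all()

    def test_mask_stays_binary_and_tracks_geometry(self):
        img = np.zeros((96, 96))
        img[46:50, 10:86] = 1.0          # one horizontal tube
        msk = (img > 0).astype(np.uint8)
        pol = AugmentationPolicy(p_brightness_contrast=0, p_mult_noise=0, p_blur_noise=0,
                                 p_elastic=0, crop_size=96, out_size=96)
        out_img, out_msk = augment_sample(img, msk, pol, seed=11)
        assert set(np.unique(out_msk)).issubset({0, 1})
        bright = out_img > 0.5 * out_img.max()
        if bright.any():
            assert (out_msk[bright].mean()) > 0.6   # mask follows the transformed tube

    def test_small_image_is_padded(self, rng):
        img = rng.normal(size=(40, 40))
        msk = np.zeros((40, 40), np.uint8)
        out_img, _ = augment_sample(img, msk, AugmentationPolicy(crop_size=64, out_size=32), seed=0)
        assert out_img.shape == (32, 32)


class TestSegConfig:
    def test_steps_per_epoch_rule(self):
        cfg = SegModelConfig(batch_size=4)
        assert cfg.train_steps == 375
        assert cfg.val_steps == 125

    def test_filters_must_increase(self):
        with pytest.raises(ConfigurationError):
            SegModelConfig(filters=(64, 32))


class TestTiledPrediction:
    class ConstStub:
        def __init__(self, value):
            self.value = value

        def predict_patch(self, patch):
            return np.full(patch.shape, self.value)

    def test_constant_stub_gives_constant_map(self, rng):
        out = predict_tiled(self.ConstStub(0.4), rng.normal(size=(700, 650)), TilingScheme())
        assert out.image.shape == (700, 650)
        np.testing.assert_allclose(out.image, 0.4)

    def test_overlap_blending_is_exact_average(self):
        class AlternatingStub:
            def __init__(self):
                self.calls = 0

            def predict_patch(self, patch):
                self.calls += 1
                return np.full(patch.shape, 0.4 if self.calls == 1 else 0.6)

        scheme = TilingScheme(patch_size=64, stride=32, input_size=32)
        img = np.zeros((64, 96))
        out = predict_tiled(AlternatingStub(), img, scheme)
        np.testing.assert_allclose(out.image[:, 32:64], 0.5)   # overlap of both tiles
        np.testing.assert_allclose(out.image[:, :32], 0.4)
        np.testing.assert_allclose(out.image[:, 64:], 0.6)

    def test_image_smaller_than_patch_keeps_shape(self):
        out = predict_tiled(self.ConstStub(0.2), np.zeros((100, 80)), TilingScheme(patch_size=512, stride=256))
        assert out.image.shape == (100, 80)

    def test_stride_must_be_smaller_than_patch(self):
        with pytest.raises(ConfigurationError):
            TilingScheme(patch_size=64, stride=64)


class TestCircularityAndWeights:
    def test_ideal_disk_circularity_close_to_one(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (xx - 31.5) ** 2 + (yy - 31.5) ** 2 <= 25**2
        assert 0.9 <= component_circularity(disk) <= 1.05

    def test_rectangle_circularity_matches_formula(self):
        rect = np.zeros((20, 120), bool)
        rect[8:12, 10:110] = True        # 100 x 4 rectangle
        # 4*pi*400 / 208^2 ~ 0.116
        assert component_circularity(rect) == pytest.approx(0.116, abs=0.03)

    def test_medial_weights_limits(self):
        mask = np.zeros((21, 60), bool)
        mask[5:16, 5:55] = True          # 11-row band: medial axis on row 10
        w = medial_axis_weights(mask)
        assert w[10, 20:40].min() >= 0.999            # 1 on the medial axis
        assert w[~mask].max() == 0.0                  # 0 on background
        # equidistant between axis and border -> about one half
        assert w[7, 30] == pytest.approx(0.5, abs=0.15)


class TestRefinement:
    def test_blob_component_removed_tube_kept(self):
        prob = np.zeros((96, 160))
        yy, xx = np.mgrid[0:96, 0:160]
        prob[(xx - 130) ** 2 + (yy - 30) ** 2 <= 15**2] = 0.9       # disk: removed
        prob[45:49, 10:90] = 0.9                                     # tube with a junction spur
        prob[20:45, 48:52] = 0.9
        out = refine_probability_map(ProbabilityMap(image=prob))
        assert out.image[30, 130] == 0.0
        assert out.image[46:48, 20:40].max() > 0.0

    def test_junction_free_component_removed(self):
        prob = np.zeros((64, 128))
        prob[30:34, 10:110] = 0.9        # bare tube: skeleton has no junction
        out = refine_probability_map(ProbabilityMap(image=prob))
        assert out.image.max() == 0.0
        kept = refine_probability_map(ProbabilityMap(image=prob), require_junctions=False)
        assert kept.image.max() > 0.0

    def test_refinement_never_amplifies(self, rng):
        prob = np.clip(rng.random((64, 64)), 0, 1)
        out = refine_probability_map(ProbabilityMap(image=prob))
        assert np.all(out.image <= prob + 1e-12)


class TestSatoRoute:
    def test_blank_stack_gives_zero_map(self):
        stack = ZStack([np.zeros((64, 64)) for _ in range(4)], 1.0, 1.0)
        out = sato_vesselness_2d(stack)
        assert out.image.max() == 0.0

    def test_single_deep_tube_recovered(self):
        from mpmtools.morse_graph import MorseParams, extract_morse_skeleton, prune_and_filter, smooth_branches
        from mpmtools.synthetic_fixtures import true_network_stats
        from mpmtools.topology_stats import network_statistics

        spec = VesselFixtureSpec(n_branches=1, snr=20, seed=5, image_size=256,
                                 branch_length_um=(200, 260), pixel_size_um=2.0,
                                 render="zstack", n_planes=8)
        stack, truth, _ = make_vessel_fixture(spec)
        vess = sato_vesselness_2d(stack)
        assert vess.image.max() == 1.0
        g = smooth_branches(prune_and_filter(extract_morse_skeleton(vess, MorseParams(), 2.0), MorseParams()), 5)
        stats, _ = network_statistics(g)
        ts = true_network_stats(truth)
        assert stats.total_length_um == pytest.approx(ts["total_length_um"], rel=0.10)

    def test_tubes_at_different_depths_both_preserved(self):
        from mpmtools.morse_graph import MorseParams, extract_morse_skeleton, prune_and_filter, smooth_branches
        from mpmtools.synthetic_fixtures import true_network_stats
        from mpmtools.topology_stats import network_statistics

        spec = VesselFixtureSpec(n_branches=3, snr=20, seed=11, image_size=256,
                                 branch_length_um=(60, 150), pixel_size_um=2.0,
                                 render="zstack", n_planes=8)
        stack, truth, _ = make_vessel_fixture(spec)
        vess = sato_vesselness_2d(stack)
        g = smooth_branches(prune_and_filter(extract_morse_skeleton(vess, MorseParams(), 2.0), MorseParams()), 5)
        stats, _ = network_statistics(g)
        ts = true_network_stats(truth)
        assert abs(stats.branch_count - ts["branch_count"]) <= 1
        assert stats.total_length_um == pytest.approx(ts["total_length_um"], rel=0.15)


class TestTraining:
    def test_non_binary_mask_rejected(self, rng):
        pairs = [(rng.random((64, 64)), rng.random((64, 64)))]
        with pytest.raises(LabelError):
            train_segmentation_model(pairs, pairs, SegModelConfig(filters=(4, 8), input_size=32, epochs=1, steps_per_epoch=1))

    def test_desk_unet_reaches_dice_080(self):
        pairs = make_segmentation_pairs(40, seed=0)
        cfg = SegModelConfig(filters=(8, 16, 32, 64), input_size=64, epochs=5,
                             batch_size=4, steps_per_epoch=75)
        model = train_segmentation_model(pairs[:30], pairs[30:], cfg, seed=0)
        dices = [dice_score(model.predict_patch(img) >= 0.5, m) for img, m in pairs[30:]]
        assert float(np.mean(dices)) >= 0.8
        assert model.history["val_loss"][-1] < model.history["val_loss"][0]

    def test_grid_search_single_candidate_returns_it(self):
        pairs = make_segmentation_pairs(8, seed=3)
        base = SegModelConfig(filters=(4, 8), input_size=32, epochs=1, batch_size=2, steps_per_epoch=4)
        model, table = grid_search_segmentation(pairs[:6], pairs[6:], (1e-3,), ((4, 8),), base, seed=0)
        assert model.learning_rate == 1e-3
        assert model.filters == (4, 8)
        assert list(table) == [(1e-3, (4, 8))]
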