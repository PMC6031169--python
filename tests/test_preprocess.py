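import numpy as np
import pytest
from scipy import ndimage

from conftest import blob_from_mask
from oracles import connected_components_by_flood_fill
from layerfusion.io import DepthFrame
from layerfusion.preprocess import (
    NoSubjectError,
    build_background_model,
    denoise_mask,
    extract_blob,
    extract_foreground,
    locate_blob,
    masked_depth,
    remove_arms,
)


def _frame(arr, index=0):
    return DepthFrame(np.asarray(arr, dtype=np.uint8), frame_index=index)


class TestBackgroundModel:
    def test_constant_frames_give_zero_spread(self):
        frames = [_frame(np.full((5, 5), 100), i) for i in range(40)]
        model = build_background_model(frames)
        assert model.frame_count == 40
        np.testing.assert_array_equal(model.reference, 100.0)
        np.testing.assert_array_equal(model.spread, 0.0)

    def test_alternating_values_take_lower_median(self):
        frames = [_frame(np.full((3, 3), 100 if i % 2 == 0 else 102), i)
                  for i in range(40)]
        model = build_background_model(frames)
        np.testing.assert_array_equal(model.reference, 100.0)

    def test_single_frame_model_equals_frame(self, rng):
        px = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        model = build_background_model([_frame(px)])
        np.testing.assert_array_equal(model.reference, px.astype(float))

    def test_zero_frames_error(self):
        with pytest.raises(ValueError):
            build_background_model([])


class TestForeground:
    def test_background_identical_frame_gives_empty_mask(self):
        frames = [_frame(np.full((8, 8), 200), i) for i in range(10)]
        model = build_background_model(frames)
        mask = extract_foreground(_frame(np.full((8, 8), 200)), model, threshold=15)
        assert mask.sum() == 0

    def test_rectangular_subject_recovered_exactly(self):
        bg = np.full((40, 60), 200, dtype=np.uint8)
        model = build_background_model([_frame(bg, i) for i in range(5)])
        scene = bg.copy()
        scene[10:30, 25:35] = 80  # 20 rows x 10 cols at nearer depth
        mask = extract_foreground(_frame(scene), model, threshold=15)
        expected = np.zeros_like(scene)
        expected[10:30, 25:35] = 1
        np.testing.assert_array_equal(mask, expected)

    def test_saturated_threshold_gives_empty_mask(self):
        bg = np.zeros((5, 5), dtype=np.uint8)
        model = build_background_model([_frame(bg)])
        mask = extract_foreground(_frame(np.full((5, 5), 255)), model, threshold=255)
        assert mask.sum() == 0

    def test_dimension_mismatch_errors(self):
        model = build_background_model([_frame(np.zeros((4, 4)))])
        with pytest.raises(ValueError, match="shape"):
            extract_foreground(_frame(np.zeros((5, 5))), model)


class TestDenoise:
    def test_radius_zero_is_identity(self, rng):
        mask = (rng.random((20, 20)) < 0.5).astype(np.uint8)
        np.testing.assert_array_equal(denoise_mask(mask, 0), mask)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 4] = 1
        assert denoise_mask(mask, 1).sum() == 0

    def test_hole_filled_square_preserved(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[5:25, 5:25] = 1
        mask[12, 12] = 0
        # independent reference: scipy's grey-agnostic binary morphology
        structure = np.ones((3, 3), dtype=bool)
        expected = ndimage.binary_closing(
            ndimage.binary_opening(mask.astype(bool), structure), structure
        )
        result = denoise_mask(mask, 1)
        np.testing.assert_array_equal(result.astype(bool), expected)
        assert result[12, 12] == 1          # hole filled
        assert result[5:25, 5:25].all()     # square intact

    def test_open_close_filter_stable_on_silhouette_masks(self, rng):
        """On subject-like silhouettes (solid shapes plus speckle noise)
        a second denoise pass changes nothing."""
        from layerfusion.synthetic import (
            BACKGROUND_DEPTH, BodyParams, SceneConfig, render_action,
        )

        config = SceneConfig(mask_flip_rate=0.01, seed=0)
        for i, action in enumerate(("standing_walking", "sitting", "stooping",
                                    "lying")):
            frame = render_action(
                action, BodyParams(orientation_deg=45), 0.0, config,
                np.random.default_rng(i), dist_cm=380.0, x_center=80.0,
                n_frames=1,
            )[0]
            mask = (frame.pixels < BACKGROUND_DEPTH - 10).astype(np.uint8)
            once = denoise_mask(mask, 1)
            np.testing.assert_array_equal(denoise_mask(once, 1), once)


class TestMaskedDepth:
    def test_full_mask_is_identity(self, rng):
        px = rng.integers(0, 256, (7, 7)).astype(np.uint8)
        np.testing.assert_array_equal(
            masked_depth(np.ones((7, 7), np.uint8), _frame(px)), px
        )

    def test_empty_mask_gives_zeros(self):
        out = masked_depth(np.zeros((4, 4), np.uint8), _frame(np.full((4, 4), 9)))
        assert out.sum() == 0

    def test_checkerboard(self):
        mask = np.indices((6, 6)).sum(axis=0) % 2
        out = masked_depth(mask.astype(np.uint8), _frame(np.full((6, 6), 7)))
        np.testing.assert_array_equal(out, mask * 7)

    def test_zero_exactly_off_mask_pixelwise(self, rng):
        mask = (rng.random((15, 15)) < 0.5).astype(np.uint8)
        px = rng.integers(1, 256, (15, 15)).astype(np.uint8)
        out = masked_depth(mask, _frame(px))
        assert (out[mask == 0] == 0).all()
        np.testing.assert_array_equal(out[mask == 1], px[mask == 1])

    def test_mismatch_errors(self):
        with pytest.raises(ValueError):
            masked_depth(np.zeros((3, 3), np.uint8), _frame(np.zeros((4, 4))))


class TestLocateBlob:
    def test_single_rectangle(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[4:12, 3:8] = 1  # x=3, y=4, w=5, h=8
        assert locate_blob(mask) == (3, 4, 5, 8)

    def test_largest_of_two_components_selected(self, rng):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[2:6, 2:5] = 1     # 12 px
        mask[15:20, 10:18] = 1  # 40 px
        components = connected_components_by_flood_fill(mask)
        biggest = max(components, key=len)
        ys = [p[0] for p in biggest]
        xs = [p[1] for p in biggest]
        expected = (min(xs), min(ys), max(xs) - min(xs) + 1, max(ys) - min(ys) + 1)
        assert locate_blob(mask) == expected == (10, 15, 8, 5)

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(25):
            mask = (rng.random((25, 25)) < 0.25).astype(np.uint8)
            if not mask.any():
                continue
            components = connected_components_by_flood_fill(mask)
            best = max(components, key=len)
            areas = [len(c) for c in components]
            if areas.count(len(best)) != 1:
                continue  # ambiguous area tie: covered by the scan-order test
            ys = [p[0] for p in best]
            xs = [p[1] for p in best]
            assert locate_blob(mask) == (
                min(xs), min(ys), max(xs) - min(xs) + 1, max(ys) - min(ys) + 1
            )

    def test_area_tie_breaks_to_first_in_scan_order(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[1:3, 1:3] = 1  # topmost 4-px component
        mask[6:8, 6:8] = 1  # equal-area component further down
        assert locate_blob(mask) == (1, 1, 2, 2)

    def test_box_tightness(self, rng):
        for _ in range(20):
            mask = (rng.random((20, 20)) < 0.3).astype(np.uint8)
            if not mask.any():
                continue
            x, y, w, h = locate_blob(mask)
            # every edge row/column of the box contains a foreground pixel
            sub = mask[y:y + h, x:x + w]
            assert sub[0, :].any() and sub[-1, :].any()
            assert sub[:, 0].any() and sub[:, -1].any()

    def test_empty_mask_raises_no_subject(self):
        with pytest.raises(NoSubjectError):
            locate_blob(np.zeros((5, 5), dtype=np.uint8))


class TestRemoveArms:
    def test_strength_zero_is_identity(self, rng):
        blob = blob_from_mask((rng.random((30, 20)) < 0.6).astype(np.uint8))
        assert remove_arms(blob, strength=0) is blob

    def test_thin_arm_removed_box_shrinks_to_torso(self):
        # torso 20 px wide, 60 px tall, with a 2-px horizontal arm poking out
        mask = np.zeros((60, 45), dtype=np.uint8)
        mask[:, 5:25] = 1          # torso
        mask[20:22, 25:44] = 1     # arm: 2 rows tall, 19 cols long
        blob = blob_from_mask(mask)
        assert blob.width == 39
        out = remove_arms(blob, strength=0.05)  # element side = 3
        assert out.width == 20
        assert out.height == 60
        assert (out.depth_profile[out.mask == 0] == 0).all()

    def test_never_enlarges_mask(self, rng):
        for _ in range(10):
            blob = blob_from_mask((rng.random((40, 30)) < 0.7).astype(np.uint8))
            try:
                out = remove_arms(blob, strength=0.1)
            except NoSubjectError:
                continue
            assert out.mask.sum() <= blob.mask.sum()
            assert out.width <= blob.width and out.height <= blob.height

    def test_blob_thinner_than_element_raises(self):
        mask = np.zeros((40, 10), dtype=np.uint8)
        mask[:, 5] = 1  # 1-px-wide line, element side 2 wipes it out
        blob = blob_from_mask(mask)
        with pytest.raises(NoSubjectError):
            remove_arms(blob, strength=0.2)


class TestExtractBlob:
    def _scene(self):
        bg = np.full((60, 80), 220, dtype=np.uint8)
        model = build_background_model([_frame(bg, i) for i in range(5)])
        scene = bg.copy()
        scene[10:50, 30:50] = 90
        return model, scene

    def test_full_chain_recovers_subject_box(self):
        model, scene = self._scene()
        blob = extract_blob(_frame(scene), model, arm_strength=0)
        assert blob.bbox == (30, 10, 20, 40)
        assert blob.mask.sum() == 800
        assert (blob.depth_profile[blob.mask == 1] == 90).all()

    def test_external_mask_bypasses_background_model(self):
        model, scene = self._scene()
        ext = np.zeros((60, 80), dtype=np.uint8)
        ext[20:40, 10:20] = 255
        blob = extract_blob(_frame(scene), model, external_mask=ext, arm_strength=0)
        assert blob.bbox == (10, 20, 10, 20)

    def test_bbox_recovered_within_2px_under_noise(self):
        """Noisy rendering (<=1% flips) must not move the box by >2 px/side."""
        from layerfusion.synthetic import (
            BodyParams, SceneConfig, render_action, render_background,
        )

        clean_cfg = SceneConfig(mask_flip_rate=0.0, depth_jitter_sigma=0.0, seed=0)
        noisy_cfg = SceneConfig(mask_flip_rate=0.01, depth_jitter_sigma=1.0, seed=0)
        body = BodyParams(orientation_deg=0)
        kwargs = dict(dist_cm=400.0, x_center=80.0, n_frames=1)
        clean = render_action("standing_walking", body, 0.0, clean_cfg,
                              np.random.default_rng(3), **kwargs)[0]
        noisy = render_action("standing_walking", body, 0.0, noisy_cfg,
                              np.random.default_rng(3), **kwargs)[0]
        truth = locate_blob((clean.pixels < 235).astype(np.uint8))

        model = build_background_model(
            render_background(noisy_cfg, np.random.default_rng(4), 40)
        )
        blob = extract_blob(noisy, model, arm_strength=0)
        for got, want, size in zip(blob.bbox, truth, (1, 1, 0, 0)):
            assert abs(got - want) <= 2
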