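"""Image/mask I/O conventions and the synthetic scene generator."""

import numpy as np
import pytest
from PIL import Image as PILImage

from lesiongan.errors import ContractError, FormatError
from lesiongan.fixtures import (
    DatasetManifest,
    SceneParams,
    generate_dataset,
    generate_scene,
    read_image,
    read_mask,
    resize_pair,
    write_image,
    write_mask,
)


class TestImageIO:
    @pytest.mark.parametrize("value,expected", [(255, 1.0), (0, 0.0)])
    def test_eight_bit_scaling(self, tmp_path, value, expected):
        path = tmp_path / "c.png"
        PILImage.fromarray(np.full((4, 4, 3), value, np.uint8)).save(path)
        np.testing.assert_allclose(read_image(path), expected)

    def test_grayscale_replicated_to_three_channels(self, tmp_path):
        path = tmp_path / "g.png"
        PILImage.fromarray(np.full((4, 4), 128, np.uint8), mode="L").save(path)
        img = read_image(path)
        assert img.shape == (4, 4, 3)
        np.testing.assert_allclose(img, 128 / 255, atol=1e-7)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "absent.png")

    def test_non_image_content_raises(self, tmp_path):
        path = tmp_path / "junk.png"
        path.write_text("this is not an image")
        with pytest.raises(FormatError):
            read_image(path)

    def test_write_read_round_trip(self, tmp_path, rng):
        img = (rng.integers(0, 256, (8, 8, 3)) / 255.0).astype(np.float32)
        write_image(tmp_path / "rt.png", img)
        np.testing.assert_allclose(read_image(tmp_path / "rt.png"), img, atol=1e-7)


class TestMaskIO:
    def test_threshold_at_128(self, tmp_path):
        vals = np.array([[0, 127], [128, 255]], np.uint8)
        path = tmp_path / "m.png"
        PILImage.fromarray(vals, mode="L").save(path)
        np.testing.assert_array_equal(read_mask(path), [[0, 0], [1, 1]])

    def test_multichannel_unequal_raises(self, tmp_path):
        arr = np.zeros((4, 4, 3), np.uint8)
        arr[:, :, 0] = 255
        path = tmp_path / "bad.png"
        PILImage.fromarray(arr).save(path)
        with pytest.raises(FormatError):
            read_mask(path)

    def test_write_read_is_identity(self, tmp_path, rng):
        mask = rng.integers(0, 2, (16, 16)).astype(np.uint8)
        write_mask(tmp_path / "m.png", mask)
        np.testing.assert_array_equal(read_mask(tmp_path / "m.png"), mask)


class TestResizePair:
    def test_identity_resize(self, rng):
        img = rng.random((10, 10, 3)).astype(np.float32)
        mask = rng.integers(0, 2, (10, 10)).astype(np.uint8)
        rimg, rmask = resize_pair(img, mask, 10)
        np.testing.assert_array_equal(rimg, img)
        np.testing.assert_array_equal(rmask, mask)

    def test_constant_mask_upsample_stays_constant(self):
        img = np.zeros((100, 100, 3), np.float32)
        mask = np.ones((100, 100), np.uint8)
        _, rmask = resize_pair(img, mask, 512)
        assert rmask.shape == (512, 512)
        assert np.all(rmask == 1)

    def test_checkerboard_downsample_stays_binary(self):
        mask = (np.indices((64, 64)).sum(0) % 2).astype(np.uint8)
        img = np.repeat(mask[:, :, None], 3, 2).astype(np.float32)
        _, rmask = resize_pair(img, mask, 16)
        assert set(np.unique(rmask)) <= {0, 1}

    def test_mismatched_pair_raises(self):
        with pytest.raises(ContractError):
            resize_pair(np.zeros((8, 8, 3)), np.zeros((9, 9)), 4)


class TestSceneGeneration:
    def test_deterministic_in_params_and_seed(self):
        p = SceneParams(image_size=64)
        a = generate_scene(p, 5)
        b = generate_scene(p, 5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_different_seeds_differ(self):
        p = SceneParams(image_size=64)
        a = generate_scene(p, 5)
        b = generate_scene(p, 6)
        assert not np.array_equal(a[1], b[1])

    def test_lesion_area_within_requested_range(self):
        p = SceneParams(image_size=96, lesion_area_range=(0.05, 0.4))
        for seed in range(12):
            _, mask = generate_scene(p, seed)
            assert 0.05 <= mask.mean() <= 0.4

    def test_contrast_gap_without_noise(self):
        p = SceneParams(image_size=96, noise_sd=0, vignette_strength=0,
                        hair_count=0, contrast_delta=0.5)
        img, mask = generate_scene(p, 3)
        intensity = img.mean(axis=2)
        gap = intensity[mask == 0].mean() - intensity[mask == 1].mean()
        # anti-aliased boundary ring softens the gap slightly
        assert gap == pytest.approx(0.5, abs=0.02)

    def test_clean_scene_histogram_is_bimodal(self):
        from scipy import ndimage
        p = SceneParams(image_size=96, noise_sd=0, vignette_strength=0,
                        hair_count=0, contrast_delta=0.5)
        img, mask = generate_scene(p, 3)
        intensity = img.mean(axis=2)
        # exclude the 1-px anti-aliased boundary ring on both sides
        interior = ndimage.binary_erosion(mask, iterations=2)
        exterior = ndimage.binary_erosion(1 - mask, iterations=2)
        inside = intensity[interior]
        outside = intensity[exterior]
        assert inside.std() < 1e-4 and outside.std() < 1e-4  # two sharp modes
        assert outside.mean() - inside.mean() == pytest.approx(0.5, abs=0.005)

    def test_hair_only_affects_image_not_mask(self):
        base = SceneParams(image_size=64, hair_count=0, noise_sd=0)
        hairy = SceneParams(image_size=64, hair_count=5, noise_sd=0)
        _, m0 = generate_scene(base, 9)
        img_h, m1 = generate_scene(hairy, 9)
        np.testing.assert_array_equal(m0, m1)

    def test_invalid_params_raise(self):
        with pytest.raises(ContractError):
            SceneParams(lesion_area_range=(0.4, 0.1))
        with pytest.raises(ContractError):
            SceneParams(noise_sd=-0.1)


class TestDatasetGeneration:
    def test_record_count_and_files(self, tmp_path):
        man = generate_dataset(3, SceneParams(image_size=48), 1, tmp_path / "d")
        assert len(man) == 3
        pngs = sorted((tmp_path / "d").glob("*.png"))
        assert len(pngs) == 6

    def test_regeneration_is_byte_identical(self, tmp_path):
        man1 = generate_dataset(2, SceneParams(image_size=48), 7, tmp_path / "a")
        man2 = generate_dataset(2, SceneParams(image_size=48), 7, tmp_path / "b")
        for i in range(2):
            assert man1.image_path(i).read_bytes() == man2.image_path(i).read_bytes()
            assert man1.mask_path(i).read_bytes() == man2.mask_path(i).read_bytes()

    def test_all_masks_nonempty(self, tmp_path):
        man = generate_dataset(50, SceneParams(image_size=48), 13, tmp_path / "d")
        for i in range(len(man)):
            assert read_mask(man.mask_path(i)).sum() > 0

    def test_manifest_round_trip(self, tmp_path):
        man = generate_dataset(3, SceneParams(image_size=48), 1, tmp_path / "d")
        loaded = DatasetManifest.load(tmp_path / "d" / "manifest.tsv")
        assert [r.seed for r in loaded.records] == [r.seed for r in man.records]
        assert loaded.image_path(0).exists()

    def test_seeds_unique(self, tmp_path):
        man = generate_dataset(20, SceneParams(image_size=48), 3, tmp_path / "d")
        seeds = [r.seed for r in man.records]
        assert len(set(seeds)) == 20
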