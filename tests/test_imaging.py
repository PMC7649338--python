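import numpy as np
import pytest

from sunseg.errors import CoverageError, FormatError, ShapeError, SizeError
from sunseg.imaging import (
    InstanceLabelMap,
    RgbPatch,
    build_pyramid,
    read_image,
    read_label_map,
    stitch_patches,
    tile_patches,
    write_image,
    write_label_map,
)


class TestReadWrite:
    def test_rgb_round_trip(self, tmp_path):
        arr = np.random.default_rng(0).integers(0, 256, (37, 29, 3), dtype=np.uint8)
        write_image(tmp_path / "a.png", arr)
        patch = read_image(tmp_path / "a.png")
        assert patch.origin == (0, 0)
        np.testing.assert_array_equal(patch.pixels, arr)

    def test_grayscale_replicated_to_three_channels(self, tmp_path):
        import imageio.v3 as iio

        gray = np.random.default_rng(1).integers(0, 256, (16, 16), dtype=np.uint8)
        iio.imwrite(tmp_path / "g.png", gray)
        patch = read_image(tmp_path / "g.png")
        assert patch.pixels.shape == (16, 16, 3)
        for c in range(3):
            np.testing.assert_array_equal(patch.pixels[:, :, c], gray)

    def test_alpha_channel_dropped(self, tmp_path):
        import imageio.v3 as iio

        rgba = np.random.default_rng(2).integers(0, 256, (8, 8, 4), dtype=np.uint8)
        iio.imwrite(tmp_path / "a.png", rgba)
        np.testing.assert_array_equal(read_image(tmp_path / "a.png").pixels, rgba[:, :, :3])

    def test_truncated_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "t.png"
        bad.write_bytes(b"\x89PNG\r\n\x1a\n but then garbage")
        with pytest.raises(FormatError):
            read_image(bad)

    def test_label_map_round_trip_preserves_ids(self, tmp_path):
        labels = np.zeros((20, 20), dtype=np.uint16)
        labels[2:8, 2:8] = 3
        labels[10:15, 10:18] = 999
        write_label_map(tmp_path / "l.png", labels)
        ilm = read_label_map(tmp_path / "l.png")
        assert sorted(lid for lid, _ in ilm.objects) == [3, 999]
        np.testing.assert_array_equal(ilm.to_flat(), labels)


class TestInstanceLabelMap:
    def test_flattened_view_gives_shared_pixels_to_lowest_id(self):
        a = np.zeros((5, 5), bool)
        a[0:3, 0:3] = True
        b = np.zeros((5, 5), bool)
        b[1:4, 1:4] = True
        ilm = InstanceLabelMap(shape=(5, 5), objects=[(2, b), (1, a)])
        flat = ilm.to_flat()
        assert flat[2, 2] == 1  # shared pixel -> lowest label id
        assert flat[3, 3] == 2

    def test_duplicate_or_empty_objects_rejected(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ShapeError):
            InstanceLabelMap(shape=(4, 4), objects=[(1, m), (1, m)])
        with pytest.raises(ShapeError):
            InstanceLabelMap(shape=(4, 4), objects=[(1, np.zeros((4, 4), bool))])

    def test_overlap_mask_is_multiply_covered_pixels(self):
        a = np.zeros((5, 5), bool)
        a[:3, :3] = True
        b = np.zeros((5, 5), bool)
        b[2:, 2:] = True
        ilm = InstanceLabelMap(shape=(5, 5), objects=[(1, a), (2, b)])
        np.testing.assert_array_equal(ilm.overlap_mask(), a & b)
        np.testing.assert_array_equal(ilm.union_mask(), a | b)


class TestTiling:
    def test_1000px_image_tiles_into_nine_inward_shifted_patches(self):
        img = RgbPatch(np.zeros((1000, 1000, 3), np.uint8))
        patches = tile_patches(img, 384, 384)
        assert len(patches) == 9
        origins = {p.origin for p in patches}
        assert origins == {(r, c) for r in (0, 384, 616) for c in (0, 384, 616)}
        assert all(p.pixels.shape == (384, 384, 3) for p in patches)

    def test_exact_fit_gives_single_tile(self):
        img = RgbPatch(np.zeros((384, 384, 3), np.uint8))
        patches = tile_patches(img, 384, 100)
        assert len(patches) == 1 and patches[0].origin == (0, 0)

    def test_image_smaller_than_patch_raises(self):
        with pytest.raises(SizeError):
            tile_patches(RgbPatch(np.zeros((200, 200, 3), np.uint8)), 384)

    def test_tile_then_stitch_reproduces_image(self):
        rng = np.random.default_rng(3)
        img = rng.random((70, 90))
        pieces = tile_patches(img, 32, 24)
        out = stitch_patches(pieces, (70, 90))
        np.testing.assert_allclose(out, img, atol=1e-12)


class TestStitching:
    def test_single_full_piece_is_identity(self):
        m = np.random.default_rng(4).random((10, 12))
        np.testing.assert_array_equal(stitch_patches([(m, (0, 0))], (10, 12)), m)

    def test_overlap_strip_is_averaged(self):
        a = np.full((4, 6), 0.2)
        b = np.full((4, 6), 0.6)
        out = stitch_patches([(a, (0, 0)), (b, (0, 4))], (4, 10))
        np.testing.assert_allclose(out[:, 4:6], 0.4)
        np.testing.assert_allclose(out[:, :4], 0.2)
        np.testing.assert_allclose(out[:, 6:], 0.6)

    def test_piece_past_border_raises(self):
        with pytest.raises(CoverageError):
            stitch_patches([(np.zeros((5, 5)), (6, 6))], (10, 10))

    def test_uncovered_pixels_raise(self):
        with pytest.raises(CoverageError):
            stitch_patches([(np.zeros((5, 5)), (0, 0))], (10, 10))


class TestPyramid:
    def test_level_sizes_at_384(self):
        pyr = build_pyramid(np.zeros((384, 384, 3), np.uint8))
        assert [lvl.shape[0] for _, lvl in pyr.levels] == [480, 384, 288, 192]
        assert [f for f, _ in pyr.levels] == [1.25, 1.0, 0.75, 0.5]

    def test_constant_image_stays_constant_at_every_level(self):
        img = np.full((64, 64, 3), 137, np.uint8)
        for _, lvl in build_pyramid(img).levels:
            assert (lvl == 137).all()

    def test_binary_fourth_channel_stays_binary(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 256, (64, 64, 4), dtype=np.uint8)
        x[:, :, 3] = (rng.random((64, 64)) > 0.5) * 255
        for _, lvl in build_pyramid(x).levels:
            assert set(np.unique(lvl[:, :, 3])) <= {0, 255}

    def test_non_square_patch_rejected(self):
        with pytest.raises(ShapeError):
            build_pyramid(np.zeros((64, 32, 3), np.uint8))
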