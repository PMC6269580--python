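"""Loading, binarization, alignment, unfolding and matrix preprocessing."""

import numpy as np
import pytest
from PIL import Image

from miaqsar import StructureImage, align, center, drop_zero_variance, fold, load_image, unfold
from miaqsar.imaging import DescriptorMatrix, _translate


def _save(tmp_path, arr, name="img.png"):
    path = tmp_path / name
    Image.fromarray(np.asarray(arr, dtype=np.uint8), mode="L").save(path)
    return path


class TestLoadImage:
    def test_all_white_image_has_no_strokes(self, tmp_path):
        path = _save(tmp_path, np.full((4, 4), 255))
        img = load_image(path)
        assert img.pixels.sum() == 0

    def test_dark_on_light_drawing_is_inverted(self, tmp_path):
        """Dark pixels (value 0) are the strokes after polarity inversion."""
        arr = np.full((6, 6), 255)
        arr[2, 1:5] = 0
        img = load_image(_save(tmp_path, arr), threshold=0.5)
        assert np.array_equal(img.pixels, (arr == 0).astype(np.uint8))

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.png"
        bad.write_text("not an image")
        with pytest.raises(ValueError, match="cannot read"):
            load_image(bad)


class TestAlign:
    def test_image_already_at_anchor_is_unchanged(self):
        px = np.zeros((9, 9), dtype=np.uint8)
        px[4, 4] = 1
        out = align([StructureImage(px, anchor=(4, 4))], (4, 4))
        assert np.array_equal(out[0].pixels, px)

    def test_single_pixel_lands_on_common_anchor(self):
        px = np.zeros((100, 120), dtype=np.uint8)
        px[10, 10] = 1
        out = align([StructureImage(px, anchor=(10, 10))], (80, 110))
        assert out[0].pixels[80, 110] == 1
        assert out[0].pixels.sum() == 1

    def test_translate_then_align_equals_align_of_original(self, rng):
        # strokes confined to the center so neither translation clips them
        base = np.zeros((20, 20), dtype=np.uint8)
        base[7:14, 7:14] = (rng.random((7, 7)) < 0.4).astype(np.uint8)
        base[10, 10] = 1
        for dr, dc in [(2, 3), (-4, 1), (0, -5)]:
            moved = _translate(base, dr, dc)
            a = align([StructureImage(moved, anchor=(10 + dr, 10 + dc))], (12, 12))[0]
            b = align([StructureImage(base, anchor=(10, 10))], (12, 12))[0]
            assert np.array_equal(a.pixels, b.pixels)

    def test_dimension_mismatch_names_compound(self):
        a = StructureImage(np.zeros((4, 4), dtype=np.uint8), anchor=(0, 0), compound_id="A")
        b = StructureImage(np.zeros((5, 5), dtype=np.uint8), anchor=(0, 0), compound_id="B")
        with pytest.raises(ValueError, match="B"):
            align([a, b], (0, 0))


class TestUnfold:
    def test_31_images_unfold_to_31_by_38400(self):
        imgs = [
            StructureImage(np.zeros((160, 240), dtype=np.uint8)) for _ in range(31)
        ]
        m = unfold(imgs)
        assert m.values.shape == (31, 38400)

    def test_single_pixel_image(self):
        m = unfold([StructureImage(np.ones((1, 1), dtype=np.uint8))])
        assert m.values.shape == (1, 1)

    def test_fold_inverts_unfold(self, rng):
        imgs = [
            StructureImage((rng.random((7, 9)) < 0.5).astype(np.uint8)) for _ in range(5)
        ]
        grids = fold(unfold(imgs))
        for grid, im in zip(grids, imgs):
            assert np.array_equal(grid, im.pixels)


class TestDropZeroVariance:
    def test_retains_only_varying_columns(self):
        m = DescriptorMatrix(
            values=np.array([[0.0, 1.0], [0.0, 0.0]]),
            column_map=[(0, 0), (0, 1)],
            image_shape=(1, 2),
        )
        out = drop_zero_variance(m)
        assert out.values.shape == (2, 1)
        assert tuple(out.column_map[0]) == (0, 1)
        assert tuple(out.removed_columns[0]) == (0, 0)

    def test_idempotent(self, rng):
        values = (rng.random((6, 40)) < 0.5).astype(float)
        values[:, ::4] = 1.0  # constant columns
        m = DescriptorMatrix(values=values, column_map=np.argwhere(np.ones((4, 10))), image_shape=(4, 10))
        once = drop_zero_variance(m)
        twice = drop_zero_variance(once)
        assert np.array_equal(once.values, twice.values)

    def test_never_removes_disagreeing_column(self, rng):
        values = (rng.random((8, 50)) < 0.3).astype(float)
        m = DescriptorMatrix(values=values, column_map=np.argwhere(np.ones((5, 10))), image_shape=(5, 10))
        out = drop_zero_variance(m)
        kept = {tuple(rc) for rc in out.column_map}
        for j in range(50):
            if values[:, j].max() != values[:, j].min():
                assert (j // 10, j % 10) in kept

    def test_all_constant_raises(self):
        m = DescriptorMatrix(
            values=np.ones((3, 4)), column_map=np.argwhere(np.ones((2, 2))), image_shape=(2, 2)
        )
        with pytest.raises(ValueError, match="constant"):
            drop_zero_variance(m)

    def test_column_accounting_invariant(self, default_dataset):
        full = unfold(default_dataset.images)
        filt = drop_zero_variance(full)
        h, w = filt.image_shape
        assert filt.n_columns + len(filt.removed_columns) == h * w


class TestCenter:
    def test_self_centering_zeroes_column_sums(self, rng):
        m = DescriptorMatrix(
            values=rng.random((6, 8)), column_map=np.argwhere(np.ones((2, 4))), image_shape=(2, 4)
        )
        out = center(m)
        np.testing.assert_allclose(out.values.sum(axis=0), 0, atol=1e-9 * 6)

    def test_training_means_centering_is_invertible(self, rng):
        means = rng.random(4)
        row = rng.random((1, 4))
        m = DescriptorMatrix(
            values=row, column_map=np.argwhere(np.ones((1, 4))), image_shape=(1, 4)
        )
        out = center(m, means=means)
        np.testing.assert_allclose(out.values + means, row)

    def test_two_row_binary_column_becomes_plus_minus_half(self):
        m = DescriptorMatrix(
            values=np.array([[0.0], [1.0]]), column_map=[(0, 0)], image_shape=(1, 1)
        )
        np.testing.assert_allclose(center(m).values, [[-0.5], [0.5]])

    def test_means_length_mismatch_raises(self):
        m = DescriptorMatrix(
            values=np.zeros((2, 3)), column_map=np.argwhere(np.ones((1, 3))), image_shape=(1, 3)
        )
        with pytest.raises(ValueError, match="means"):
            center(m, means=np.zeros(5))
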