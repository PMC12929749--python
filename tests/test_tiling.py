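import numpy as np
import pytest

from rpeseg.core import GeometryError
from rpeseg.planes import PlaneView
from rpeseg.tiling import (Tile, lattice_offsets, reassemble, sample_tiles,
                           stretch_axial, unstretch_axial)


def _brute_force_keep(footprint, r, c, size, frac_min, abs_min):
    total = footprint.sum()
    inside = footprint[r:r + size, c:c + size].sum()
    return total > 0 and (inside >= frac_min * total or inside >= abs_min)


class TestStretch:
    def test_32_slices_stretch_to_64_factor_2(self):
        arr = np.random.default_rng(0).random((32, 10, 10))
        out, factor = stretch_axial(arr)
        assert out.shape == (64, 10, 10)
        assert factor == 2.0

    def test_long_enough_stack_unchanged(self):
        arr = np.random.default_rng(0).random((70, 8, 8))
        out, factor = stretch_axial(arr)
        assert factor == 1.0
        np.testing.assert_array_equal(out, arr)

    def test_mask_round_trip_exact_at_factor_2(self):
        mask = (np.random.default_rng(1).random((32, 12, 12)) > 0.8).astype(np.uint8)
        stretched, factor = stretch_axial(mask, order=0)
        assert factor == 2.0
        back = unstretch_axial(stretched, 32, order=0)
        np.testing.assert_array_equal(back, mask)

    def test_linear_stretch_preserves_constants(self):
        arr = np.full((40, 4, 4), 0.7)
        out, _ = stretch_axial(arr, order=1)
        np.testing.assert_allclose(out, 0.7)


class TestLattice:
    def test_exact_multiple_has_no_clamped_square(self):
        assert lattice_offsets(128) == [0, 32, 64]

    def test_edge_clamp_added_when_needed(self):
        assert lattice_offsets(100) == [0, 32, 36]

    def test_too_small_extent_raises(self):
        with pytest.raises(GeometryError):
            lattice_offsets(40)


class TestSampleTiles:
    def test_small_region_inside_one_square_is_kept(self):
        img = np.zeros((128, 128))
        fp = np.zeros((128, 128), dtype=np.uint8)
        fp[10:15, 10:16] = 1  # 30 px, all inside the (0,0) square
        tiles = sample_tiles(img, fp, PlaneView.AXIAL, 0, abs_min=1000)
        offs = {(t.row_off, t.col_off) for t in tiles}
        assert (0, 0) in offs
        # squares with zero overlap are never kept
        assert (64, 64) not in offs

    def test_empty_footprint_gives_no_tiles(self):
        img = np.zeros((128, 128))
        fp = np.zeros((128, 128), dtype=np.uint8)
        assert sample_tiles(img, fp, PlaneView.AXIAL, 0) == []

    def test_abs_min_rule_keeps_large_absolute_overlap(self):
        img = np.zeros((128, 128))
        fp = np.ones((128, 128), dtype=np.uint8)  # every square holds 4096 px
        tiles = sample_tiles(img, fp, PlaneView.AXIAL, 0,
                             frac_min=10.0, abs_min=1000)
        assert len(tiles) == 9  # kept via the absolute rule only

    def test_matches_exhaustive_rule_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(500):
            h = int(rng.integers(64, 140))
            w = int(rng.integers(64, 140))
            img = rng.random((h, w))
            fp = np.zeros((h, w), dtype=np.uint8)
            if rng.random() > 0.1:
                r0, c0 = rng.integers(0, h - 4), rng.integers(0, w - 4)
                fp[r0:r0 + rng.integers(2, 40), c0:c0 + rng.integers(2, 40)] = 1
            abs_min = int(rng.integers(10, 200))
            tiles = sample_tiles(img, fp, PlaneView.AXIAL, 0, abs_min=abs_min)
            got = {(t.row_off, t.col_off) for t in tiles}
            expected = {(r, c)
                        for r in lattice_offsets(h)
                        for c in lattice_offsets(w)
                        if _brute_force_keep(fp, r, c, 64, 1 / 3, abs_min)}
            assert got == expected

    def test_tile_pixels_cut_with_exact_provenance(self):
        rng = np.random.default_rng(9)
        img = rng.random((128, 128))
        fp = np.zeros((128, 128), dtype=np.uint8)
        fp[40:60, 40:60] = 1
        for t in sample_tiles(img, fp, PlaneView.AXIAL, 5):
            np.testing.assert_allclose(
                np.asarray(t.pixels, float),
                img[t.row_off:t.row_off + 64, t.col_off:t.col_off + 64],
                atol=1e-3)
            assert t.slice_index == 5


class TestReassemble:
    def test_single_tile_inserts_exactly(self):
        tile = Tile(pixels=np.zeros((64, 64), np.float16), view=PlaneView.AXIAL,
                    slice_index=2, row_off=32, col_off=0)
        out = reassemble([tile], [np.ones((64, 64))], (5, 128, 128))
        assert out[2, 32:96, 0:64].min() == 1.0
        assert out.sum() == 64 * 64  # zero everywhere else

    def test_overlap_mean_rule(self):
        mk = lambda r, c: Tile(pixels=np.zeros((64, 64), np.float16),
                               view=PlaneView.AXIAL, slice_index=0,
                               row_off=r, col_off=c)
        out = reassemble([mk(0, 0), mk(0, 32)],
                         [np.ones((64, 64)), np.zeros((64, 64))],
                         (1, 64, 128))
        assert out[0, :, :32].min() == 1.0
        np.testing.assert_allclose(out[0, :, 32:64], 0.5)

    def test_no_tiles_gives_all_zero_map(self):
        out = reassemble([], [], (4, 64, 64))
        assert not out.any()

    def test_permutation_invariant_over_tile_order(self):
        rng = np.random.default_rng(2)
        tiles, preds = [], []
        for r in (0, 32, 64):
            for c in (0, 32, 64):
                tiles.append(Tile(pixels=np.zeros((64, 64), np.float16),
                                  view=PlaneView.CORONAL, slice_index=1,
                                  row_off=r, col_off=c))
                preds.append(rng.random((64, 64)))
        a = reassemble(tiles, preds, (128, 3, 128))
        order = rng.permutation(len(tiles))
        b = reassemble([tiles[i] for i in order], [preds[i] for i in order],
                       (128, 3, 128))
        np.testing.assert_allclose(a, b)

    def test_out_of_bounds_provenance_rejected(self):
        tile = Tile(pixels=np.zeros((64, 64), np.float16), view=PlaneView.AXIAL,
                    slice_index=0, row_off=100, col_off=0)
        with pytest.raises(GeometryError):
            reassemble([tile], [np.ones((64, 64))], (1, 128, 128))

    def test_sagittal_tiles_land_in_zy_plane(self):
        tile = Tile(pixels=np.zeros((64, 64), np.float16),
                    view=PlaneView.SAGITTAL, slice_index=3, row_off=0, col_off=0)
        out = reassemble([tile], [np.ones((64, 64))], (64, 64, 8))
        assert out[:, :, 3].all() and out[:, :, 2].sum() == 0
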