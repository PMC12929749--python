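import numpy as np
import pytest

from rpeseg.core import BinaryMask3D
from rpeseg.localize import PositiveRegion, build_region
from rpeseg.planes import PlaneView, view_labels
from rpeseg.segment import (SegTrainConfig, build_unet, collect_view_tiles,
                            majority_vote, predict_view_mask, train_unet)


def _mask(data, spacing=(1, 1, 1)):
    return BinaryMask3D(data=np.asarray(data, np.uint8), spacing=spacing)


class TestArchitecture:
    def test_reference_parameter_count(self):
        assert build_unet(seed=0).num_params() == 116_753

    def test_output_matches_input_spatial_shape(self):
        u = build_unet(seed=0, filters=(2, 3, 4))
        p = u.predict_tiles(np.random.default_rng(0).random((3, 64, 64)))
        assert p.shape == (3, 64, 64)
        assert p.min() > 0.0 and p.max() < 1.0

    def test_seeded_rebuild_is_identical(self):
        x = np.random.default_rng(1).random((2, 64, 64)).astype(np.float32)
        a = build_unet(seed=4, filters=(2, 3, 4)).predict_tiles(x)
        b = build_unet(seed=4, filters=(2, 3, 4)).predict_tiles(x)
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip(self, tmp_path):
        from rpeseg._nn import load_params, save_params
        x = np.random.default_rng(2).random((1, 64, 64)).astype(np.float32)
        src = build_unet(seed=7, filters=(2, 3, 4))
        save_params(tmp_path / "u.npz", src.params)
        dst = build_unet(seed=8, filters=(2, 3, 4))
        load_params(tmp_path / "u.npz", dst.params)
        np.testing.assert_array_equal(src.predict_tiles(x), dst.predict_tiles(x))
        wrong = build_unet(seed=0, filters=(2, 3, 8))
        with pytest.raises(ValueError):
            load_params(tmp_path / "u.npz", wrong.params)


class TestTraining:
    @pytest.fixture(scope="class")
    def blob_tiles(self):
        """Bright-blob tiles whose truth is the blob itself."""
        rng = np.random.default_rng(6)
        xs, qs = [], []
        for _ in range(70):
            img = rng.normal(0.2, 0.05, (64, 64))
            q = np.zeros((64, 64), np.float32)
            r, c = rng.integers(8, 40, 2)
            q[r:r + 16, c:c + 16] = 1
            img[q > 0] += 0.5
            xs.append(np.clip(img, 0, 1))
            qs.append(q)
        return np.stack(xs).astype(np.float32), np.stack(qs)

    def test_soft_dice_loss_decreases(self, blob_tiles):
        x, q = blob_tiles
        u = build_unet(seed=0, filters=(2, 4, 8))
        hist = train_unet(u, x, q, SegTrainConfig(epochs=8, seed=0))
        assert hist[-1] < hist[0]

    def test_learns_to_segment_held_out_blob(self, blob_tiles):
        x, q = blob_tiles
        u = build_unet(seed=1, filters=(4, 8, 16))
        train_unet(u, x[:60], q[:60], SegTrainConfig(epochs=30, seed=1))
        p = (u.predict_tiles(x[60:]) >= 0.5)
        inter = (p * q[60:]).sum()
        dice = 2 * inter / (p.sum() + q[60:].sum())
        assert dice > 0.5

    def test_all_empty_truth_rejected(self, blob_tiles):
        x, _ = blob_tiles
        u = build_unet(seed=0, filters=(2, 2, 2))
        with pytest.raises(ValueError):
            train_unet(u, x, np.zeros_like(x), SegTrainConfig(epochs=1))


class TestMajorityVote:
    def test_three_identical_masks_pass_through(self, small_mask):
        out = majority_vote(small_mask, small_mask, small_mask)
        np.testing.assert_array_equal(out.data, small_mask.data)

    def test_matches_vote_truth_table(self):
        """Per-voxel 2-of-3 rule against brute-force enumeration."""
        rng = np.random.default_rng(1)
        a, b, c = (rng.integers(0, 2, (4, 4, 4)) for _ in range(3))
        out = majority_vote(_mask(a), _mask(b), _mask(c)).data
        for z in range(4):
            for y in range(4):
                for x in range(4):
                    votes = a[z, y, x] + b[z, y, x] + c[z, y, x]
                    assert out[z, y, x] == (1 if votes >= 2 else 0)

    def test_bounded_by_intersection_and_union(self):
        rng = np.random.default_rng(2)
        a, b, c = (rng.integers(0, 2, (5, 5, 5)) for _ in range(3))
        out = majority_vote(_mask(a), _mask(b), _mask(c)).data
        inter = a & b & c
        union = a | b | c
        assert np.all(out >= inter)
        assert np.all(out <= union)

    def test_duplicate_mask_dominates(self):
        rng = np.random.default_rng(3)
        m = _mask(rng.integers(0, 2, (3, 3, 3)))
        other = _mask(rng.integers(0, 2, (3, 3, 3)))
        out = majority_vote(m, m, other)
        np.testing.assert_array_equal(out.data, m.data)


class TestPrediction:
    def test_empty_region_gives_empty_mask(self, easy_case):
        u = build_unet(seed=0, filters=(2, 2, 2))
        empty = PositiveRegion((), (), ())
        out = predict_view_mask(u, easy_case.volume, empty, PlaneView.AXIAL)
        assert not out.data.any()
        assert out.shape == easy_case.volume.shape

    def test_prediction_confined_to_tile_footprints(self, easy_case):
        """Zero-initialized maps: voxels no tile covers stay negative."""
        region = build_region(view_labels(easy_case.mask, PlaneView.AXIAL),
                              view_labels(easy_case.mask, PlaneView.CORONAL),
                              view_labels(easy_case.mask, PlaneView.SAGITTAL))
        u = build_unet(seed=0, filters=(2, 2, 2))
        out = predict_view_mask(u, easy_case.volume, region, PlaneView.AXIAL,
                                threshold=1e-9, abs_min=62)
        tiles, _, _, _ = collect_view_tiles(easy_case.volume, region,
                                            PlaneView.AXIAL, abs_min=62)
        footprint = np.zeros(easy_case.volume.shape, bool)
        for t in tiles:
            footprint[t.slice_index, t.row_off:t.row_off + 64,
                      t.col_off:t.col_off + 64] = True
        # even with threshold 0 every positive voxel lies under some tile
        assert np.all(footprint[out.data.astype(bool)])

    def test_truth_tiles_share_provenance_with_image_tiles(self, easy_case):
        region = build_region(view_labels(easy_case.mask, PlaneView.AXIAL),
                              view_labels(easy_case.mask, PlaneView.CORONAL),
                              view_labels(easy_case.mask, PlaneView.SAGITTAL))
        tiles, truths, shape, nz = collect_view_tiles(
            easy_case.volume, region, PlaneView.CORONAL,
            mask=easy_case.mask, abs_min=62)
        assert len(tiles) == len(truths) > 0
        assert shape[0] == 64 and nz == easy_case.volume.shape[0]
        # truth patches are binary and some carry lesion
        assert all(set(np.unique(q)) <= {0.0, 1.0} for q in truths)
        assert any(q.sum() > 0 for q in truths)
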