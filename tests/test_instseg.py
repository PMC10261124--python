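import numpy as np
import pytest
from scipy import ndimage

from nucsplit3d import (
    InstanceSegParams,
    LabelVolume,
    VectorField,
    blob_map,
    conditional_erosion,
    generate_vector_field,
    gradient_map,
    remove_small,
    segment_instances,
    watershed_split,
)


def sobel_kernel(axis):
    """Unnormalized 3D Sobel: derivative [-1,0,1] along axis (as a
    correlation stencil), smoothing [1,2,1] along the others."""
    deriv = np.array([-1.0, 0.0, 1.0])
    smooth = np.array([1.0, 2.0, 1.0])
    parts = [smooth, smooth, smooth]
    parts[axis] = deriv
    return np.einsum("i,j,k->ijk", *parts)


def ball(radius, shape, center):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


class TestGradientMap:
    def test_constant_field_is_zero(self):
        field = VectorField(np.full((8, 8, 8, 3), 3.7, dtype=np.float32))
        assert not gradient_map(field).any()

    def test_matches_brute_force_convolution(self, rng):
        field = VectorField(rng.standard_normal((10, 10, 10, 3)).astype(np.float32))
        got = gradient_map(field)
        responses = [
            ndimage.correlate(field.data[..., a].astype(np.float64),
                              sobel_kernel(a), mode="reflect")
            for a in range(3)
        ]
        expected = np.maximum(np.maximum(responses[0], responses[1]), responses[2])
        np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_peak_on_plane_between_touching_nuclei(self):
        # two slabs along x whose vectors point at their own centroids:
        # the x-component jumps negative -> positive at the interface
        labels = np.zeros((20, 8, 8), dtype=np.int32)
        labels[2:10] = 1
        labels[10:18] = 2
        field = generate_vector_field(LabelVolume(labels))
        g = gradient_map(field)
        peak_x = np.unravel_index(np.argmax(g), g.shape)[0]
        assert peak_x in (9, 10)

    def test_negative_inside_single_convex_nucleus(self):
        labels = ball(5, (16, 16, 16), (8, 8, 8)).astype(np.int32)
        field = generate_vector_field(LabelVolume(labels))
        g = gradient_map(field)
        interior = ball(3, (16, 16, 16), (8, 8, 8))
        assert (g[interior] < 0).all()


class TestBlobMap:
    def test_threshold_above_all_gradients_keeps_mask(self, rng):
        mask = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        g = rng.standard_normal((8, 8, 8))
        np.testing.assert_array_equal(blob_map(mask, g, g.max() + 1), mask)

    def test_threshold_below_all_gradients_empties(self, rng):
        mask = np.ones((8, 8, 8), dtype=np.uint8)
        g = rng.standard_normal((8, 8, 8))
        assert not blob_map(mask, g, g.min()).any()

    def test_carving_splits_touching_pair(self):
        labels = np.zeros((24, 10, 10), dtype=np.int32)
        labels[2:12, 2:8, 2:8] = 1
        labels[12:22, 2:8, 2:8] = 2
        mask = (labels > 0).astype(np.uint8)
        field = generate_vector_field(LabelVolume(labels))
        g = gradient_map(field)
        blob = blob_map(mask, g, 16.0)
        n_before = ndimage.label(mask, structure=np.ones((3, 3, 3)))[1]
        n_after = ndimage.label(blob, structure=np.ones((3, 3, 3)))[1]
        assert n_before == 1
        assert n_after == 2


class TestConditionalErosion:
    def test_small_component_unchanged(self):
        blob = np.zeros((10, 10, 10), dtype=np.uint8)
        blob[3:5, 3:5, 3:5] = 1  # 8 voxels, below both thresholds
        p = InstanceSegParams(t_c=100, t_f=20)
        out = conditional_erosion(blob, p)
        np.testing.assert_array_equal(out.data > 0, blob > 0)

    def test_ball_erosion_matches_oracle(self):
        # solid ball radius 5 has 515 voxels; erode with the coarse element
        # until below t_c = 200, then the fine element until below t_f = 40
        blob = ball(5, (16, 16, 16), (8, 8, 8))
        assert blob.sum() == 515
        p = InstanceSegParams(t_c=200, t_f=40)

        def oracle(mask, selem, thr):
            while mask.sum() >= thr:
                e = ndimage.binary_erosion(mask, structure=selem)
                if not e.any():
                    break
                mask = e
            return mask

        expected = oracle(oracle(blob.copy(), p.b_coarse, 200), p.b_fine, 40)
        out = conditional_erosion(blob.astype(np.uint8), p)
        assert out.labels().size == 1
        np.testing.assert_array_equal(out.data > 0, expected)
        assert 1 <= (out.data > 0).sum() < 200

    def test_dumbbell_yields_two_markers(self):
        blob = np.zeros((40, 16, 16), dtype=np.uint8)
        blob |= ball(6, blob.shape, (10, 8, 8)).astype(np.uint8)
        blob |= ball(6, blob.shape, (28, 8, 8)).astype(np.uint8)
        blob[9:30, 7:9, 7:9] = 1  # thin bridge
        p = InstanceSegParams(t_c=400, t_f=100)
        out = conditional_erosion(blob, p)
        assert out.labels().size >= 2


class TestWatershed:
    def test_single_marker_single_component(self):
        mask = ball(4, (12, 12, 12), (6, 6, 6))
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[6, 6, 6] = 1
        out = watershed_split(LabelVolume(markers), mask)
        np.testing.assert_array_equal(out.data > 0, mask)
        assert out.labels().size == 1

    def test_fused_spheres_split_near_own_seed(self):
        shape = (30, 14, 14)
        mask = ball(5, shape, (9, 7, 7)) | ball(5, shape, (19, 7, 7))
        markers = np.zeros(shape, dtype=np.int32)
        markers[9, 7, 7] = 1
        markers[19, 7, 7] = 2
        out = watershed_split(LabelVolume(markers), mask)
        assert out.labels().size == 2
        for k, seed in ((1, np.array([9, 7, 7])), (2, np.array([19, 7, 7]))):
            com = np.argwhere(out.data == k).mean(axis=0)
            other = np.array([19, 7, 7]) if k == 1 else np.array([9, 7, 7])
            assert np.linalg.norm(com - seed) < np.linalg.norm(com - other)

    def test_marker_free_component_rescued(self):
        shape = (20, 10, 10)
        mask = np.zeros(shape, dtype=bool)
        mask[2:6, 2:6, 2:6] = True       # has a marker
        mask[12:17, 2:7, 2:4] = True     # 50 voxels, no marker
        markers = np.zeros(shape, dtype=np.int32)
        markers[4, 4, 4] = 1
        out = watershed_split(LabelVolume(markers), mask)
        assert out.labels().size == 2
        rescued = out.data[12:17, 2:7, 2:4]
        assert np.unique(rescued).size == 1
        assert (out.data == rescued[0, 0, 0]).sum() == 50

    def test_empty_mask_is_empty_labeling(self):
        markers = np.zeros((6, 6, 6), dtype=np.int32)
        out = watershed_split(LabelVolume(markers), np.zeros((6, 6, 6), bool))
        assert not out.data.any()


class TestRemoveSmall:
    def test_below_threshold_removed(self):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data[0, 0, :19 // 10 + 2] = 1  # small
        out = remove_small(LabelVolume(data), 20)
        assert not out.data.any()

    def test_nineteen_voxels_removed_twenty_kept(self):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data[1, 1:20 // 5 + 1, :5] = 1  # exactly 20 voxels
        data[5, 5, :9] = 2  # 9 voxels (< 20)
        out = remove_small(LabelVolume(data), 20)
        assert set(np.unique(out.data)) == {0, 1}
        assert (out.data == 1).sum() == 20

    def test_zero_min_size_is_identity(self, small_labels):
        out = remove_small(small_labels, 0)
        np.testing.assert_array_equal(out.data, small_labels.data)

    def test_idempotent(self, small_labels):
        once = remove_small(small_labels, 20)
        twice = remove_small(once, 20)
        np.testing.assert_array_equal(once.data, twice.data)


class TestSegmentInstances:
    def test_empty_mask(self):
        field = VectorField(np.zeros((8, 8, 8, 3), dtype=np.float32))
        out = segment_instances(np.zeros((8, 8, 8), np.uint8), field)
        assert not out.data.any()

    def test_partition_within_mask(self, small_labels):
        field = generate_vector_field(small_labels)
        seg = segment_instances(small_labels.binary_mask(), field)
        assert not seg.data[small_labels.data == 0].any()

    def test_oracle_inputs_recover_instances(self, small_labels):
        field = generate_vector_field(small_labels)
        seg = segment_instances(small_labels.binary_mask(), field)
        assert seg.labels().size == small_labels.labels().size
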