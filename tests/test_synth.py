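import numpy as np
import pytest

from nucsplit3d import (
    DeformationField,
    EllipsoidParams,
    LabelVolume,
    SynthConfig,
    apply_deformation,
    make_deformation_field,
    place_nuclei,
    rasterize_ellipsoid,
    sample_ellipsoid,
)
from nucsplit3d.synth import _rotation_matrix


def brute_force_ellipsoid(p, shape):
    """Independent oracle: test the body-frame inequality at every voxel."""
    import itertools

    r = _rotation_matrix(p.angles)
    a = np.asarray(p.semi_axes)
    c = np.asarray(p.center)
    out = set()
    for x, y, z in itertools.product(*[range(s) for s in shape]):
        body = r.T @ (np.array([x, y, z], dtype=float) - c)
        if np.sum((body / a) ** 2) < 1.0:
            out.add((x, y, z))
    return out


class TestSampling:
    def test_degenerate_range_is_constant(self, rng):
        cfg = SynthConfig(shape=(16, 16, 16), a_min=5, a_max=5)
        p = sample_ellipsoid(cfg, rng, 1)
        assert p.semi_axes == (5.0, 5.0, 5.0)

    def test_fixed_seed_reproducible(self):
        cfg = SynthConfig(shape=(16, 16, 16), a_min=4, a_max=8)
        p1 = sample_ellipsoid(cfg, np.random.default_rng(3), 1)
        p2 = sample_ellipsoid(cfg, np.random.default_rng(3), 1)
        assert p1 == p2

    def test_semi_axis_mean_matches_uniform_law(self, rng):
        # 10^4 draws from U[4, 8]: mean within 3 standard errors of 6
        cfg = SynthConfig(shape=(16, 16, 16), a_min=4, a_max=8)
        draws = np.array([sample_ellipsoid(cfg, rng, 1).semi_axes[0]
                          for _ in range(10_000)])
        se = (8 - 4) / np.sqrt(12) / np.sqrt(draws.size)
        assert abs(draws.mean() - 6.0) < 3 * se


class TestRasterize:
    def test_sphere_matches_brute_force(self):
        p = EllipsoidParams((3, 3, 3), (0, 0, 0), (8, 8, 8), 1)
        vox = rasterize_ellipsoid(p, (16, 16, 16))
        assert set(map(tuple, vox)) == brute_force_ellipsoid(p, (16, 16, 16))

    def test_right_angle_rotation_permutes_axes(self):
        # rotating a=(3,6,3) by 90 deg about x maps the y semi-axis onto z:
        # identical voxel set to the axis-aligned a=(3,3,6) ellipsoid
        center = (12.2, 11.7, 12.3)
        rot = EllipsoidParams((3, 6, 3), (np.pi / 2, 0, 0), center, 1)
        ref = EllipsoidParams((3, 3, 6), (0, 0, 0), center, 1)
        vox_rot = set(map(tuple, rasterize_ellipsoid(rot, (25, 25, 25))))
        vox_ref = set(map(tuple, rasterize_ellipsoid(ref, (25, 25, 25))))
        assert vox_rot == vox_ref

    def test_corner_center_is_clipped_in_bounds(self):
        p = EllipsoidParams((4, 4, 4), (0.3, 0.2, 0.1), (0, 0, 0), 1)
        vox = rasterize_ellipsoid(p, (16, 16, 16))
        assert vox.shape[0] > 0
        assert vox.min() >= 0

    def test_volume_close_to_ellipsoid_formula(self, rng):
        for _ in range(5):
            a = tuple(rng.uniform(4, 8, 3))
            p = EllipsoidParams(a, tuple(rng.uniform(0, 2 * np.pi, 3)),
                                (24, 24, 24), 1)
            count = rasterize_ellipsoid(p, (48, 48, 48)).shape[0]
            expected = 4 / 3 * np.pi * np.prod(a)
            assert abs(count - expected) / expected < 0.10


class TestPlacement:
    def test_zero_nuclei_gives_empty_volume(self, rng):
        cfg = SynthConfig(shape=(16, 16, 16), n_nuclei=0)
        vol = place_nuclei(cfg, rng)
        assert vol.data.max() == 0

    def test_determinism(self):
        cfg = SynthConfig(shape=(32, 32, 32), n_nuclei=8, a_min=3, a_max=6,
                          t_ov=5)
        a = place_nuclei(cfg, np.random.default_rng(5))
        b = place_nuclei(cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a.data, b.data)

    def test_labels_consecutive(self, rng):
        cfg = SynthConfig(shape=(32, 32, 32), n_nuclei=8, a_min=3, a_max=6,
                          t_ov=5)
        vol = place_nuclei(cfg, rng)
        ids = vol.labels()
        np.testing.assert_array_equal(ids, np.arange(1, ids.size + 1))

    @pytest.mark.parametrize("t_ov", [0, 10])
    def test_overlap_budget_enforced(self, t_ov):
        # exhaustive pairwise check of the accepted rasterizations
        cfg = SynthConfig(shape=(32, 32, 32), n_nuclei=12, a_min=3, a_max=6,
                          t_ov=t_ov)
        vol, params = place_nuclei(cfg, np.random.default_rng(11),
                                   return_params=True)
        masks = [set(map(tuple, rasterize_ellipsoid(p, cfg.shape)))
                 for p in params]
        for i in range(len(masks)):
            for j in range(i):
                assert len(masks[i] & masks[j]) <= t_ov


class TestDeformation:
    def test_zero_sigma_identity(self, rng, small_labels):
        field = make_deformation_field(small_labels.shape, 4, 0.0, rng)
        assert not field.smooth.any()
        out = apply_deformation(small_labels, field)
        np.testing.assert_array_equal(out.data, small_labels.data)

    def test_spline_reproduces_constants(self):
        from nucsplit3d.synth import interpolate_coarse

        coarse = np.full((4, 4, 4, 3), 2.5)
        smooth = interpolate_coarse(coarse, (10, 12, 14))
        np.testing.assert_allclose(smooth, 2.5, atol=1e-9)

    def test_coarse_variance_matches_law(self):
        # pooled coarse entries across seeds: sample variance near sigma^2 = 1
        pool = []
        for seed in range(60):
            f = make_deformation_field((8, 8, 8), 4, 1.0,
                                       np.random.default_rng(seed))
            pool.append(f.coarse.ravel())
        pool = np.concatenate(pool)
        assert pool.size >= 10_000
        se = np.sqrt(2.0 / pool.size)  # var of sample variance of N(0,1)
        assert abs(pool.var() - 1.0) < 3 * se

    def test_uniform_integer_shift_translates(self, small_labels):
        shift = np.array([2, -3, 1])
        smooth = np.broadcast_to(shift.astype(float),
                                 small_labels.shape + (3,)).copy()
        field = DeformationField(coarse=np.zeros((4, 4, 4, 3)), smooth=smooth)
        out = apply_deformation(small_labels, field)
        # backward warp by -shift == forward translation by +shift
        expected = np.zeros_like(small_labels.data)
        src = small_labels.data[
            max(0, -shift[0]) : small_labels.shape[0] - max(0, shift[0]),
            max(0, -shift[1]) : small_labels.shape[1] - max(0, shift[1]),
            max(0, -shift[2]) : small_labels.shape[2] - max(0, shift[2]),
        ]
        expected[
            max(0, shift[0]) : small_labels.shape[0] - max(0, -shift[0]),
            max(0, shift[1]) : small_labels.shape[1] - max(0, -shift[1]),
            max(0, shift[2]) : small_labels.shape[2] - max(0, -shift[2]),
        ] = src
        np.testing.assert_array_equal(out.data, expected)

    def test_warp_cannot_invent_labels(self, rng, small_labels):
        field = make_deformation_field(small_labels.shape, 5, 3.0, rng)
        out = apply_deformation(small_labels, field)
        assert set(np.unique(out.data)) <= set(np.unique(small_labels.data))

    def test_displacement_grows_with_sigma(self):
        mags = []
        for sigma in (0.5, 1.0, 2.0, 4.0):
            f = make_deformation_field((16, 16, 16), 4, sigma,
                                       np.random.default_rng(42))
            mags.append(np.linalg.norm(f.smooth, axis=-1).max())
        assert mags == sorted(mags)
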