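import numpy as np
import pytest

from epreg import autodiff as ad
from epreg.transform import (affine_grid, aggregate_field, compose_grid,
                             field_to_voxels, identity_grid, resize_field,
                             upsample_grid, voxels_to_field, warp)

from conftest import brute_trilinear


class TestIdentityGrid:
    def test_corners_are_plus_minus_one(self):
        g = identity_grid((2, 2, 2))
        np.testing.assert_array_equal(np.sort(np.unique(g)), [-1.0, 1.0])
        assert g[:, 0, 0, 0].tolist() == [-1.0, -1.0, -1.0]
        assert g[:, 1, 1, 1].tolist() == [1.0, 1.0, 1.0]

    def test_warp_with_identity_is_identity(self, rng):
        vol = rng.random((5, 6, 7))
        np.testing.assert_allclose(warp(vol, identity_grid(vol.shape)), vol,
                                   atol=1e-12)


class TestAffineGrid:
    def test_identity_matrix_gives_identity_grid(self):
        m = np.concatenate([np.eye(3), np.zeros((3, 1))], axis=1)
        np.testing.assert_allclose(affine_grid(m, (4, 5, 6)),
                                   identity_grid((4, 5, 6)), atol=1e-12)

    def test_pure_translation_shifts_grid(self):
        t = np.array([0.1, -0.2, 0.3])
        m = np.concatenate([np.eye(3), t.reshape(3, 1)], axis=1)
        g = affine_grid(m, (4, 4, 4))
        np.testing.assert_allclose(
            g, identity_grid((4, 4, 4)) + t.reshape(3, 1, 1, 1), atol=1e-12)

    def test_central_scaling_halves_coordinates(self):
        m = np.concatenate([0.5 * np.eye(3), np.zeros((3, 1))], axis=1)
        g = affine_grid(m, (5, 5, 5))
        # per-voxel matrix multiply oracle
        ident = identity_grid((5, 5, 5))
        expected = np.einsum("ij,jdhw->idhw", 0.5 * np.eye(3), ident)
        np.testing.assert_allclose(g, expected, atol=1e-12)

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            affine_grid(np.eye(3), (4, 4, 4))


class TestWarp:
    def test_matches_brute_force_oracle(self, rng):
        vol = rng.random((8, 8, 8))
        grid = identity_grid((8, 8, 8)) + rng.uniform(-0.3, 0.3, (3, 8, 8, 8))
        np.testing.assert_allclose(warp(vol, grid),
                                   brute_trilinear(vol, grid), atol=1e-5)

    def test_one_voxel_shift_of_ramp(self):
        # ramp I = z shifted by exactly one voxel along z rises by 1 inside
        n = 8
        vol = np.broadcast_to(np.arange(n, dtype=float), (n, n, n)).copy()
        disp = np.zeros((3, n, n, n))
        disp[2] = 2.0 / (n - 1)  # +1 voxel in normalized coordinates
        warped = warp(vol, identity_grid((n, n, n)) + disp)
        np.testing.assert_allclose(warped[:, :, :-1], vol[:, :, :-1] + 1,
                                   atol=1e-9)

    def test_nodal_exactness(self, rng):
        vol = rng.random((5, 5, 5))
        g = identity_grid((5, 5, 5))
        np.testing.assert_allclose(warp(vol, g), vol, atol=1e-12)

    def test_linearity(self, rng):
        u, v = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        g = identity_grid((5, 5, 5)) + rng.uniform(-0.2, 0.2, (3, 5, 5, 5))
        np.testing.assert_allclose(warp(2 * u + 3 * v, g),
                                   2 * warp(u, g) + 3 * warp(v, g), atol=1e-10)

    def test_rejects_bad_vector_dim(self, rng):
        with pytest.raises(ValueError):
            warp(rng.random((4, 4, 4)), np.zeros((2, 4, 4, 4)))


class TestUpsampleCompose:
    def test_upsampled_identity_is_identity(self):
        up = upsample_grid(identity_grid((4, 4, 4)), 2)
        np.testing.assert_allclose(up, identity_grid((8, 8, 8)), atol=1e-12)

    def test_zero_field_stays_zero(self):
        np.testing.assert_array_equal(upsample_grid(np.zeros((3, 4, 4, 4)), 2),
                                      np.zeros((3, 8, 8, 8)))

    def test_linear_field_keeps_slope(self):
        # a field linear in normalized coords upsamples to the same function
        g = identity_grid((5, 6, 7))
        field = 0.3 * g + 0.1
        up = upsample_grid(field, 2)
        np.testing.assert_allclose(up, 0.3 * identity_grid((10, 12, 14)) + 0.1,
                                   atol=1e-12)

    def test_compose_with_zero_residual(self):
        g = identity_grid((4, 4, 4)) + 0.05
        np.testing.assert_allclose(compose_grid(g, np.zeros((3, 8, 8, 8))),
                                   upsample_grid(g, 2), atol=1e-12)

    def test_compose_constant_shift(self):
        g = compose_grid(identity_grid((4, 4, 4)),
                         np.full((3, 8, 8, 8), 0.25))
        np.testing.assert_allclose(g, identity_grid((8, 8, 8)) + 0.25,
                                   atol=1e-12)

    def test_two_successive_compositions_expand_additively(self, rng):
        phi_a = rng.uniform(-0.1, 0.1, (3, 8, 8, 8))
        phi_b = rng.uniform(-0.1, 0.1, (3, 16, 16, 16))
        g = compose_grid(compose_grid(identity_grid((4, 4, 4)), phi_a), phi_b)
        expected = (identity_grid((16, 16, 16))
                    + upsample_grid(phi_a, 2) + phi_b)
        np.testing.assert_allclose(g, expected, atol=1e-12)

    def test_compose_shape_mismatch(self):
        with pytest.raises(ValueError):
            compose_grid(identity_grid((4, 4, 4)), np.zeros((3, 6, 6, 6)))

    def test_resample_composition_mode(self, rng):
        # with zero residual both composition rules coincide; with a
        # constant residual the resampled coarse identity grid is the
        # shifted identity (clamped at the domain border)
        g = identity_grid((4, 4, 4))
        zero = np.zeros((3, 8, 8, 8))
        np.testing.assert_allclose(compose_grid(g, zero, mode="resample"),
                                   compose_grid(g, zero), atol=1e-12)
        shift = np.full((3, 8, 8, 8), 0.1)
        out = compose_grid(g, shift, mode="resample")
        inner = (slice(None), slice(None, -1), slice(None, -1), slice(None, -1))
        np.testing.assert_allclose(
            out[inner], (identity_grid((8, 8, 8)) + 0.1)[inner], atol=1e-7)
        with pytest.raises(ValueError):
            compose_grid(g, zero, mode="bogus")


class TestAggregate:
    def test_all_zero_levels_aggregate_to_zero(self):
        phis = {i: np.zeros((3,) + (16 // 2**i,) * 3) for i in range(1, 5)}
        np.testing.assert_array_equal(aggregate_field(phis, (16, 16, 16)), 0.0)

    def test_single_level_equals_its_upsampling(self, rng):
        phi1 = rng.uniform(-0.1, 0.1, (3, 8, 8, 8))
        phis = {1: phi1}
        phis.update({i: np.zeros((3,) + (16 // 2**i,) * 3) for i in (2, 3, 4)})
        np.testing.assert_allclose(aggregate_field(phis, (16, 16, 16)),
                                   upsample_grid(phi1, 2), atol=1e-12)

    def test_matches_independent_recomputation(self, rng):
        shape = (16, 16, 16)
        phis = {i: rng.uniform(-0.1, 0.1, (3,) + (16 // 2**i,) * 3)
                for i in range(1, 5)}
        agg = aggregate_field(phis, shape)
        expected = sum(
            np.stack([brute_trilinear(phis[i][c], identity_grid(shape))
                      for c in range(3)])
            for i in range(1, 5))
        np.testing.assert_allclose(agg, expected, atol=1e-10)


class TestUnitConversion:
    def test_round_trip(self, rng):
        f = rng.standard_normal((3, 6, 7, 8))
        np.testing.assert_allclose(voxels_to_field(field_to_voxels(f)), f,
                                   atol=1e-12)

    def test_one_voxel_displacement(self):
        d = np.zeros((3, 9, 9, 9))
        d[0] = 1.0  # one voxel along axis 0
        f = voxels_to_field(d)
        np.testing.assert_allclose(f[0], 2.0 / 8.0)


def test_resize_field_agrees_with_grid_sample_path(rng):
    f = rng.standard_normal((3, 6, 7, 8))
    target = (9, 5, 11)
    via_resize = resize_field(f, target)
    via_sample = ad.grid_sample(ad.Tensor(f),
                                ad.Tensor(identity_grid(target))).data
    np.testing.assert_allclose(via_resize, via_sample, atol=1e-12)
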