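import numpy as np
import pytest

from epreg import autodiff as ad
from epreg.losses import LossConfig, lncc_loss, smoothness_loss, total_loss
from epreg.transform import identity_grid

from conftest import brute_lncc


class TestLncc:
    def test_identical_nonconstant_pair_near_volume_size(self, rng):
        vol = rng.random((14, 14, 14))
        loss = lncc_loss(vol, vol, LossConfig(window=5))
        assert loss == pytest.approx(-vol.size, rel=0.02)

    def test_affine_intensity_invariance(self, rng):
        vol = rng.random((10, 10, 10))
        base = lncc_loss(vol, vol, LossConfig(window=3))
        scaled = lncc_loss(vol, 2.0 * vol + 0.3, LossConfig(window=3))
        assert scaled == pytest.approx(base, rel=1e-4)

    def test_matches_direct_summation_oracle(self, rng):
        f = rng.random((12, 12, 12))
        w = rng.random((12, 12, 12))
        loss = lncc_loss(f, w, LossConfig(window=3))
        assert loss == pytest.approx(brute_lncc(f, w, 3), abs=1e-4)

    def test_symmetry(self, rng):
        f, w = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        cfg = LossConfig(window=3)
        assert lncc_loss(f, w, cfg) == pytest.approx(lncc_loss(w, f, cfg),
                                                     rel=1e-10)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            lncc_loss(rng.random((4, 4, 4)), rng.random((5, 4, 4)))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(window=4)


class TestSmoothness:
    def test_constant_field_is_zero(self):
        assert smoothness_loss(np.full((3, 5, 5, 5), 0.7)) == 0.0

    def test_linear_field_counting_oracle(self):
        # single component linear along axis 2 with slope s: each forward
        # difference contributes s^2 at every interior difference site
        n = 6
        field = np.zeros((3, n, n, n))
        s = 0.25
        field[1] = s * np.arange(n)[None, None, :]
        sites = n * n * (n - 1)
        assert smoothness_loss(field) == pytest.approx(s**2 * sites, rel=1e-12)

    def test_quadratic_homogeneity(self, rng):
        f = rng.standard_normal((3, 6, 6, 6))
        assert smoothness_loss(2 * f) == pytest.approx(4 * smoothness_loss(f),
                                                       rel=1e-12)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            smoothness_loss(np.zeros((2, 4, 4, 4)))


class TestTotalLoss:
    def _identity_setup(self, rng, n=32):
        vol = rng.random((n, n, n))
        grids = {i: identity_grid((n // 2**i,) * 3) for i in range(1, 5)}
        agg = np.zeros((3, n, n, n))
        return vol, grids, agg

    def test_identity_cascade_on_identical_pair(self, rng):
        vol, grids, agg = self._identity_setup(rng)
        cfg = LossConfig(window=3)
        total, breakdown = total_loss(vol, vol, grids, agg, cfg)
        expected_sim = -sum((32 // 2**i)**3 for i in range(1, 5))
        assert breakdown["smooth"] == 0.0
        assert total.item() == pytest.approx(expected_sim, rel=0.02)

    def test_lambda_zero_drops_regularizer(self, rng):
        vol, grids, _ = self._identity_setup(rng)
        agg = rng.uniform(-0.05, 0.05, (3, 32, 32, 32))
        t0, b0 = total_loss(vol, vol, grids, agg, LossConfig(window=3, lam=0.0))
        assert b0["smooth"] == 0.0
        sims = sum(v for k, v in b0.items() if k.startswith("sim"))
        assert t0.item() == pytest.approx(sims, rel=1e-10)

    def test_breakdown_sums_to_total(self, rng):
        vol, grids, _ = self._identity_setup(rng)
        other = rng.random(vol.shape)
        agg = rng.uniform(-0.05, 0.05, (3, 32, 32, 32))
        total, b = total_loss(vol, other, grids, agg, LossConfig(window=3))
        parts = sum(v for k, v in b.items() if k != "total")
        assert b["total"] == pytest.approx(parts, rel=1e-9)
        assert total.item() == b["total"]

    def test_avgpool_downsampling_flag(self, rng):
        vol, grids, agg = self._identity_setup(rng)
        cfg = LossConfig(window=3, downsample="avgpool")
        total, b = total_loss(vol, vol, grids, agg, cfg)
        expected_sim = -sum((32 // 2**i)**3 for i in range(1, 5))
        assert total.item() == pytest.approx(expected_sim, rel=0.05)
        with pytest.raises(ValueError):
            LossConfig(downsample="nearest")

    def test_missing_level_rejected(self, rng):
        vol, grids, agg = self._identity_setup(rng)
        del grids[2]
        with pytest.raises(ValueError):
            total_loss(vol, vol, grids, agg)


def test_gradient_check_through_warp_and_loss(rng):
    """Autodiff gradient of the objective w.r.t. field entries matches
    central finite differences on a small instance."""
    n = 8
    fixed = rng.random((n, n, n))
    moving = rng.random((n, n, n))
    cfg = LossConfig(window=3, lam=10.0)
    phi = rng.uniform(-0.1, 0.1, (3, n, n, n))

    def objective(phi_arr, as_tensor=False):
        t = ad.Tensor(phi_arr, requires_grad=as_tensor)
        grid = ad.Tensor(identity_grid((n, n, n))) + t
        from epreg.transform import warp
        sim = lncc_loss(ad.Tensor(fixed), warp(ad.Tensor(moving), grid), cfg)
        smooth = smoothness_loss(t)
        return t, sim + smooth * cfg.lam

    t, loss = objective(phi, as_tensor=True)
    loss.backward()
    eps = 1e-5
    idx_list = [(0, 2, 3, 4), (1, 5, 1, 2), (2, 0, 0, 7), (1, 3, 3, 3)]
    for idx in idx_list:
        pp, pm = phi.copy(), phi.copy()
        pp[idx] += eps
        pm[idx] -= eps
        num = (objective(pp)[1].item() - objective(pm)[1].item()) / (2 * eps)
        denom = max(abs(num), abs(t.grad[idx]), 1e-8)
        assert abs(t.grad[idx] - num) / denom < 1e-3
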