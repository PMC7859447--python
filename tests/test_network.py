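import numpy as np
import pytest

from epreg.edge import make_dual_input
from epreg.network import EPRegNet, NetworkConfig
from epreg.transform import upsample_grid


@pytest.fixture(scope="module")
def small_net():
    return EPRegNet(NetworkConfig(enc_channels=(4, 8, 8, 16),
                                  head_channels=8, seed=0))


@pytest.fixture(scope="module")
def pair():
    rng = np.random.default_rng(3)
    from scipy import ndimage
    fixed = ndimage.gaussian_filter(rng.random((32, 32, 32)), 2.0)
    moving = ndimage.gaussian_filter(rng.random((32, 32, 32)), 2.0)
    for v in (fixed, moving):
        v -= v.min()
        v /= v.max()
    return fixed, moving


class TestEncoder:
    def test_pyramid_shapes_halve_four_times(self, small_net, pair):
        feats = small_net.encode(make_dual_input(pair[0]))
        for i in range(1, 5):
            assert feats[i].shape[1:] == (32 // 2**i,) * 3
        assert [feats[i].shape[0] for i in range(1, 5)] == [4, 8, 8, 16]

    def test_shared_weights_give_identical_pyramids(self, small_net, pair):
        dual = make_dual_input(pair[0])
        small_net.train_mode(False)
        f1 = small_net.encode(dual)
        f2 = small_net.encode(dual)
        small_net.train_mode(True)
        for i in range(1, 5):
            np.testing.assert_array_equal(f1[i].data, f2[i].data)

    def test_zero_input_is_finite(self, small_net):
        small_net.train_mode(False)
        feats = small_net.encode(np.zeros((2, 16, 16, 16), dtype=np.float32))
        small_net.train_mode(True)
        for f in feats.values():
            assert np.all(np.isfinite(f.data))

    def test_non_divisible_shape_rejected(self, small_net):
        with pytest.raises(ValueError):
            small_net.encode(np.zeros((2, 20, 16, 16)))


class TestHeads:
    def test_fresh_affine_head_outputs_identity(self, small_net, pair):
        result = small_net.forward(*pair)
        expected = np.concatenate([np.eye(3), np.zeros((3, 1))], axis=1)
        np.testing.assert_allclose(result.affine.data, expected, atol=1e-7)
        assert result.affine.data.size == 12

    def test_fresh_deformable_heads_output_zero(self, small_net, pair):
        result = small_net.forward(*pair)
        for i in (1, 2, 3):
            np.testing.assert_allclose(result.phis[i].data, 0.0, atol=1e-8)
            assert result.phis[i].shape[0] == 3


class TestForward:
    def test_identity_on_fresh_network(self, small_net, pair):
        fixed, _ = pair
        result = small_net.forward(fixed, fixed)
        np.testing.assert_allclose(result.warped.data, fixed, atol=1e-5)
        np.testing.assert_allclose(result.aggregate.data, 0.0, atol=1e-6)

    def test_grid_shapes(self, pair):
        net = EPRegNet(NetworkConfig(enc_channels=(4, 8, 8, 16),
                                     head_channels=8, seed=1))
        rng = np.random.default_rng(0)
        fixed = rng.random((64, 64, 64))
        moving = rng.random((64, 64, 64))
        result = net.forward(fixed, moving)
        for i in range(1, 5):
            assert result.grids[i].shape == (3,) + (64 // 2**i,) * 3

    def test_grid_composition_identity_holds(self, small_net, pair):
        result = small_net.forward(*pair)
        for i in (1, 2, 3):
            recomposed = (upsample_grid(result.grids[i + 1].data, 2)
                          + result.phis[i].data)
            np.testing.assert_allclose(result.grids[i].data, recomposed,
                                       atol=1e-6)

    def test_deterministic_across_runs(self, pair):
        outs = []
        for _ in range(2):
            net = EPRegNet(NetworkConfig(enc_channels=(4, 8, 8, 16),
                                         head_channels=8, seed=9))
            outs.append(net.forward(*pair))
        np.testing.assert_array_equal(outs[0].warped.data,
                                      outs[1].warped.data)
        np.testing.assert_array_equal(outs[0].grids[1].data,
                                      outs[1].grids[1].data)

    def test_shape_mismatch_rejected(self, small_net, rng):
        with pytest.raises(ValueError):
            small_net.forward(rng.random((32, 32, 32)),
                              rng.random((32, 32, 16)))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, pair):
        net = EPRegNet(NetworkConfig(enc_channels=(4, 8, 8, 16),
                                     head_channels=8, seed=4))
        rng = np.random.default_rng(0)
        for p in net.params():  # perturb away from init
            p.data = p.data + rng.standard_normal(p.data.shape).astype(
                p.data.dtype) * 0.01
        path = tmp_path / "ckpt.npz"
        net.save(path)
        net2 = EPRegNet.load(path)
        assert net2.config == net.config
        net.train_mode(False)
        net2.train_mode(False)
        np.testing.assert_array_equal(net.forward(*pair).warped.data,
                                      net2.forward(*pair).warped.data)

    def test_architecture_mismatch_detected(self, tmp_path):
        net = EPRegNet(NetworkConfig(enc_channels=(4, 8, 8, 16),
                                     head_channels=8, seed=0))
        path = tmp_path / "ckpt.npz"
        net.save(path)
        import json
        import numpy as np
        with np.load(path) as data:
            state = dict(data)
        cfg = NetworkConfig(enc_channels=(8, 16, 16, 32), head_channels=8)
        state["config_json"] = np.frombuffer(
            json.dumps(cfg.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **state)
        with pytest.raises(ValueError):
            EPRegNet.load(path)
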