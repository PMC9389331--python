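"""Backbone, attention blocks and heads: shapes, ranges, contracts."""

import numpy as np
import pytest

from tomatodet.network import (
    CBAM,
    ChannelAttention,
    CircleDetector,
    NetworkConfig,
    SpatialAttention,
    build_network,
    load_checkpoint,
    save_checkpoint,
)
from tomatodet.nn import Tensor


@pytest.fixture(scope="module")
def tiny_net():
    return build_network(NetworkConfig(preset="tiny", seed=42))


class TestChannelAttention:
    def test_shape_and_open_interval(self, rng):
        ca = ChannelAttention(8, reduction=4, rng=rng)
        out = ca(Tensor(rng.normal(size=(2, 8, 5, 5)).astype(np.float32)))
        assert out.shape == (2, 8, 1, 1)
        assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_identity_mlp_on_constant_input_gives_sigmoid_of_twice_value(self, rng):
        """With pass-through MLP weights and a constant plane per channel,
        avg and max descriptors coincide, so the gate is sigmoid(2v)."""
        ca = ChannelAttention(4, reduction=1, rng=rng)
        eye = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1)
        ca.fc1.weight.data = eye.copy()
        ca.fc2.weight.data = eye.copy()
        ca.fc1.bias.data[:] = 0
        ca.fc2.bias.data[:] = 0
        v = np.array([0.5, 1.0, 2.0, 3.0], dtype=np.float32)
        x = np.broadcast_to(v.reshape(1, 4, 1, 1), (1, 4, 6, 6)).copy()
        out = ca(Tensor(x))
        expected = 1.0 / (1.0 + np.exp(-2.0 * v))
        np.testing.assert_allclose(out.data.ravel(), expected, atol=1e-6)

    def test_channel_permutation_equivariance(self, rng):
        ca = ChannelAttention(6, reduction=2, rng=rng)
        x = rng.normal(size=(1, 6, 4, 4)).astype(np.float32)
        perm = np.array([3, 0, 5, 1, 4, 2])
        base = ca(Tensor(x)).data
        # permuting both the input channels and the MLP weights permutes Mc
        ca.fc1.weight.data = ca.fc1.weight.data[:, perm]
        ca.fc2.weight.data = ca.fc2.weight.data[perm]
        ca.fc2.bias.data = ca.fc2.bias.data[perm]
        out = ca(Tensor(x[:, perm])).data
        np.testing.assert_allclose(out, base[:, perm], atol=1e-6)


class TestSpatialAttention:
    def test_shape_and_range(self, rng):
        sa = SpatialAttention(7, rng=rng)
        out = sa(Tensor(rng.normal(size=(2, 8, 9, 9)).astype(np.float32)))
        assert out.shape == (2, 1, 9, 9)
        assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_constant_input_gives_constant_interior(self, rng):
        sa = SpatialAttention(3, rng=rng)
        x = np.full((1, 4, 10, 10), 1.7, dtype=np.float32)
        out = sa(Tensor(x)).data[0, 0]
        interior = out[1:-1, 1:-1]
        assert np.allclose(interior, interior[0, 0], atol=1e-6)

    def test_matches_hand_convolution_on_tiny_input(self, rng):
        sa = SpatialAttention(3, rng=rng)
        x = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        out = sa(Tensor(x)).data[0, 0]
        # single channel: mean map == max map == the input plane
        w = sa.conv.weight.data[0]
        b = sa.conv.bias.data[0]
        xp = np.pad(x[0, 0], 1)
        for yy in range(4):
            for xx in range(4):
                patch = xp[yy : yy + 3, xx : xx + 3]
                lin = float((patch * w[0]).sum() + (patch * w[1]).sum() + b)
                assert out[yy, xx] == pytest.approx(1 / (1 + np.exp(-lin)), abs=1e-5)


class TestCBAM:
    def test_gating_identity_with_saturated_gates(self, rng):
        cbam = CBAM(4, reduction=2, spatial_kernel=3, rng=rng)
        # huge positive biases saturate both sigmoids at ~1
        cbam.channel.fc2.bias.data[:] = 50.0
        cbam.spatial.conv.weight.data[:] = 0.0
        cbam.spatial.conv.bias.data[:] = 50.0
        x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        out = cbam(Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-4)

    def test_gates_shrink_nonnegative_input(self, rng):
        cbam = CBAM(4, reduction=2, spatial_kernel=3, rng=rng)
        x = rng.random((1, 4, 5, 5)).astype(np.float32)
        out = cbam(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)

    def test_composes_channel_then_spatial(self, rng):
        cbam = CBAM(3, reduction=1, spatial_kernel=3, rng=rng)
        x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        mc = cbam.channel(Tensor(x)).data
        fp = mc * x
        ms = cbam.spatial(Tensor(fp)).data
        np.testing.assert_allclose(cbam(Tensor(x)).data, ms * fp, atol=1e-6)


class TestDetectorForward:
    def test_output_shapes_and_heatmap_range(self, tiny_net, rng):
        x = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
        hm, off, size = tiny_net(Tensor(x))
        assert hm.shape == (2, 1, 16, 16)
        assert off.shape == (2, 2, 16, 16)
        assert size.shape == (2, 1, 16, 16)
        assert np.all(hm.data > 0) and np.all(hm.data < 1)

    def test_initial_foreground_probability_near_one_percent(self, tiny_net, rng):
        x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32) * 0.1
        hm, _, _ = tiny_net(Tensor(x))
        assert 0.001 < float(np.median(hm.data)) < 0.1

    def test_indivisible_input_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net(Tensor(np.zeros((1, 3, 30, 64), np.float32)))

    def test_batch_independence_in_eval_mode(self, rng):
        net = build_network(NetworkConfig(preset="tiny", seed=5))
        net.eval()
        x = rng.normal(size=(3, 3, 32, 32)).astype(np.float32)
        hm_all, _, _ = net(Tensor(x))
        hm_one, _, _ = net(Tensor(x[1:2]))
        np.testing.assert_allclose(hm_all.data[1], hm_one.data[0], atol=1e-6)

    def test_forward_deterministic(self, tiny_net, rng):
        net = tiny_net
        net.eval()
        x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
        a = net(Tensor(x))[0].data
        b = net(Tensor(x))[0].data
        assert np.array_equal(a, b)

    def test_tiny_parameter_budget(self, tiny_net):
        assert tiny_net.num_parameters() < 500_000

    def test_cbam_off_and_box_head_variants_run(self, rng):
        for kwargs in ({"use_cbam": False}, {"head_type": "box"}):
            net = build_network(NetworkConfig(preset="tiny", seed=2, **kwargs))
            hm, off, size = net(Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32)))
            assert hm.shape == (1, 1, 8, 8)
            if kwargs.get("head_type") == "box":
                assert size.shape == (1, 2, 8, 8)

    def test_dla34_preset_constructs_and_runs(self, rng):
        net = build_network(NetworkConfig(preset="dla34_cbam", seed=1))
        hm, off, size = net(Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32)))
        assert hm.shape == (1, 1, 16, 16)


def test_checkpoint_round_trip(tmp_path, rng):
    net = build_network(NetworkConfig(preset="tiny", seed=8))
    net.eval()
    x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
    before = net(Tensor(x))[0].data
    save_checkpoint(tmp_path / "ckpt.npz", net)
    restored = load_checkpoint(tmp_path / "ckpt.npz")
    after = restored(Tensor(x))[0].data
    assert restored.cfg == net.cfg
    np.testing.assert_allclose(after, before, atol=0)
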