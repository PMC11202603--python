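"""BGN layer algebra, encoder wiring, prediction contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonoac.autodiff import Tensor
from sonoac.errors import InputError
from sonoac.network import (
    ACRegressionNet,
    NetworkConfig,
    bgn_denormalize,
    reduced_network_config,
    slice_moments,
)

TINY = NetworkConfig(
    input_shape=(5, 8, 32), bmode_shape=(16, 16), encoder_widths=(4, 6),
    bgn_conv_channels=4, bgn_fc_hidden=8, trunk_widths=(4, 6), head_hidden=8,
    seed=0,
)


def random_inputs(rng, batch=3, cfg=TINY):
    env = rng.standard_normal((batch,) + cfg.input_shape)
    bm = rng.random((batch, 1) + cfg.bmode_shape)
    return env, bm


class TestBGNAlgebra:
    def test_identity_case(self, rng):
        """gamma=sigma, beta=mu reproduces the input exactly."""
        x = rng.standard_normal((2, 6, 5)) * 3 + 1
        mu, sigma = slice_moments(Tensor(x))
        out = bgn_denormalize(x, sigma.data, mu.data)
        assert np.allclose(out.data, x, atol=1e-5)

    def test_moment_case(self, rng):
        """Slice mean becomes beta, slice sd becomes |gamma|."""
        x = rng.standard_normal((2, 50, 7)) * 2
        gamma = rng.standard_normal((2, 1, 7))
        beta = rng.standard_normal((2, 1, 7))
        out = bgn_denormalize(x, gamma, beta).data
        assert np.allclose(out.mean(axis=1), beta[:, 0], atol=1e-5)
        assert np.allclose(out.std(axis=1), np.abs(gamma[:, 0]), rtol=1e-4, atol=1e-6)

    def test_hand_example(self):
        """x=[1,2,3], gamma=2, beta=1 with population sd."""
        out = bgn_denormalize(np.array([[[1.0], [2.0], [3.0]]]),
                              np.array(2.0), np.array(1.0), eps=0.0)
        expected = np.array([-1.4494897, 1.0, 3.4494897])
        assert np.allclose(out.data[0, :, 0], expected, atol=1e-5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_affine_moment_property(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal((1, 20, 4)) * r.uniform(0.5, 4.0)
        g = r.uniform(-3, 3, size=(1, 1, 4))
        b = r.uniform(-3, 3, size=(1, 1, 4))
        out = bgn_denormalize(x, g, b).data
        assert np.allclose(out.mean(axis=1), b[:, 0], atol=1e-6)
        assert np.allclose(out.std(axis=1), np.abs(g[:, 0]), rtol=1e-3, atol=1e-6)

    def test_low_variance_stabilized(self):
        x = np.full((1, 4, 2), 5.0)  # zero-variance slices
        out = bgn_denormalize(x, np.array(1.0), np.array(0.0))
        assert np.all(np.isfinite(out.data))


class TestEncoder:
    def test_independent_angle_paths(self, rng):
        net = ACRegressionNet(TINY)
        env, _ = random_inputs(rng, batch=2)
        env[:] = env[:, :1]  # five identical frames
        fused = net.encode(Tensor(env)).data
        c = TINY.encoder_widths[-1]
        per_angle = [fused[:, i * c:(i + 1) * c] for i in range(5)]
        for i in range(1, 5):
            assert not np.allclose(per_angle[0], per_angle[i])

    def test_channel_concatenation_arithmetic(self, rng):
        net = ACRegressionNet(TINY)
        env, _ = random_inputs(rng)
        assert net.encode(Tensor(env)).shape[1] == 5 * TINY.encoder_widths[-1]

    def test_wrong_frame_count_rejected(self, rng):
        net = ACRegressionNet(TINY)
        with pytest.raises(InputError):
            net.encode(Tensor(rng.standard_normal((2, 4, 8, 32))))

    def test_deterministic_features(self, rng):
        env, _ = random_inputs(rng)
        f1 = ACRegressionNet(TINY).encode(Tensor(env)).data
        f2 = ACRegressionNet(TINY).encode(Tensor(env)).data
        assert np.array_equal(f1, f2)


class TestPredict:
    def test_batch_of_scalars_in_range(self, rng):
        net = ACRegressionNet(TINY)
        env, bm = random_inputs(rng, batch=4)
        out = net.predict(env, bm)
        assert out.shape == (4,)
        assert np.all(np.isfinite(out))
        lo, hi = TINY.ac_range
        assert np.all((out >= lo) & (out <= hi))

    def test_batch_order_equivariance(self, rng):
        net = ACRegressionNet(TINY)
        env, bm = random_inputs(rng, batch=5)
        out = net.predict(env, bm)
        perm = np.array([3, 0, 4, 1, 2])
        assert np.allclose(net.predict(env[perm], bm[perm]), out[perm], atol=1e-12)

    def test_bit_stable_across_calls(self, rng):
        net = ACRegressionNet(TINY)
        env, bm = random_inputs(rng)
        assert np.array_equal(net.predict(env, bm), net.predict(env, bm))

    def test_shape_mismatch_rejected(self, rng):
        net = ACRegressionNet(TINY)
        with pytest.raises(InputError):
            net.predict(rng.standard_normal((2, 5, 8, 16)), rng.random((2, 1, 16, 16)))


def test_gradient_flows_to_both_branches(rng):
    """Loss gradients reach the envelope input and the B-mode input."""
    net = ACRegressionNet(TINY)
    # the gamma/beta output layers start at zero (identity modulation), which
    # blocks the input-gradient path; perturb them to test the wiring itself
    net.gamma_fcs[-1].w.data[:] = 0.01
    net.beta_fcs[-1].w.data[:] = 0.01
    env, bm = random_inputs(rng, batch=2)
    env_t = Tensor(env, requires_grad=True)
    bm_t = Tensor(bm, requires_grad=True)
    net.training = True
    loss = (net.forward(env_t, bm_t) - Tensor(np.array([0.3, 0.7]))).abs().mean()
    loss.backward()
    assert env_t.grad is not None and np.abs(env_t.grad).max() > 0
    assert bm_t.grad is not None and np.abs(bm_t.grad).max() > 0


def test_ablation_weight_count_comparable():
    """No-B-mode variant differs only by the BGN branch parameters."""
    full = ACRegressionNet(TINY)
    abl = ACRegressionNet(dataclasses.replace(TINY, use_bmode=False))
    branch = sum(p.data.size for conv in full.bgn_convs for p in conv.params())
    branch += sum(p.data.size for stack in (full.gamma_fcs, full.beta_fcs)
                  for fc in stack for p in fc.params())
    assert full.n_parameters() - branch == abl.n_parameters()


def test_ablation_ignores_bmode(rng):
    net = ACRegressionNet(dataclasses.replace(TINY, use_bmode=False))
    env, bm = random_inputs(rng)
    assert np.array_equal(net.predict(env, None), net.predict(env, bm * 0))


def test_default_bgn_depths():
    cfg = NetworkConfig()
    assert cfg.bgn_conv_layers == 4 and cfg.bgn_fc_layers == 4
    net = ACRegressionNet(reduced_network_config())
    assert len(net.bgn_convs) == 4
    assert len(net.gamma_fcs) == 4 and len(net.beta_fcs) == 4


def test_vector_gamma_mode(rng):
    cfg = dataclasses.replace(TINY, gamma_vector_mode=True)
    net = ACRegressionNet(cfg)
    env, bm = random_inputs(rng, batch=2, cfg=cfg)
    gamma, beta = net.bgn_params(Tensor(bm))
    assert gamma.shape == (2, net.c_fused, net.t_feat)
    out = net.predict(env, bm)
    assert out.shape == (2,) and np.all(np.isfinite(out))


def test_checkpoint_roundtrip(rng, tmp_path):
    from sonoac.network import load_checkpoint, save_checkpoint

    net = ACRegressionNet(TINY)
    env, bm = random_inputs(rng)
    before = net.predict(env, bm)
    path = tmp_path / "model.npz"
    save_checkpoint(net, path, seed=3, config_hash="abc")
    back, meta = load_checkpoint(path)
    assert meta == {"seed": 3, "config_hash": "abc"}
    assert np.array_equal(back.predict(env, bm), before)


def test_state_dict_roundtrip(rng):
    net = ACRegressionNet(TINY)
    env, bm = random_inputs(rng)
    before = net.predict(env, bm)
    clone = net.clone()
    for p in net.params():
        p.data += 0.1
    assert np.array_equal(clone.predict(env, bm), before)
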