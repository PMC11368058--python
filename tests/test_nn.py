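"""The reverse-mode engine: forward agreement with reference
implementations and gradient checks against finite differences."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from pseudohealthy.nn import Adam, Conv2d, GatedConv2d, Tensor, concat, conv2d, lr_at_epoch


def finite_diff(f, param, eps=1e-2):
    """Central-difference gradient of scalar f() w.r.t. param.data."""
    g = np.zeros_like(param.data)
    flat = param.data.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


class TestConv:
    def test_forward_matches_scipy_correlate(self, rng):
        x = rng.normal(size=(1, 1, 9, 9)).astype(np.float32)
        w = rng.normal(size=(1, 1, 3, 3)).astype(np.float32)
        out = conv2d(Tensor(x), Tensor(w), None, padding=1).data[0, 0]
        ref = ndi.correlate(x[0, 0], w[0, 0], mode="constant")
        np.testing.assert_allclose(out, ref, atol=1e-5)

    @pytest.mark.parametrize("stride,pad,dil", [(1, 1, 1), (2, 1, 1), (1, 2, 2)])
    def test_output_size_follows_conv_arithmetic(self, stride, pad, dil, rng):
        # closed form: floor((H + 2p - d(k-1) - 1)/s) + 1
        h, k = 16, 3
        expected = (h + 2 * pad - dil * (k - 1) - 1) // stride + 1
        x = Tensor(rng.normal(size=(1, 2, h, h)).astype(np.float32))
        w = Tensor(rng.normal(size=(4, 2, k, k)).astype(np.float32))
        out = conv2d(x, w, None, stride=stride, padding=pad, dilation=dil)
        assert out.shape[2:] == (expected, expected)

    def test_gradients_match_finite_differences(self, rng):
        x = Tensor(rng.normal(size=(2, 2, 6, 6)).astype(np.float32), requires_grad=True)
        w = Tensor((rng.normal(size=(3, 2, 3, 3)) * 0.5).astype(np.float32), requires_grad=True)
        b = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
        t = rng.normal(size=(2, 3, 3, 3)).astype(np.float32)

        def loss():
            out = conv2d(x, w, b, stride=2, padding=1)
            return float(((out - Tensor(t)) * (out - Tensor(t))).mean().data)

        out = conv2d(x, w, b, stride=2, padding=1)
        ((out - Tensor(t)) * (out - Tensor(t))).mean().backward()
        for p in (w, b, x):
            fd = finite_diff(loss, p)
            np.testing.assert_allclose(p.grad, fd, atol=5e-3)
            p.grad = None

    def test_elementwise_and_reduction_gradients(self, rng):
        z = Tensor(rng.normal(size=(4, 5)).astype(np.float32), requires_grad=True)

        def loss():
            return float((Tensor(z.data).tanh().abs().mean()).data)

        z.tanh().abs().mean().backward()
        zg = z.grad

        g_fd = np.zeros_like(z.data)
        eps = 1e-2
        for i in np.ndindex(z.data.shape):
            orig = z.data[i]
            z.data[i] = orig + eps
            hi = loss()
            z.data[i] = orig - eps
            lo = loss()
            z.data[i] = orig
            g_fd[i] = (hi - lo) / (2 * eps)
        np.testing.assert_allclose(zg, g_fd, atol=2e-3)

    def test_bce_with_logits_gradient(self, rng):
        z = Tensor(rng.normal(size=(8,)).astype(np.float32), requires_grad=True)
        y = (rng.random(8) > 0.5).astype(np.float32)
        z.bce_with_logits(y).backward()
        s = 1 / (1 + np.exp(-z.data))
        np.testing.assert_allclose(z.grad, (s - y) / 8, atol=1e-6)


class TestOps:
    def test_upsample2_and_avgpool2_are_adjoint_up_to_scale(self, rng):
        # <up(x), y> = <x, 4 * avgpool(y)>
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        y = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        up = Tensor(x).upsample2().data
        pool = Tensor(y).avg_pool2().data
        assert np.vdot(up, y) == pytest.approx(4 * np.vdot(x, pool), rel=1e-4)

    def test_apply_patch_matrix_matches_einsum(self, rng):
        x = rng.normal(size=(2, 5, 7)).astype(np.float32)
        m = rng.normal(size=(5, 5)).astype(np.float32)
        out = Tensor(x).apply_patch_matrix(m).data
        np.testing.assert_allclose(out, np.einsum("pq,nqd->npd", m, x), atol=1e-5)

    def test_flip_w_involution_and_grad(self, rng):
        x = Tensor(rng.normal(size=(1, 1, 3, 4)).astype(np.float32), requires_grad=True)
        out = x.flip_w().flip_w()
        np.testing.assert_array_equal(out.data, x.data)
        (out * Tensor(np.ones_like(x.data))).sum().backward()
        np.testing.assert_array_equal(x.grad, np.ones_like(x.data))

    def test_concat_gradient_splits(self, rng):
        a = Tensor(rng.normal(size=(1, 2, 2, 2)).astype(np.float32), requires_grad=True)
        b = Tensor(rng.normal(size=(1, 3, 2, 2)).astype(np.float32), requires_grad=True)
        (concat([a, b]) * 2.0).sum().backward()
        assert np.all(a.grad == 2.0) and np.all(b.grad == 2.0)
        assert a.grad.shape == a.data.shape and b.grad.shape == b.data.shape


class TestLayers:
    def test_symmetric_conv_weight_is_width_symmetric(self, rng):
        layer = Conv2d(2, 3, 3, rng=rng, sym="width")
        w = layer.effective_weight().data
        np.testing.assert_allclose(w, w[..., ::-1], atol=1e-7)

    def test_gated_conv_gate_saturation(self, rng):
        layer = GatedConv2d(1, 2, 3, rng=rng)
        x = Tensor(rng.normal(size=(1, 1, 8, 8)).astype(np.float32))
        layer.gate.b.data[:] = 10.0  # gate ~ 1 -> plain convolution
        plain = layer.feat(x).data
        np.testing.assert_allclose(layer(x).data, plain, atol=1e-3)
        layer.gate.b.data[:] = -10.0  # gate ~ 0 -> output ~ 0
        assert np.abs(layer(x).data).max() < 1e-3

    def test_adam_zero_lr_keeps_parameters(self, rng):
        layer = Conv2d(1, 1, 3, rng=rng)
        before = layer.w.data.copy()
        opt = Adam(layer.parameters(), lr=0.0)
        out = layer(Tensor(rng.normal(size=(1, 1, 6, 6)).astype(np.float32)))
        out.mean().backward()
        opt.step()
        np.testing.assert_array_equal(layer.w.data, before)


def test_lr_schedule_halves_every_five_epochs():
    assert lr_at_epoch(0.001, 0) == pytest.approx(0.001)
    assert lr_at_epoch(0.001, 5) == pytest.approx(0.0005)
    assert lr_at_epoch(0.001, 10) == pytest.approx(0.00025)
    assert lr_at_epoch(0.001, 4) == pytest.approx(0.001)
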