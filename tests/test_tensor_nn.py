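"""Gradient and contract checks for the autodiff engine and layers.

Analytic gradients are verified against central finite differences; the
convolution forward pass is verified against an explicit sliding-window
loop oracle.
"""

import numpy as np
import pytest

from segresdeit.nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    LayerNorm,
    Linear,
    MultiheadSelfAttention,
    conv2d,
    max_pool_with_indices,
    max_unpool,
)
from segresdeit.tensor import Tensor, concat, softmax


def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f(x)
        x[i] -= 2 * eps
        fm = f(x)
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "expr",
    [
        lambda t: (t * t + 2.0 * t).sum(),
        lambda t: (t.sigmoid() * t.tanh()).sum(),
        lambda t: t.gelu().sum(),
        lambda t: (t.exp() / (1.0 + t.exp())).log().sum() * -1.0,
        lambda t: softmax(t, axis=-1).sum(axis=0).mean(),
        lambda t: (t.reshape(2, 6).transpose(1, 0) ** 2).mean(),
        lambda t: t.clip(-0.5, 0.5).sum(),
        lambda t: t[1:, :2].sum(),
    ],
)
def test_elementwise_and_shape_gradients(expr, rng):
    x0 = rng.normal(size=(3, 4))
    xt = Tensor(x0.copy(), requires_grad=True)
    expr(xt).backward()
    num = numerical_grad(lambda xd: expr(Tensor(xd)).data.sum(), x0.copy())
    assert np.allclose(xt.grad, num, atol=1e-6)


def test_matmul_gradients_batched(rng):
    a0 = rng.normal(size=(2, 3, 4))
    b0 = rng.normal(size=(4, 5))
    at = Tensor(a0.copy(), requires_grad=True)
    bt = Tensor(b0.copy(), requires_grad=True)
    ((at @ bt) ** 2).sum().backward()
    na = numerical_grad(lambda x: ((Tensor(x) @ Tensor(b0)).data ** 2).sum(), a0.copy())
    nb = numerical_grad(lambda x: ((Tensor(a0) @ Tensor(x)).data ** 2).sum(), b0.copy())
    assert np.allclose(at.grad, na, atol=1e-5)
    assert np.allclose(bt.grad, nb, atol=1e-5)


def test_concat_gradient(rng):
    a0, b0 = rng.normal(size=(2, 3)), rng.normal(size=(2, 2))
    at, bt = Tensor(a0.copy(), requires_grad=True), Tensor(b0.copy(), requires_grad=True)
    (concat([at, bt], axis=1) ** 2).sum().backward()
    assert np.allclose(at.grad, 2 * a0)
    assert np.allclose(bt.grad, 2 * b0)


def test_reused_node_accumulates_gradient():
    x = Tensor(np.array([3.0]), requires_grad=True)
    y = x * x + x  # dy/dx = 2x + 1 = 7
    y.backward()
    assert np.allclose(x.grad, [7.0])


def test_conv_forward_matches_window_loop_oracle(rng):
    x = rng.normal(size=(2, 3, 5, 5))
    w = rng.normal(size=(4, 3, 3, 3))
    b = rng.normal(size=4)
    y = conv2d(Tensor(x), Tensor(w), Tensor(b), pad=1).data
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    ref = np.zeros_like(y)
    for n in range(2):
        for o in range(4):
            for i in range(5):
                for j in range(5):
                    ref[n, o, i, j] = (xp[n, :, i:i + 3, j:j + 3] * w[o]).sum() + b[o]
    assert np.allclose(y, ref)


def test_conv_gradients(rng):
    x0 = rng.normal(size=(1, 2, 4, 4))
    w0 = rng.normal(size=(3, 2, 3, 3))
    b0 = rng.normal(size=3)
    xt = Tensor(x0.copy(), requires_grad=True)
    wt = Tensor(w0.copy(), requires_grad=True)
    bt = Tensor(b0.copy(), requires_grad=True)
    (conv2d(xt, wt, bt, pad=1) ** 2).sum().backward()
    nx = numerical_grad(
        lambda v: (conv2d(Tensor(v), Tensor(w0), Tensor(b0), 1).data ** 2).sum(),
        x0.copy(), 1e-5)
    nw = numerical_grad(
        lambda v: (conv2d(Tensor(x0), Tensor(v), Tensor(b0), 1).data ** 2).sum(),
        w0.copy(), 1e-5)
    assert np.allclose(xt.grad, nx, atol=1e-5)
    assert np.allclose(wt.grad, nw, atol=1e-5)
    assert np.allclose(bt.grad, numerical_grad(
        lambda v: (conv2d(Tensor(x0), Tensor(w0), Tensor(v), 1).data ** 2).sum(),
        b0.copy(), 1e-5), atol=1e-5)


def test_conv_channel_mismatch_raises(rng):
    with pytest.raises(ValueError, match="channel"):
        conv2d(Tensor(rng.normal(size=(1, 3, 4, 4))),
               Tensor(rng.normal(size=(2, 4, 3, 3))), None, pad=1)


def test_batchnorm_train_gradients(rng):
    bn = BatchNorm2d(3)
    x0 = rng.normal(size=(2, 3, 4, 4))
    xt = Tensor(x0.copy(), requires_grad=True)
    (bn(xt) ** 2).sum().backward()

    def f(v):
        bn2 = BatchNorm2d(3)
        bn2.gamma.data = bn.gamma.data
        bn2.beta.data = bn.beta.data
        return (bn2(Tensor(v)).data ** 2).sum()

    assert np.allclose(xt.grad, numerical_grad(f, x0.copy(), 1e-5), atol=1e-4)


def test_batchnorm_eval_uses_running_stats(rng):
    bn = BatchNorm2d(2)
    for _ in range(10):
        bn(Tensor(rng.normal(1.5, 2.0, size=(4, 2, 3, 3))))
    bn.eval()
    x = rng.normal(size=(1, 2, 3, 3))
    out1 = bn(Tensor(x)).data
    out2 = bn(Tensor(x)).data  # eval forward must not mutate statistics
    assert np.array_equal(out1, out2)


def test_layernorm_gradient(rng):
    ln = LayerNorm(5)
    x0 = rng.normal(size=(2, 3, 5))
    xt = Tensor(x0.copy(), requires_grad=True)
    (ln(xt) ** 2).sum().backward()

    def f(v):
        ln2 = LayerNorm(5)
        return (ln2(Tensor(v)).data ** 2).sum()

    assert np.allclose(xt.grad, numerical_grad(f, x0.copy(), 1e-5), atol=1e-4)


def test_attention_gradient_flows(rng):
    att = MultiheadSelfAttention(8, 2, rng)
    x = Tensor(rng.normal(size=(2, 5, 8)), requires_grad=True)
    (att(x) ** 2).sum().backward()
    assert x.grad is not None and np.abs(x.grad).max() > 0
    for p in att.parameters():
        assert p.grad is not None


class TestPooling:
    def test_single_window(self):
        x = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]])[None, None])
        pooled, idx = max_pool_with_indices(x)
        assert pooled.data.item() == 4.0
        assert idx.item() == 3  # position of 4 in row-major window scan

    def test_constant_input_tie_break_first_position(self):
        x = Tensor(np.ones((1, 1, 4, 4)))
        pooled, idx = max_pool_with_indices(x)
        assert np.all(pooled.data == 1.0)
        assert np.all(idx == 0)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError, match="even"):
            max_pool_with_indices(Tensor(np.zeros((1, 1, 3, 4))))

    def test_unpool_places_value_at_index(self):
        x = Tensor(np.array([[[[4.0]]]]))
        out = max_unpool(x, np.array([[[[3]]]]), (2, 2))
        assert np.array_equal(out.data[0, 0], [[0, 0], [0, 4]])

    def test_unpool_zero_tensor(self):
        out = max_unpool(Tensor(np.zeros((1, 2, 2, 2))),
                         np.zeros((1, 2, 2, 2), int), (4, 4))
        assert out.shape == (1, 2, 4, 4) and not out.data.any()

    def test_unpool_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            max_unpool(Tensor(np.ones((1, 1, 1, 1))), np.array([[[[4]]]]), (2, 2))

    def test_unpool_restores_values_at_argmax_positions(self, rng):
        x = rng.normal(size=(1, 1, 8, 8))
        pooled, idx = max_pool_with_indices(Tensor(x))
        up = max_unpool(pooled, idx, (8, 8)).data[0, 0]
        # brute-force window scan
        for i in range(4):
            for j in range(4):
                win = x[0, 0, 2 * i:2 * i + 2, 2 * j:2 * j + 2]
                uwin = up[2 * i:2 * i + 2, 2 * j:2 * j + 2]
                k = np.unravel_index(np.argmax(win), (2, 2))
                assert uwin[k] == win.max()
                assert (uwin != 0).sum() <= 1

    def test_pool_unpool_duality_mass_preserved(self, rng):
        x = Tensor(rng.random((2, 3, 8, 8)))
        pooled, idx = max_pool_with_indices(x)
        up = max_unpool(pooled, idx, (8, 8))
        assert np.isclose(up.data.sum(), pooled.data.sum())

    def test_pool_unpool_pool_idempotent_on_nonnegative_maps(self, rng):
        # post-ReLU activations are non-negative, the operative domain
        x = Tensor(rng.random((2, 2, 8, 8)))
        pooled, idx = max_pool_with_indices(x)
        up = max_unpool(pooled, idx, (8, 8))
        pooled2, _ = max_pool_with_indices(up)
        assert np.allclose(pooled2.data, pooled.data)

    def test_pool_gradient(self, rng):
        x0 = rng.normal(size=(1, 1, 4, 4))
        xt = Tensor(x0.copy(), requires_grad=True)
        pooled, _ = max_pool_with_indices(xt)
        (pooled ** 2).sum().backward()
        num = numerical_grad(
            lambda v: (max_pool_with_indices(Tensor(v))[0].data ** 2).sum(),
            x0.copy(), 1e-5)
        assert np.allclose(xt.grad, num, atol=1e-5)


def test_adam_reduces_quadratic_loss(rng):
    w = Tensor(rng.normal(size=(5,)), requires_grad=True)
    opt = Adam([w], lr=0.1)
    first = (w ** 2).sum().item()
    for _ in range(50):
        opt.zero_grad()
        loss = (w ** 2).sum()
        loss.backward()
        opt.step()
    assert (w ** 2).sum().item() < 1e-2 * max(first, 1.0)


def test_linear_and_conv_seeded_init_reproducible():
    a = Conv2d(3, 4, 3, np.random.default_rng(9))
    b = Conv2d(3, 4, 3, np.random.default_rng(9))
    assert np.array_equal(a.weight.data, b.weight.data)
    la = Linear(6, 2, np.random.default_rng(9))
    lb = Linear(6, 2, np.random.default_rng(9))
    assert np.array_equal(la.weight.data, lb.weight.data)
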