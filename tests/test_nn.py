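"""Engine correctness: every analytic gradient agrees with finite differences.

The whole model's validity rests on these checks, so they cover each layer
kind (dense, conv stride 1/2, batch norm train/eval, pooling, attention-style
reductions) and the fused three-group kernels against their sequential
equivalents.
"""

import numpy as np
import pytest

from dpanet.nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Linear,
    MaxPool2d,
    Module,
    Tensor,
    concat,
    cross_entropy_from_probs,
    global_avg_pool,
    softmax,
    stack_mean,
)
from dpanet.nn.fused import (
    fused_batchnorm,
    fused_conv,
    fused_linear,
    stack_group,
    unstack_group,
)
from dpanet.nn.layers import AvgPool2d


@pytest.fixture(autouse=True)
def float64_engine(monkeypatch):
    """Gradient checks need double precision to beat finite-difference noise."""
    from dpanet.nn import autograd

    monkeypatch.setattr(autograd, "DTYPE", np.float64)
    yield


def numgrad(f, arr, h=1e-5):
    """Central-difference gradient of scalar f wrt an array."""
    g = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + h
        fp = f()
        arr[i] = old - h
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * h)
    return g


def check_param_grads(build_loss, params, rtol=1e-5, atol=1e-7):
    """Analytic vs numeric gradient for every parameter array."""
    loss = build_loss()
    loss.backward()
    analytic = [p.grad.copy() for p in params]
    for p, a in zip(params, analytic):
        n = numgrad(lambda: float(build_loss().data), p.data)
        assert np.allclose(a, n, rtol=rtol, atol=atol), (
            f"grad mismatch: max abs diff {np.abs(a - n).max()}"
        )


@pytest.fixture()
def x_small(rng):
    return rng.standard_normal((2, 3, 8, 8)).astype(np.float32)


class TestLayerGradients:
    def test_linear(self, rng):
        lin = Linear(5, 4, rng)
        x = Tensor(rng.standard_normal((3, 5)).astype(np.float32))

        def loss():
            return (lin(x) * lin(x)).sum()

        check_param_grads(loss, [lin.W, lin.b])

    @pytest.mark.parametrize("stride,k", [(1, 3), (2, 3), (1, 7)])
    def test_conv(self, rng, x_small, stride, k):
        conv = Conv2d(3, 2, k, rng, stride=stride)
        x = Tensor(x_small)

        def loss():
            return (conv(x) * conv(x)).sum()

        check_param_grads(loss, [conv.W, conv.b])

    def test_conv_input_gradient(self, rng, x_small):
        # chain two convs so the inner one must propagate dx (incl. k=7 path)
        c1 = Conv2d(3, 2, 3, rng)
        c2 = Conv2d(2, 1, 7, rng)
        inner = Tensor(x_small, requires_grad=True)

        def loss():
            return (c2(c1(inner)) * 1.0).sum()

        check_param_grads(loss, [inner, c1.W])

    def test_conv_stride2_input_gradient(self, rng, x_small):
        c1 = Conv2d(3, 2, 3, rng, stride=2)
        inner = Tensor(x_small, requires_grad=True)

        def loss():
            return (c1(inner) * c1(inner)).sum()

        check_param_grads(loss, [inner])

    @pytest.mark.parametrize("training", [True, False])
    def test_batchnorm(self, rng, x_small, training):
        bn = BatchNorm2d(3)
        bn.running_mean[:] = rng.standard_normal(3)
        bn.running_var[:] = 0.5 + rng.random(3)
        bn.train(training)
        x = Tensor(x_small, requires_grad=True)
        frozen_rm, frozen_rv = bn.running_mean.copy(), bn.running_var.copy()

        def loss():
            bn.running_mean[:] = frozen_rm  # keep stats fixed across evals
            bn.running_var[:] = frozen_rv
            return (bn(x) * bn(x)).sum()

        check_param_grads(loss, [bn.gamma, bn.beta, x])

    @pytest.mark.parametrize("pool", [MaxPool2d(3, 2, 1), AvgPool2d(2)])
    def test_pooling(self, rng, x_small, pool):
        x = Tensor(x_small, requires_grad=True)

        def loss():
            return (pool(x) * pool(x)).sum()

        check_param_grads(loss, [x])

    def test_reductions_and_elementwise(self, rng):
        x = Tensor(rng.standard_normal((2, 4, 3, 3)).astype(np.float32), requires_grad=True)

        def loss():
            t = x.sigmoid() * x.relu() + x.mean(axis=(2, 3), keepdims=True)
            return (t.max(axis=1, keepdims=True) + global_avg_pool(t).reshape(2, 4, 1, 1)).sum()

        check_param_grads(loss, [x])

    def test_softmax_cross_entropy(self, rng):
        logits = Tensor(rng.standard_normal((5, 2)).astype(np.float32), requires_grad=True)
        labels = np.array([0, 1, 1, 0, 1])

        def loss():
            return cross_entropy_from_probs(softmax(logits), labels)

        check_param_grads(loss, [logits])

    def test_concat_stack_mean(self, rng):
        a = Tensor(rng.standard_normal((2, 3)).astype(np.float32), requires_grad=True)
        b = Tensor(rng.standard_normal((2, 3)).astype(np.float32), requires_grad=True)

        def loss():
            return (concat([a, b], axis=1) * 1.0).sum() + (stack_mean([a, b]) * a).sum()

        check_param_grads(loss, [a, b])


class TestFusedKernels:
    """Fused group kernels must match the sequential layers exactly."""

    def test_fused_conv_matches_sequential(self, rng):
        convs = [Conv2d(3, 4, 3, rng, stride=2) for _ in range(3)]
        x = rng.standard_normal((3, 2, 3, 8, 8)).astype(np.float32)
        fused = fused_conv(Tensor(x), convs)
        seq = np.stack([convs[i](Tensor(x[i])).data for i in range(3)])
        np.testing.assert_array_equal(fused.data, seq)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_fused_conv_gradients(self, rng, stride):
        convs = [Conv2d(2, 3, 3, rng, stride=stride) for _ in range(3)]
        x = Tensor(rng.standard_normal((3, 2, 2, 6, 6)).astype(np.float32),
                   requires_grad=True)

        def loss():
            out = fused_conv(x, convs)
            return (out * out).sum()

        check_param_grads(loss, [x, convs[0].W, convs[1].b, convs[2].W])

    def test_fused_batchnorm_matches_and_grads(self, rng):
        bns = [BatchNorm2d(3) for _ in range(3)]
        from dpanet.nn import autograd as ag

        for bn in bns:
            bn.gamma.data = (rng.random(3) + 0.5).astype(ag.DTYPE)
            bn.beta.data = rng.standard_normal(3).astype(ag.DTYPE)
        x_np = rng.standard_normal((3, 4, 3, 5, 5)).astype(np.float32)
        seq = np.stack([bns[i](Tensor(x_np[i])).data for i in range(3)])
        for bn in bns:  # reset running stats touched by the sequential pass
            bn.running_mean[:] = 0
            bn.running_var[:] = 1
        fused = fused_batchnorm(Tensor(x_np), bns)
        np.testing.assert_allclose(fused.data, seq, atol=1e-5)

        x = Tensor(x_np, requires_grad=True)

        def loss():
            rm = [(bn.running_mean.copy(), bn.running_var.copy()) for bn in bns]
            out = fused_batchnorm(x, bns)
            for bn, (m, v) in zip(bns, rm):
                bn.running_mean[:] = m
                bn.running_var[:] = v
            return (out * out).sum()

        check_param_grads(loss, [x, bns[0].gamma, bns[2].beta])

    def test_fused_linear_and_group_ops(self, rng):
        lins = [Linear(4, 3, rng) for _ in range(3)]
        x = Tensor(rng.standard_normal((3, 2, 4)).astype(np.float32), requires_grad=True)

        def loss():
            parts = unstack_group(fused_linear(x, lins))
            return (stack_group(parts) * 1.0).sum() + (parts[1] * parts[1]).sum()

        check_param_grads(loss, [x, lins[0].W, lins[1].b])


class TestOptimizer:
    def test_adam_minimizes_quadratic(self):
        p = Tensor(np.array([5.0, -3.0], dtype=np.float32), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_flat_buffer_aliases_parameters(self, rng):
        lin = Linear(3, 2, rng)
        opt = Adam([lin.W, lin.b], lr=1e-2)
        before = lin.W.data.copy()
        x = Tensor(rng.standard_normal((4, 3)).astype(np.float32))
        loss = (lin(x) * lin(x)).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
        # parameter views must see the flat-buffer update
        assert not np.allclose(before, lin.W.data)


class TestModuleBasics:
    def test_state_dict_roundtrip_and_mismatch(self, rng):
        class Net(Module):
            def __init__(self):
                super().__init__()
                self.a = Linear(3, 4, rng)
                self.bn = BatchNorm2d(4)

        net, net2 = Net(), Net()
        net.bn.running_mean[:] = 7.0
        net2.load_state_dict(net.state_dict())
        np.testing.assert_array_equal(net2.a.W.data, net.a.W.data)
        np.testing.assert_array_equal(net2.bn.running_mean, net.bn.running_mean)

        bad = net.state_dict()
        bad["a.W"] = np.zeros((2, 2), dtype=np.float32)
        with pytest.raises(ValueError, match="shape mismatch"):
            net2.load_state_dict(bad)

    def test_shared_submodule_params_not_duplicated(self, rng):
        class Net(Module):
            def __init__(self):
                super().__init__()
                shared = Linear(2, 2, rng)
                self.x = shared
                self.y = shared

        assert len(Net().parameters()) == 2  # W and b once
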