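"""Neural-network layers with fused numpy forward/backward kernels.

Convolution uses an im2col + BLAS matmul strategy; batch normalisation and
max-pooling carry hand-written backward closures.  All layers subclass
:class:`Module`, which provides parameter collection and train/eval mode
switching (batch norm is the only mode-dependent layer).
"""

from __future__ import annotations

import numpy as np

from . import autograd
from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "MaxPool2d",
    "global_avg_pool",
    "softmax",
    "cross_entropy_from_probs",
]


class Module:
    """Base class: parameter registry plus train/eval flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        # dedupe by identity: shared submodules must contribute each param once
        out: list[Tensor] = []
        seen: set[int] = set()
        for p in self._params.values():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        for m in self._modules.values():
            for p in m.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        if isinstance(self, BatchNorm2d):
            out[prefix + "running_mean"] = self.running_mean
            out[prefix + "running_var"] = self.running_var
        for name, m in self._modules.items():
            out.update(m.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.data.copy() for k, v in self.named_parameters().items()}
        d.update({k: v.copy() for k, v in self.buffers().items()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        """Load parameters/buffers, reporting every shape or name mismatch."""
        own_params = self.named_parameters()
        own_bufs = self.buffers()
        problems = []
        for k, v in own_params.items():
            if k not in d:
                problems.append(f"missing parameter: {k}")
            elif d[k].shape != v.data.shape:
                problems.append(
                    f"shape mismatch for {k}: checkpoint {d[k].shape} vs model {v.data.shape}"
                )
        for k in d:
            if k not in own_params and k not in own_bufs:
                problems.append(f"unexpected key in checkpoint: {k}")
        if problems:
            raise ValueError("checkpoint incompatible:\n  " + "\n  ".join(problems))
        for k, v in own_params.items():
            v.data = np.asarray(d[k], dtype=autograd.DTYPE)
        for k in own_bufs:
            if k in d:
                own_bufs[k][...] = d[k]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(autograd.DTYPE), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out, dtype=autograd.DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


# -- convolution -----------------------------------------------------------

def _pad_nchw(x: np.ndarray, pad: int, value: float = 0.0) -> np.ndarray:
    if not pad:
        return x
    n, c, h, w = x.shape
    buf = np.full((n, c, h + 2 * pad, w + 2 * pad), value, dtype=x.dtype)
    buf[:, :, pad:pad + h, pad:pad + w] = x
    return buf


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> contiguous (N, C*kh*kw, Ho*Wo) patch matrix."""
    n, c, _, _ = x.shape
    x = _pad_nchw(x, pad)
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        (n, c, kh, kw, ho, wo),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
    )
    return view.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`; dcols has shape (N, C*kh*kw, Ho*Wo)."""
    n, c, h, w = x_shape
    dc = dcols.reshape(n, c, kh, kw, ho, wo)
    buf = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        hi = i + stride * ho
        for j in range(kw):
            wj = j + stride * wo
            buf[:, :, i:hi:stride, j:wj:stride] += dc[:, :, i, j]
    if pad:
        buf = buf[:, :, pad:-pad, pad:-pad]
    return buf


def _needs_grad(t: Tensor) -> bool:
    return t.requires_grad or bool(t._prev)


def _conv_dx(g: np.ndarray, w: np.ndarray, k: int, pad: int, hw: tuple[int, int]) -> np.ndarray:
    """Input gradient of a stride-1 convolution as a transposed convolution.

    Much faster than the col2im scatter loop for large kernels: one im2col of
    the output gradient against the 180-degree-rotated, channel-transposed
    kernel.
    """
    n = g.shape[0]
    c_out, c_in = w.shape[:2]
    wt = np.ascontiguousarray(
        w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    ).reshape(c_in, c_out * k * k)
    gcols, ho, wo = _im2col(g, k, k, 1, k - 1 - pad)
    assert (ho, wo) == hw
    return np.matmul(wt, gcols).reshape(n, c_in, ho, wo)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = True):
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        self.W = _he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = Tensor(np.zeros(c_out, dtype=autograd.DTYPE), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        n = x.data.shape[0]
        c_out = self.W.data.shape[0]
        cols, ho, wo = _im2col(x.data, self.k, self.k, self.stride, self.pad)
        w2 = self.W.data.reshape(c_out, -1)
        out_data = (w2 @ cols).reshape(n, c_out, ho, wo)
        if self.b is not None:
            out_data += self.b.data[None, :, None, None]
        prev = (x, self.W) if self.b is None else (x, self.W, self.b)
        out = Tensor(out_data, _prev=prev)
        x_shape = x.data.shape

        def _bw(g):
            g3 = g.reshape(n, c_out, ho * wo)
            dW = np.matmul(g3, cols.transpose(0, 2, 1)).sum(axis=0)
            self.W._accumulate(dW.reshape(self.W.data.shape))
            if self.b is not None:
                self.b._accumulate(g3.sum(axis=(0, 2)))
            if _needs_grad(x):  # leaf inputs (the images) need no gradient
                if self.stride == 1:
                    x._accumulate(
                        _conv_dx(g, self.W.data, self.k, self.pad, x_shape[2:])
                    )
                else:
                    dcols = np.matmul(w2.T, g3)
                    x._accumulate(
                        _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad, ho, wo)
                    )

        out._backward = _bw
        return out


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(c, dtype=autograd.DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=autograd.DTYPE), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=autograd.DTYPE)
        self.running_var = np.ones(c, dtype=autograd.DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * invstd[None, :, None, None]
        out_data = xhat * self.gamma.data[None, :, None, None] + self.beta.data[None, :, None, None]
        out = Tensor(out_data, _prev=(x, self.gamma, self.beta))
        training = self.training

        def _bw(g):
            self.gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            self.beta._accumulate(g.sum(axis=(0, 2, 3)))
            gw = g * self.gamma.data[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                s1 = gw.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gw * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gw - s1 / m - xhat * s2 / m) * invstd[None, :, None, None]
            else:
                dx = gw * invstd[None, :, None, None]
            x._accumulate(dx)

        out._backward = _bw
        return out


class MaxPool2d(Module):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        k, stride, pad = self.k, self.stride, self.pad
        xp = _pad_nchw(x.data, pad, value=-np.inf)
        hp, wp = xp.shape[2], xp.shape[3]
        ho = (hp - k) // stride + 1
        wo = (wp - k) // stride + 1
        s = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, (n, c, ho, wo, k, k),
            (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        ).reshape(n, c, ho, wo, k * k)
        flat_idx = view.argmax(axis=-1)
        out_data = np.take_along_axis(view, flat_idx[..., None], axis=-1)[..., 0]
        out = Tensor(out_data, _prev=(x,))

        def _bw(g):
            oy = (np.arange(ho) * stride)[:, None]
            ox = (np.arange(wo) * stride)[None, :]
            rows = oy + flat_idx // k          # (n,c,ho,wo) broadcast
            colsi = ox + flat_idx % k
            base = (np.arange(n * c) * (hp * wp)).reshape(n, c, 1, 1)
            flat = (base + rows * wp + colsi).ravel()
            buf = np.bincount(flat, weights=g.ravel(), minlength=n * c * hp * wp)
            buf = buf.reshape(n, c, hp, wp).astype(g.dtype)
            x._accumulate(buf[:, :, pad:hp - pad, pad:wp - pad] if pad else buf)

        out._backward = _bw
        return out


class AvgPool2d(Module):
    """Non-overlapping k x k average pooling (spatial dims must divide k)."""

    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {k}")
        out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
        out = Tensor(out_data, _prev=(x,))

        def _bw(g):
            gk = g / (k * k)
            x._accumulate(
                np.broadcast_to(
                    gk[:, :, :, None, :, None], (n, c, h // k, k, w // k, k)
                ).reshape(n, c, h, w)
            )

        out._backward = _bw
        return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def softmax(logits: Tensor) -> Tensor:
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, _prev=(logits,))

    def _bw(g):
        dot = (g * p).sum(axis=-1, keepdims=True)
        logits._accumulate(p * (g - dot))

    out._backward = _bw
    return out


def cross_entropy_from_probs(probs: Tensor, labels: np.ndarray,
                             eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy -[y ln p1 + (1-y) ln p2] over the batch.

    ``probs`` has shape (N, 2) with column 0 the positive-class (ER)
    probability; probabilities are clamped to [eps, 1-eps] inside the logs.
    """
    labels = np.asarray(labels)
    n = probs.data.shape[0]
    y = labels.astype(np.float32)
    p = np.clip(probs.data, eps, 1.0 - eps)
    loss = -(y * np.log(p[:, 0]) + (1.0 - y) * np.log(p[:, 1])).mean()
    out = Tensor(loss, _prev=(probs,))

    def _bw(g):
        dp = np.zeros_like(probs.data)
        dp[:, 0] = -y / p[:, 0]
        dp[:, 1] = -(1.0 - y) / p[:, 1]
        probs._accumulate(g * dp / n)

    out._backward = _bw
    return out
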