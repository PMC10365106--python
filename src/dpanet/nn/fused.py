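"""Fused lockstep execution of three structurally identical branches.

The three phase branches share an architecture but not weights.  Running them
one at a time wastes most of the step time on per-op overhead at desk scale,
so these helpers evaluate the same layers group-batched: activations carry a
leading group axis G (= 3 phases), convolutions become batched GEMMs over
per-group weight stacks, and batch-norm statistics are computed per (group,
channel).  Each helper reads and accumulates gradients into the *original*
per-branch parameter tensors, so results, checkpoints and the
branch-independence property are identical to the sequential path (up to
floating-point associativity of the shared GEMM, which is in fact the same
per group).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .layers import BatchNorm2d, Conv2d, _col2im, _im2col, _needs_grad

__all__ = ["fused_conv", "fused_batchnorm", "fused_linear", "unstack_group", "stack_group"]


def fused_conv(x: Tensor, convs: list[Conv2d]) -> Tensor:
    """(G,N,Ci,H,W) through G same-shaped Conv2d layers -> (G,N,Co,Ho,Wo)."""
    g_, n = x.data.shape[:2]
    ref = convs[0]
    c_out = ref.W.data.shape[0]
    k, stride, pad = ref.k, ref.stride, ref.pad
    xf = x.data.reshape(g_ * n, *x.data.shape[2:])
    cols, ho, wo = _im2col(xf, k, k, stride, pad)       # (G*N, ckk, howo)
    colsg = cols.reshape(g_, n, *cols.shape[1:])
    w = np.stack([c.W.data.reshape(c_out, -1) for c in convs])  # (G, Co, ckk)
    out = np.matmul(w[:, None], colsg).reshape(g_, n, c_out, ho, wo)
    has_bias = ref.b is not None
    if has_bias:
        b = np.stack([c.b.data for c in convs])
        out += b[:, None, :, None, None]
    prev = [x]
    for c in convs:
        prev.append(c.W)
        if has_bias:
            prev.append(c.b)
    t = Tensor(out, _prev=tuple(prev))
    x_shape = x.data.shape

    def _bw(g):
        g4 = g.reshape(g_, n, c_out, ho * wo)
        dw = np.matmul(g4, colsg.transpose(0, 1, 3, 2)).sum(axis=1)  # (G,Co,ckk)
        for gi, c in enumerate(convs):
            c.W._accumulate(dw[gi].reshape(c.W.data.shape))
            if has_bias:
                c.b._accumulate(g4[gi].sum(axis=(0, 2)))
        if _needs_grad(x):
            if stride == 1:
                wall = np.stack([c.W.data for c in convs]).reshape(
                    g_ * c_out, *convs[0].W.data.shape[1:]
                )
                # grouped transposed conv: flip kernels, swap in/out channels
                c_in = wall.shape[1]
                wt = np.ascontiguousarray(
                    wall.reshape(g_, c_out, c_in, k, k)[:, :, :, ::-1, ::-1]
                    .transpose(0, 2, 1, 3, 4)
                ).reshape(g_, c_in, c_out * k * k)
                gf = g.reshape(g_ * n, c_out, ho, wo)
                gcols, h2, w2_ = _im2col(gf, k, k, 1, k - 1 - pad)
                gcolsg = gcols.reshape(g_, n, *gcols.shape[1:])
                dx = np.matmul(wt[:, None], gcolsg).reshape(x_shape)
                x._accumulate(dx)
            else:
                dcols = np.matmul(w.transpose(0, 2, 1)[:, None], g4)
                dxf = _col2im(
                    dcols.reshape(g_ * n, *cols.shape[1:]),
                    (g_ * n, *x_shape[2:]), k, k, stride, pad, ho, wo,
                )
                x._accumulate(dxf.reshape(x_shape))

    t._backward = _bw
    return t


def fused_batchnorm(x: Tensor, bns: list[BatchNorm2d]) -> Tensor:
    """(G,N,C,H,W) through G BatchNorm2d layers with per-(group,channel) stats."""
    g_, n, c = x.data.shape[:3]
    ref = bns[0]
    training = ref.training
    if training:
        mu = x.data.mean(axis=(1, 3, 4))                 # (G, C)
        xm2 = np.square(x.data).mean(axis=(1, 3, 4))
        var = np.maximum(xm2 - mu * mu, 0.0)
        for gi, bn in enumerate(bns):
            bn.running_mean += bn.momentum * (mu[gi] - bn.running_mean)
            bn.running_var += bn.momentum * (var[gi] - bn.running_var)
    else:
        mu = np.stack([bn.running_mean for bn in bns])
        var = np.stack([bn.running_var for bn in bns])
    invstd = 1.0 / np.sqrt(var + ref.eps)
    bshape = (g_, 1, c, 1, 1)
    xhat = (x.data - mu.reshape(bshape)) * invstd.reshape(bshape)
    gamma = np.stack([bn.gamma.data for bn in bns])
    beta = np.stack([bn.beta.data for bn in bns])
    out_data = xhat * gamma.reshape(bshape) + beta.reshape(bshape)
    prev = [x]
    for bn in bns:
        prev.extend((bn.gamma, bn.beta))
    out = Tensor(out_data, _prev=tuple(prev))

    def _bw(g):
        dgamma = (g * xhat).sum(axis=(1, 3, 4))
        dbeta = g.sum(axis=(1, 3, 4))
        for gi, bn in enumerate(bns):
            bn.gamma._accumulate(dgamma[gi])
            bn.beta._accumulate(dbeta[gi])
        gw = g * gamma.reshape(bshape)
        if training:
            m = n * g.shape[3] * g.shape[4]
            s1 = gw.sum(axis=(1, 3, 4), keepdims=True)
            s2 = (gw * xhat).sum(axis=(1, 3, 4), keepdims=True)
            dx = (gw - s1 / m - xhat * s2 / m) * invstd.reshape(bshape)
        else:
            dx = gw * invstd.reshape(bshape)
        x._accumulate(dx)

    out._backward = _bw
    return out


def fused_linear(x: Tensor, linears) -> Tensor:
    """(G,N,Fin) through G Linear layers -> (G,N,Fout), batched GEMM."""
    w = np.stack([l.W.data for l in linears])            # (G, Fin, Fout)
    b = np.stack([l.b.data for l in linears])
    out_data = np.matmul(x.data, w) + b[:, None, :]
    prev = [x]
    for l in linears:
        prev.extend((l.W, l.b))
    out = Tensor(out_data, _prev=tuple(prev))

    def _bw(g):
        dw = np.matmul(x.data.transpose(0, 2, 1), g)
        for gi, l in enumerate(linears):
            l.W._accumulate(dw[gi])
            l.b._accumulate(g[gi].sum(axis=0))
        if _needs_grad(x):
            x._accumulate(np.matmul(g, w.transpose(0, 2, 1)))

    out._backward = _bw
    return out


def unstack_group(t: Tensor) -> list[Tensor]:
    """Split the leading group axis into separate graph nodes."""
    outs = []
    for i in range(t.data.shape[0]):
        o = Tensor(t.data[i], _prev=(t,))

        def _bw(g, i=i):
            full = np.zeros_like(t.data)
            full[i] = g
            t._accumulate(full)

        o._backward = _bw
        outs.append(o)
    return outs


def stack_group(tensors: list[Tensor]) -> Tensor:
    """Inverse of :func:`unstack_group`."""
    out = Tensor(np.stack([t.data for t in tensors]), _prev=tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(g[i])

    out._backward = _bw
    return out
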