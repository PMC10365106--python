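"""Intra-phase and inter-phase attention.

Intra-phase attention runs a squeeze-excite channel branch and a CBAM-style
spatial branch in parallel on one phase's feature map and sums the two
attended maps:

    out = fmap * sigmoid(FC2(relu(FC1(GAP(fmap))))) + fmap * sigmoid(conv7x7([max_c; mean_c]))

Inter-phase attention computes each phase's channel vector and spatial map,
averages them across the three phases into one shared vector and one shared
map, applies the shared attention to each phase's ORIGINAL feature map, and
sums all six resulting maps into a single fused map.

Zero-initialized parameters force every sigmoid to 0.5, making the intra
module an identity and the inter module the plain sum of its three inputs —
useful identities that the tests assert.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, concat, global_avg_pool, stack_mean

__all__ = [
    "AttentionBlock",
    "build_attention",
    "channel_attention_weights",
    "spatial_attention_map",
    "intra_phase_attention",
    "inter_phase_attention",
]


class AttentionBlock(Module):
    """Parameters for one phase's channel + spatial attention.

    ``reduction`` is the squeeze-excite bottleneck ratio r (default 16); the
    hidden width is floor(C / r) clamped to at least 1.  The spatial branch is
    a single 7x7 convolution from the 2-channel [channel-max; channel-mean]
    stack to 1 channel, with same-padding.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        self.channels = channels
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial_conv = Conv2d(2, 1, 7, rng, pad=3)

    # -- graph-level forward pieces (Tensor in, Tensor out) ---------------
    def channel_weights_t(self, fmap: Tensor) -> Tensor:
        """(N,C,H,W) -> (N,C,1,1) sigmoid channel weights."""
        n, c = fmap.data.shape[:2]
        squeezed = global_avg_pool(fmap)                     # (N, C)
        w = self.fc2(self.fc1(squeezed).relu()).sigmoid()    # (N, C)
        return w.reshape(n, c, 1, 1)

    def spatial_map_t(self, fmap: Tensor) -> Tensor:
        """(N,C,H,W) -> (N,1,H,W) sigmoid spatial map."""
        mx = fmap.max(axis=1, keepdims=True)
        mn = fmap.mean(axis=1, keepdims=True)
        return self.spatial_conv(concat([mx, mn], axis=1)).sigmoid()

    def intra_t(self, fmap: Tensor) -> Tensor:
        return fmap * self.channel_weights_t(fmap) + fmap * self.spatial_map_t(fmap)


def build_attention(channels: int, seed: int, reduction: int = 16) -> AttentionBlock:
    return AttentionBlock(channels, np.random.default_rng(seed), reduction)


def inter_phase_t(fmaps: list[Tensor], blocks: list[AttentionBlock]) -> Tensor:
    """Graph-level inter-phase attention on three (N,C,H,W) tensors."""
    if len(fmaps) != 3 or len(blocks) != 3:
        raise ValueError("inter-phase attention takes exactly three maps and blocks")
    shapes = {f.data.shape for f in fmaps}
    if len(shapes) != 1:
        raise ValueError(f"phase feature maps must share a shape, got {shapes}")
    ch = stack_mean([b.channel_weights_t(f) for f, b in zip(fmaps, blocks)])
    sp = stack_mean([b.spatial_map_t(f) for f, b in zip(fmaps, blocks)])
    out = None
    for f in fmaps:
        term = f * ch + f * sp
        out = term if out is None else out + term
    return out


# -- numpy-facing API (single feature map, eval semantics) -----------------

def _to4d(fmap: np.ndarray) -> tuple[Tensor, bool]:
    from .nn import autograd

    x = np.asarray(fmap, dtype=autograd.DTYPE)
    if x.ndim == 3:
        return Tensor(x[None]), True
    if x.ndim == 4:
        return Tensor(x), False
    raise ValueError(f"feature map must be (C,H,W) or (N,C,H,W), got {x.shape}")


def _check(fmap_shape, block: AttentionBlock):
    if fmap_shape[1] != block.channels:
        raise ValueError(
            f"attention block built for C={block.channels}, feature map has C={fmap_shape[1]}"
        )


def channel_attention_weights(fmap: np.ndarray, block: AttentionBlock) -> np.ndarray:
    """Squeeze-excite weights, shape (C,1,1), values in (0,1)."""
    t, single = _to4d(fmap)
    _check(t.data.shape, block)
    w = block.channel_weights_t(t).data
    return w[0] if single else w


def spatial_attention_map(fmap: np.ndarray, block: AttentionBlock) -> np.ndarray:
    """Spatial attention, shape (1,H,W), values in (0,1)."""
    t, single = _to4d(fmap)
    _check(t.data.shape, block)
    m = block.spatial_map_t(t).data
    return m[0] if single else m


def intra_phase_attention(fmap: np.ndarray, block: AttentionBlock) -> np.ndarray:
    """Parallel channel + spatial attention, branches summed; dims preserved."""
    t, single = _to4d(fmap)
    _check(t.data.shape, block)
    out = block.intra_t(t).data
    return out[0] if single else out


def inter_phase_attention(
    fmaps: list[np.ndarray], blocks: list[AttentionBlock]
) -> np.ndarray:
    """Average per-phase attention across phases, apply to each original map, sum all."""
    prepared = [_to4d(f) for f in fmaps]
    single = prepared[0][1] if prepared else False
    tensors = [t for t, _ in prepared]
    for t in tensors:
        _check(t.data.shape, blocks[0])
    out = inter_phase_t(tensors, list(blocks)).data
    return out[0] if single else out
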