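"""Residual branch CNNs — one branch per contrast phase (NC, ART, PV).

Three independently parameterized residual networks extract per-phase feature
maps from the tumor-ROI images.  Depths:

* ``"18"`` — basic-block residual net; stage widths 64/128/256 and, by
  default, 256 in the last stage (a ``standard_conv5`` switch restores the
  conventional 512).
* ``"50"`` — bottleneck residual net (widths 256/512/1024/2048).
* ``"small"`` — a two-stage 16/32-channel variant for desk-scale training and
  tests: 3x3 stride-2 stem + 3x3/2 max-pool, one basic block per stage, both
  stages stride 2, so a 64x64 input yields a 32-channel 4x4 map.

Phase images are single-channel; by default the stem replicates them to three
channels so externally supplied natural-image pretrained weights remain
loadable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, MaxPool2d, Module, Tensor
from .nn.layers import AvgPool2d

__all__ = [
    "BranchConfig",
    "Branch",
    "build_branch",
    "branch_forward",
    "backbone_forward",
    "PHASES",
]

PHASES = ("NC", "ART", "PV")


@dataclass(frozen=True)
class BranchConfig:
    depth: str = "small"  # "18" | "50" | "small"
    input_size: tuple[int, int] = (64, 64)
    replicate_gray_to_3: bool = True
    standard_conv5: bool = False  # ResNet-18 last-stage width 512 instead of 256

    @property
    def in_channels(self) -> int:
        return 3 if self.replicate_gray_to_3 else 1

    def out_channels(self) -> int:
        return {"18": 512 if self.standard_conv5 else 256,
                "50": 2048, "small": 32}[self.depth]


class BasicBlock(Module):
    def __init__(self, c_in, c_out, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = Conv2d(c_in, c_out, 1, rng, stride=stride, pad=0, bias=False)
            self.down_bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = x if self.down is None else self.down_bn(self.down(x))
        return (out + skip).relu()


class Bottleneck(Module):
    def __init__(self, c_in, c_mid, c_out, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_mid, 1, rng, pad=0)
        self.bn1 = BatchNorm2d(c_mid)
        self.conv2 = Conv2d(c_mid, c_mid, 3, rng, stride=stride)
        self.bn2 = BatchNorm2d(c_mid)
        self.conv3 = Conv2d(c_mid, c_out, 1, rng, pad=0)
        self.bn3 = BatchNorm2d(c_out)
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = Conv2d(c_in, c_out, 1, rng, stride=stride, pad=0, bias=False)
            self.down_bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        skip = x if self.down is None else self.down_bn(self.down(x))
        return (out + skip).relu()


class _Sequential(Module):
    def __init__(self, blocks):
        super().__init__()
        for i, b in enumerate(blocks):
            setattr(self, f"b{i}", b)
        self.blocks = blocks

    def __call__(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class Branch(Module):
    """One residual branch CNN."""

    def __init__(self, config: BranchConfig, seed: int):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c_in = config.in_channels
        if config.depth == "small":
            self.stem = Conv2d(c_in, 16, 3, rng, stride=2)
            self.bn = BatchNorm2d(16)
            self.pool = AvgPool2d(2)  # cheap stand-in for the 3x3/2 max pool
            self.stages = _Sequential([
                BasicBlock(16, 16, 2, rng),
                BasicBlock(16, 32, 2, rng),
            ])
        elif config.depth == "18":
            self.stem = Conv2d(c_in, 64, 7, rng, stride=2, pad=3)
            self.bn = BatchNorm2d(64)
            self.pool = MaxPool2d(3, 2, 1)
            w5 = 512 if config.standard_conv5 else 256
            self.stages = _Sequential([
                BasicBlock(64, 64, 1, rng), BasicBlock(64, 64, 1, rng),
                BasicBlock(64, 128, 2, rng), BasicBlock(128, 128, 1, rng),
                BasicBlock(128, 256, 2, rng), BasicBlock(256, 256, 1, rng),
                BasicBlock(256, w5, 2, rng), BasicBlock(w5, w5, 1, rng),
            ])
        elif config.depth == "50":
            self.stem = Conv2d(c_in, 64, 7, rng, stride=2, pad=3)
            self.bn = BatchNorm2d(64)
            self.pool = MaxPool2d(3, 2, 1)
            spec = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)]
            blocks = []
            c = 64
            for mid, out, n, stride in spec:
                for i in range(n):
                    blocks.append(Bottleneck(c, mid, out, stride if i == 0 else 1, rng))
                    c = out
            self.stages = _Sequential(blocks)
        else:
            raise ValueError(f"unsupported depth {config.depth!r} (use '18', '50' or 'small')")

    def __call__(self, x: Tensor) -> Tensor:
        return self.stages(self.pool(self.bn(self.stem(x)).relu()))

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_branch(config: BranchConfig, seed: int) -> Branch:
    """Deterministically initialized branch; distinct calls share no weights."""
    return Branch(config, seed)


class BranchEnsemble(Module):
    """Lockstep fused evaluation of three branches (basic-block depths only).

    Activations carry a leading group axis: input (3, N, C, H, W), output
    (3, N, C', H', W').  Parameters remain owned by the individual
    :class:`Branch` modules, so checkpoints and branch independence are
    unaffected; this is purely an execution strategy.
    """

    def __init__(self, branches: list[Branch]):
        super().__init__()
        if len(branches) != 3:
            raise ValueError("ensemble needs exactly three branches")
        if any(b.config != branches[0].config for b in branches):
            raise ValueError("ensemble branches must share a config")
        if branches[0].config.depth == "50":
            raise ValueError("fused execution supports basic-block depths only")
        self.b0, self.b1, self.b2 = branches
        self.branches_list = branches

    def __call__(self, x: Tensor) -> Tensor:
        from .nn.fused import fused_batchnorm, fused_conv

        brs = self.branches_list
        t = fused_conv(x, [b.stem for b in brs])
        t = fused_batchnorm(t, [b.bn for b in brs]).relu()
        g, n = t.data.shape[:2]
        t = brs[0].pool(t.reshape(g * n, *t.data.shape[2:]))
        t = t.reshape(g, n, *t.data.shape[1:])
        for i in range(len(brs[0].stages.blocks)):
            blocks = [b.stages.blocks[i] for b in brs]
            out = fused_batchnorm(
                fused_conv(t, [bl.conv1 for bl in blocks]),
                [bl.bn1 for bl in blocks],
            ).relu()
            out = fused_batchnorm(
                fused_conv(out, [bl.conv2 for bl in blocks]),
                [bl.bn2 for bl in blocks],
            )
            if blocks[0].down is not None:
                skip = fused_batchnorm(
                    fused_conv(t, [bl.down for bl in blocks]),
                    [bl.down_bn for bl in blocks],
                )
            else:
                skip = t
            t = (out + skip).relu()
        return t


def _prep(image: np.ndarray, config: BranchConfig) -> np.ndarray:
    """(H,W) / (C,H,W) / (N,C,H,W) -> batched (N,C,H,W) with channel replication."""
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    elif x.ndim != 4:
        raise ValueError(f"expected 2-4 dims, got shape {x.shape}")
    if x.shape[1] == 1 and config.replicate_gray_to_3:
        x = np.repeat(x, 3, axis=1)
    if x.shape[1] != config.in_channels:
        raise ValueError(
            f"expected {config.in_channels} channels, got {x.shape[1]}"
        )
    if x.shape[2:] != tuple(config.input_size):
        raise ValueError(
            f"expected spatial size {config.input_size}, got {x.shape[2:]}"
        )
    return x


def branch_forward(image: np.ndarray, branch: Branch) -> np.ndarray:
    """Run one phase image through one branch (eval mode); returns (C,H,W)."""
    x = _prep(image, branch.config)
    was_training = branch.training
    branch.eval()
    out = branch(Tensor(x)).data
    branch.train(was_training)
    return out[0] if out.shape[0] == 1 else out


def backbone_forward(
    phases: list[np.ndarray] | tuple[np.ndarray, ...],
    branches: list[Branch] | tuple[Branch, ...],
) -> list[np.ndarray]:
    """Per-phase feature maps in fixed (NC, ART, PV) order."""
    if len(phases) != 3 or len(branches) != 3:
        raise ValueError(
            f"exactly three phases/branches required, got {len(phases)}/{len(branches)}"
        )
    shapes = {np.asarray(p).shape for p in phases}
    if len(shapes) != 1:
        raise ValueError(f"phase images must share a shape, got {shapes}")
    return [branch_forward(img, br) for img, br in zip(phases, branches)]
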