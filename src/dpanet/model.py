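"""The phase-attention fusion network and its training loop.

Image pathway: three residual branches (one per phase) -> intra-phase
attention on each branch's final map -> inter-phase attention fusing the
three attended maps into one -> global average pooling -> FC down to a
30-dim image feature S(I).  Clinical pathway: FC up from the 9-bit clinical
vector to a 30-dim feature T(c).  Fusion head: concatenate S ⊕ T and apply a
final 2-neuron FC + softmax, p_k = exp(z_k) / sum_k exp(z_k) with
z_k = W_k·[S ⊕ T] + b_k.

Loss: mean binary cross-entropy L = -(1/N) Σ [y ln p_1 + (1-y) ln p_2].
In joint mode auxiliary softmax heads are attached to both pathways before
concatenation and the objective becomes

    L = 1/4 L_image + 1/4 L_clinical + 1/2 L_combine.

Defaults follow the training protocol: batch size 8, 50 epochs, Adam with
learning rate 1e-4.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .attention import AttentionBlock, inter_phase_t
from .backbone import Branch, BranchConfig
from .nn import (
    Adam,
    Linear,
    Module,
    Tensor,
    concat,
    cross_entropy_from_probs,
    global_avg_pool,
    softmax,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "DPAModel",
    "JointLossComponents",
    "cross_entropy",
    "joint_loss",
    "train",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("fusion", "image_only", "clinical_only")


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "fusion"          # fusion | image_only | clinical_only
    loss_mode: str = "combined"      # combined | joint
    depth: str = "small"
    input_size: tuple[int, int] = (64, 64)
    reduction: int = 16              # squeeze-excite ratio r
    feature_dim: int = 30            # width of both pathway features
    share_inter_params: bool = False
    standard_conv5: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.loss_mode not in ("combined", "joint"):
            raise ValueError("loss_mode must be 'combined' or 'joint'")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 50
    learning_rate: float = 1e-4
    seed: int = 0
    augment: bool = False


@dataclass
class JointLossComponents:
    l_image: float
    l_clinical: float
    l_combine: float
    total: float


class DPAModel(Module):
    def __init__(self, config: ModelConfig, seed: int):
        super().__init__()
        self.config = config
        ss = np.random.SeedSequence(seed)
        seeds = [int(s) for s in ss.generate_state(12)]
        bcfg = BranchConfig(depth=config.depth, input_size=config.input_size,
                            standard_conv5=config.standard_conv5)
        self.branch_config = bcfg
        c = bcfg.out_channels()
        if config.variant != "clinical_only":
            self.branches = _ModuleList(
                [Branch(bcfg, seeds[i]) for i in range(3)]
            )
            if config.depth != "50":
                from .backbone import BranchEnsemble

                # execution strategy only — keep it out of the param registry
                object.__setattr__(self, "_ensemble", BranchEnsemble(self.branches.mods))
            self.intra = _ModuleList([
                AttentionBlock(c, np.random.default_rng(seeds[3 + i]), config.reduction)
                for i in range(3)
            ])
            if config.share_inter_params:
                shared = AttentionBlock(c, np.random.default_rng(seeds[6]), config.reduction)
                self.inter = _ModuleList([shared] * 3)
            else:
                self.inter = _ModuleList([
                    AttentionBlock(c, np.random.default_rng(seeds[6 + i]), config.reduction)
                    for i in range(3)
                ])
            rng = np.random.default_rng(seeds[9])
            self.fc_image = Linear(c, config.feature_dim, rng)
        if config.variant != "image_only":
            rng = np.random.default_rng(seeds[10])
            self.fc_clinical = Linear(9, config.feature_dim, rng)
        rng = np.random.default_rng(seeds[11])
        head_in = {
            "fusion": 2 * config.feature_dim,
            "image_only": config.feature_dim,
            "clinical_only": config.feature_dim,
        }[config.variant]
        self.head = Linear(head_in, 2, rng)
        if config.loss_mode == "joint" and config.variant == "fusion":
            self.aux_image = Linear(config.feature_dim, 2, rng)
            self.aux_clinical = Linear(config.feature_dim, 2, rng)

    # -- forward pieces ----------------------------------------------------
    def image_feature_t(self, images: Tensor) -> Tensor:
        """(N, 3, H, W) phase stack (NC, ART, PV order) -> (N, feature_dim)."""
        x = images.data.transpose(1, 0, 2, 3)[:, :, None]  # (3, N, 1, H, W)
        if self.branch_config.replicate_gray_to_3:
            x = np.repeat(x, 3, axis=2)
        if self.config.depth == "50":
            fmaps = [self.branches.mods[p](Tensor(x[p])) for p in range(3)]
        else:
            from .nn.fused import unstack_group

            fmaps = unstack_group(self._ensemble(Tensor(np.ascontiguousarray(x))))
        attended = [self.intra.mods[p].intra_t(f) for p, f in enumerate(fmaps)]
        fused = inter_phase_t(attended, self.inter.mods)
        return self.fc_image(global_avg_pool(fused)).relu()

    def clinical_feature_t(self, vectors: Tensor) -> Tensor:
        """(N, 9) binary clinical vectors -> (N, feature_dim)."""
        if vectors.data.shape[-1] != 9:
            raise ValueError(
                f"clinical vector must have 9 elements, got {vectors.data.shape[-1]}"
            )
        return self.fc_clinical(vectors).relu()

    def forward(self, images: np.ndarray | None, vectors: np.ndarray | None) -> dict:
        """Full forward pass; returns Tensors keyed by pathway."""
        out: dict[str, Tensor] = {}
        feats = []
        if self.config.variant != "clinical_only":
            s = self.image_feature_t(Tensor(np.asarray(images, dtype=np.float32)))
            out["image_feature"] = s
            feats.append(s)
        if self.config.variant != "image_only":
            t = self.clinical_feature_t(Tensor(np.asarray(vectors, dtype=np.float32)))
            out["clinical_feature"] = t
            feats.append(t)
        combined = feats[0] if len(feats) == 1 else concat(feats, axis=1)
        logits = self.head(combined)
        out["logits"] = logits
        out["probs"] = softmax(logits)
        if self.config.loss_mode == "joint" and self.config.variant == "fusion":
            out["image_probs"] = softmax(self.aux_image(out["image_feature"]))
            out["clinical_probs"] = softmax(self.aux_clinical(out["clinical_feature"]))
        return out


class _ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(self.mods):
            setattr(self, f"m{i}", m)


# -- losses ----------------------------------------------------------------

def cross_entropy(probs, labels, eps: float = 1e-7) -> float | Tensor:
    """Mean binary cross-entropy of an (N,2) probability array/Tensor.

    Column 0 is the positive-class (ER) probability; a single pair may be
    passed as shape (2,).
    """
    if isinstance(probs, Tensor):
        t = probs
    else:
        p = np.asarray(probs, dtype=np.float32)
        if p.ndim == 1:
            p = p[None]
        t = Tensor(p)
    labels = np.atleast_1d(labels)
    out = cross_entropy_from_probs(t, labels, eps)
    return out if isinstance(probs, Tensor) else float(out.data)


def joint_loss(image_probs, clinical_probs, combined_probs, labels,
               eps: float = 1e-7) -> JointLossComponents:
    """Weighted joint objective: 1/4 image + 1/4 clinical + 1/2 combined."""
    li = cross_entropy(image_probs, labels, eps)
    lc = cross_entropy(clinical_probs, labels, eps)
    lcom = cross_entropy(combined_probs, labels, eps)
    fi = float(li.data) if isinstance(li, Tensor) else li
    fc = float(lc.data) if isinstance(lc, Tensor) else lc
    fcom = float(lcom.data) if isinstance(lcom, Tensor) else lcom
    return JointLossComponents(fi, fc, fcom, 0.25 * fi + 0.25 * fc + 0.5 * fcom)


@dataclass
class TrainingSet:
    """Slice-level samples: phase stacks, clinical vectors and labels."""
    images: np.ndarray | None      # (n, 3, H, W) float32 in [0, 1]
    clinical: np.ndarray | None    # (n, 9) float32
    labels: np.ndarray             # (n,) int {0,1}

    def __len__(self):
        return len(self.labels)


def _augment_batch(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Optional flips / 90-degree rotations / intensity jitter."""
    out = images
    if rng.random() < 0.5:
        out = out[..., ::-1]
    if rng.random() < 0.5:
        out = out[..., ::-1, :]
    k = int(rng.integers(0, 4))
    if k:
        out = np.rot90(out, k, axes=(-2, -1))
    jitter = 1.0 + rng.normal(0, 0.02)
    return np.ascontiguousarray(out * jitter)


def _batch_loss(model: DPAModel, out: dict, labels: np.ndarray) -> tuple[Tensor, dict]:
    comps = {}
    l_comb = cross_entropy_from_probs(out["probs"], labels)
    comps["combine"] = float(l_comb.data)
    if model.config.loss_mode == "joint" and model.config.variant == "fusion":
        l_img = cross_entropy_from_probs(out["image_probs"], labels)
        l_clin = cross_entropy_from_probs(out["clinical_probs"], labels)
        comps["image"] = float(l_img.data)
        comps["clinical"] = float(l_clin.data)
        total = l_img * 0.25 + l_clin * 0.25 + l_comb * 0.5
    else:
        total = l_comb
    comps["total"] = float(total.data)
    return total, comps


def train(model: DPAModel, dataset: TrainingSet, config: TrainConfig) -> dict:
    """Seeded minibatch Adam training; returns per-epoch loss history."""
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: dict[str, list[float]] = {"total": [], "combine": []}
    if model.config.loss_mode == "joint" and model.config.variant == "fusion":
        history["image"] = []
        history["clinical"] = []
    model.train()
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = {k: 0.0 for k in history}
        seen = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs = None
            if dataset.images is not None:
                imgs = dataset.images[idx]
                if config.augment:
                    imgs = _augment_batch(imgs, rng)
            clin = dataset.clinical[idx] if dataset.clinical is not None else None
            out = model.forward(imgs, clin)
            loss, comps = _batch_loss(model, out, dataset.labels[idx])
            if not np.isfinite(comps["total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {_epoch}, batch start {start}: {comps}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in sums:
                sums[k] += comps[k] * len(idx)
            seen += len(idx)
        for k in history:
            history[k].append(sums[k] / seen)
    model.eval()
    return history


def predict_proba(model: DPAModel, dataset: TrainingSet, batch_size: int = 64) -> np.ndarray:
    """(n, 2) class probabilities in eval mode, column 0 = P(ER)."""
    model.eval()
    outs = []
    n = len(dataset)
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        imgs = dataset.images[sl] if dataset.images is not None else None
        clin = dataset.clinical[sl] if dataset.clinical is not None else None
        outs.append(model.forward(imgs, clin)["probs"].data)
    return np.concatenate(outs, axis=0)


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(path, model: DPAModel, seed: int | None = None,
                    history: dict | None = None) -> None:
    """Single-file .npz container: parameters + config echo + seed + history."""
    meta = {
        "config": asdict(model.config),
        "seed": seed,
        "history": history,
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expect_config: ModelConfig | None = None):
    """Load a checkpoint; validates config match and parameter shapes."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    cfg_dict = meta["config"]
    cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
    cfg = ModelConfig(**cfg_dict)
    if expect_config is not None and cfg != expect_config:
        raise ValueError(
            f"checkpoint config {cfg} does not match expected {expect_config}"
        )
    model = DPAModel(cfg, seed=meta["seed"] or 0)
    model.load_state_dict(params)
    model.eval()
    return model, meta
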