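"""The Siamese network: residual encoder, projection head, classifier.

One weight set serves both augmented views (the source/target branches
share the encoder); the projection head produces the L2-normalized
contrastive embedding z, and the classifier consumes the pooled encoder
feature h — the head is discarded for classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .layers import Linear, Module, ResidualBlock

__all__ = ["EncoderConfig", "EmbeddingBatch", "SupConNet", "build_network",
           "encode_project", "classify", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_SCHEMA = "supcon-tsc-ckpt-v1"


@dataclass
class EncoderConfig:
    """Architecture hyperparameters of the encoder / head / classifier.

    ``feature_dim`` (the size of the pooled representation h) equals the
    last block's filter count by construction of global average pooling.
    """

    in_channels: int = 3
    n_classes: int = 2
    block_filters: tuple[int, int, int] = (64, 128, 128)
    kernel_sizes: tuple[int, int, int] = (8, 5, 3)
    proj_dim: int = 64
    proj_hidden: int = 128
    clf_hidden: int = 128
    use_mask_channels: bool = False  # concatenate the mask as extra input channels

    @property
    def feature_dim(self) -> int:
        return self.block_filters[-1]

    def validate(self) -> None:
        if len(self.block_filters) != 3 or len(self.kernel_sizes) != 3:
            raise ValueError("block_filters and kernel_sizes must have length 3")
        if self.in_channels < 1 or self.n_classes < 2 or self.proj_dim < 1:
            raise ValueError("invalid encoder configuration")


@dataclass
class EmbeddingBatch:
    """Paired unit-norm projected embeddings of one mini-batch.

    ``z_source[i]`` and ``z_target[i]`` are the strong/weak views of the
    same underlying case i.
    """

    z_source: np.ndarray  # (N, D)
    z_target: np.ndarray  # (N, D)
    labels: np.ndarray  # (N,) int

    def __post_init__(self):
        self.z_source = np.asarray(self.z_source, dtype=float)
        self.z_target = np.asarray(self.z_target, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.z_source.shape != self.z_target.shape:
            raise ValueError("source/target embedding shapes differ")
        if len(self.labels) != self.z_source.shape[0]:
            raise ValueError("labels length does not match batch size")


def l2_normalize(z: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((z * z).sum(axis=1, keepdims=True) + eps) ** 0.5
    return z * norm ** -1.0


class SupConNet(Module):
    """Encoder (3 residual blocks + GAP) with projection head and classifier."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c_in = cfg.in_channels * (2 if cfg.use_mask_channels else 1)
        f1, f2, f3 = cfg.block_filters
        self.block1 = ResidualBlock(c_in, f1, cfg.kernel_sizes, rng)
        self.block2 = ResidualBlock(f1, f2, cfg.kernel_sizes, rng)
        self.block3 = ResidualBlock(f2, f3, cfg.kernel_sizes, rng)
        self.proj1 = Linear(cfg.feature_dim, cfg.proj_hidden, rng)
        self.proj2 = Linear(cfg.proj_hidden, cfg.proj_dim, rng)
        self.clf1 = Linear(cfg.feature_dim, cfg.clf_hidden, rng)
        self.clf2 = Linear(cfg.clf_hidden, cfg.n_classes, rng)
        self._last_conv: Tensor | None = None  # retained feature maps for Grad-CAM

    # ---------------------------------------------------------------- encoder
    def feature_maps(self, x: Tensor) -> Tensor:
        """Final convolutional feature maps, shape (N, F3, L)."""
        a = self.block3(self.block2(self.block1(x)))
        self._last_conv = a
        return a

    def encode(self, x: Tensor) -> Tensor:
        """Pooled representation h, shape (N, D_h): GAP over time."""
        return self.feature_maps(x).mean(axis=2)

    def project(self, h: Tensor) -> Tensor:
        return l2_normalize(self.proj2(self.proj1(h).relu()))

    def classifier_logits(self, h: Tensor) -> Tensor:
        return self.clf2(self.clf1(h).relu())

    @property
    def last_conv(self) -> Tensor | None:
        """Feature maps retained by the most recent forward pass."""
        return self._last_conv

    def encoder_modules(self) -> list[Module]:
        return [self.block1, self.block2, self.block3]

    def encoder_parameters(self) -> list[Tensor]:
        return [p for b in self.encoder_modules() for p in b.parameters()]

    def head_parameters(self) -> list[Tensor]:
        return self.proj1.parameters() + self.proj2.parameters()

    def classifier_parameters(self) -> list[Tensor]:
        return self.clf1.parameters() + self.clf2.parameters()

    def _prep(self, x_batch, mask=None) -> Tensor:
        x = x_batch if isinstance(x_batch, Tensor) else Tensor(np.asarray(x_batch, dtype=float))
        if x.ndim != 3:
            raise ValueError(f"expected (N, m, l) batch, got shape {x.shape}")
        if self.cfg.use_mask_channels:
            from .autodiff import concatenate
            if mask is None:
                mask = np.ones_like(x.data)
            x = concatenate([x, Tensor(np.asarray(mask, dtype=float))], axis=1)
        return x


def build_network(cfg: EncoderConfig, seed: int = 0) -> SupConNet:
    """Deterministically initialized network for the given architecture."""
    return SupConNet(cfg, seed=seed)


def encode_project(net: SupConNet, x_batch, mask=None) -> Tensor:
    """z = normalize(proj(E(x))): unit-norm rows, shape (N, D)."""
    return net.project(net.encode(net._prep(x_batch, mask)))


def classify(net: SupConNet, x_batch, mask=None) -> np.ndarray:
    """Class probabilities (N, c): softmax over classifier logits on h."""
    logits = net.classifier_logits(net.encode(net._prep(x_batch, mask))).data
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


# ------------------------------------------------------------------ checkpoints
def save_checkpoint(path, net: SupConNet, norm_stats=None, extra: dict | None = None) -> None:
    """Single-file NPZ archive: weights + architecture + normalization stats."""
    arrays = {f"w{i}": a for i, a in enumerate(net.get_state())}
    cfg = net.cfg
    meta = dict(schema=CHECKPOINT_SCHEMA, in_channels=cfg.in_channels,
                n_classes=cfg.n_classes, block_filters=list(cfg.block_filters),
                kernel_sizes=list(cfg.kernel_sizes), proj_dim=cfg.proj_dim,
                proj_hidden=cfg.proj_hidden, clf_hidden=cfg.clf_hidden,
                use_mask_channels=cfg.use_mask_channels, n_weights=len(arrays))
    if extra:
        meta.update(extra)
    import json

    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if norm_stats is not None:
        arrays["norm_mean"], arrays["norm_std"] = norm_stats
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[SupConNet, tuple | None, dict]:
    import json

    with np.load(path) as f:
        meta = json.loads(bytes(f["meta_json"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unknown checkpoint schema: {meta.get('schema')}")
        cfg = EncoderConfig(
            in_channels=meta["in_channels"], n_classes=meta["n_classes"],
            block_filters=tuple(meta["block_filters"]),
            kernel_sizes=tuple(meta["kernel_sizes"]), proj_dim=meta["proj_dim"],
            proj_hidden=meta["proj_hidden"], clf_hidden=meta["clf_hidden"],
            use_mask_channels=meta["use_mask_channels"])
        net = SupConNet(cfg, seed=0)
        net.set_state([f[f"w{i}"] for i in range(meta["n_weights"])])
        stats = (f["norm_mean"], f["norm_std"]) if "norm_mean" in f else None
    return net, stats, meta
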