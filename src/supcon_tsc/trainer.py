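"""Two-stage training: contrastive representation learning, then a
classifier on the frozen encoder; plus stratified k-fold ensembling and
the cross-entropy-only ablation baseline.

Stage 1 (per mini-batch): make strong/weak views -> encode and project
both through the shared encoder -> compute per-label cluster centers of
the target embeddings -> push them into the memory bank -> instance-level
loss plus (after warm-up) cluster-level loss against the bank -> Adam
step.  The last incomplete batch is dropped (contrastive losses degrade
at tiny N); stage 2 keeps all cases.

Stage 2 discards the projection head and trains the MLP classifier on
the frozen pooled features h with cross-entropy.  With ``with_supcon``
off, the encoder and classifier are instead trained jointly from scratch
with cross-entropy only — the ablation baseline; that path never touches
the projection head or the bank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import child_seed, stream_rng
from .augment import AugmentationSpec, make_views
from .autodiff import Tensor
from .bank import ClusterMemoryBank
from .io_ts import MtscDataset, znormalize
from .layers import Adam
from .losses import (alpha_schedule, cluster_centers, cluster_supcon_loss,
                     instance_supcon_loss)
from .model import EncoderConfig, SupConNet, build_network, classify, encode_project

__all__ = ["TrainConfig", "FitResult", "TrainedModel", "pretrain_representation",
           "train_classifier", "fit_two_stage", "kfold_ensemble", "predict_ensemble"]


@dataclass
class TrainConfig:
    """All hyperparameters of the two-stage procedure.

    ``warmup`` defaults to ceil(0.2 * epochs): the cluster-level term
    switches on after a fifth of stage-1 training.  ``with_supcon`` off
    selects the cross-entropy-only baseline.
    """

    batch_size: int = 32
    epochs: int = 30
    warmup: int | None = None
    tau: float = 0.1
    augment: AugmentationSpec = field(default_factory=AugmentationSpec)
    bank_capacity: int = 16
    lr: float = 1e-3
    stage2_lr: float = 1e-3
    stage2_epochs: int = 100
    baseline_epochs: int | None = None  # CE-only ablation; defaults to `epochs`
    k_folds: int = 5
    seed: int = 0
    with_supcon: bool = True
    reduction: str = "sum"
    renormalize_centers: bool = False
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    @property
    def n_warmup(self) -> int:
        return math.ceil(0.2 * self.epochs) if self.warmup is None else self.warmup

    @property
    def n_baseline_epochs(self) -> int:
        return self.epochs if self.baseline_epochs is None else self.baseline_epochs

    def validate(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 for contrastive training")
        if self.epochs < 1 or not (0 <= self.n_warmup <= self.epochs):
            raise ValueError("need 1 <= epochs and 0 <= warmup <= epochs")
        self.augment.validate()
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "augment" in kwargs:
            kwargs["augment"] = AugmentationSpec(**kwargs["augment"])
        if "encoder" in kwargs:
            enc = dict(kwargs["encoder"])
            for key in ("block_filters", "kernel_sizes"):
                if key in enc:
                    enc[key] = tuple(enc[key])
            kwargs["encoder"] = EncoderConfig(**enc)
        return cls(**kwargs)


@dataclass
class TrainedModel:
    """A usable classifier: network + the normalization stats it was fit with."""

    net: SupConNet
    norm_stats: tuple[np.ndarray, np.ndarray]
    class_names: list[str]

    def _normalize(self, values: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
        mean, std = self.norm_stats
        x = (np.asarray(values, dtype=float) - mean[None, :, None]) / std[None, :, None]
        if mask is not None:
            x = np.where(np.asarray(mask).astype(bool), x, 0.0)
        return x

    def predict_proba(self, values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        self.net.eval()
        return classify(self.net, self._normalize(values, mask), mask)

    def predict(self, values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        return np.argmax(self.predict_proba(values, mask), axis=1)

    def features(self, values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        self.net.eval()
        return self.net.encode(self.net._prep(self._normalize(values, mask), mask)).data

    def embeddings(self, values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        self.net.eval()
        return encode_project(self.net, self._normalize(values, mask), mask).data


@dataclass
class FitResult:
    model: TrainedModel
    trace: list[dict] = field(default_factory=list)  # stage-1 per-epoch record
    stage2_trace: list[dict] = field(default_factory=list)
    fold_id: int | None = None
    val_accuracy: float | None = None


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator, drop_last: bool):
    perm = rng.permutation(n)
    end = n - (n % batch_size) if drop_last else n
    for start in range(0, end, batch_size):
        idx = perm[start : start + batch_size]
        if len(idx) > 0:
            yield idx


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    logprob = shift - shift.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(Tensor(onehot) * logprob).sum() * (1.0 / len(labels))


def pretrain_representation(ds: MtscDataset, cfg: TrainConfig) -> FitResult:
    """Stage 1: contrastive pre-training of encoder + projection head."""
    cfg.validate()
    if cfg.batch_size > ds.n:
        raise ValueError(f"batch_size {cfg.batch_size} exceeds dataset size {ds.n}")
    if ds.n_classes < 2:
        raise ValueError("contrastive pre-training needs at least 2 classes")
    enc_cfg = replace(cfg.encoder, in_channels=ds.m, n_classes=ds.n_classes)
    ds_n, stats = znormalize(ds)
    net = build_network(enc_cfg, seed=child_seed(cfg.seed, "init"))
    bank = ClusterMemoryBank(cfg.bank_capacity)
    opt = Adam(net.encoder_parameters() + net.head_parameters(), lr=cfg.lr)
    shuffle_rng = stream_rng(cfg.seed, "shuffle")
    aug_rng = stream_rng(cfg.seed, "augment")
    net.train()
    trace: list[dict] = []
    batch_counter = 0
    for epoch in range(1, cfg.epochs + 1):
        alpha = alpha_schedule(epoch, cfg.n_warmup)
        ins_sum = clus_sum = 0.0
        n_anchors = skipped_total = 0
        for idx in _iter_batches(ds_n.n, cfg.batch_size, shuffle_rng, drop_last=True):
            x, mask, labels = ds_n.values[idx], ds_n.mask[idx], ds_n.labels[idx]
            x_s, x_t = make_views(x, cfg.augment, mask, aug_rng)
            z_s = encode_project(net, x_s, mask)
            z_t = encode_project(net, x_t, mask)
            centers = cluster_centers(z_t.data, labels, cfg.renormalize_centers)
            bank.update(centers, batch_counter)
            per_ins, loss = instance_supcon_loss(z_s, z_t, labels, cfg.tau)
            ins_sum += per_ins.sum()
            n_anchors += len(idx)
            if alpha:
                per_clus, clus_total, skipped = cluster_supcon_loss(
                    z_s, labels, bank, cfg.tau)
                loss = loss + clus_total
                clus_sum += per_clus.sum()
                skipped_total += skipped
            else:
                skipped_total += len(idx)
            if cfg.reduction == "mean":
                loss = loss * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_counter += 1
        trace.append(dict(epoch=epoch, alpha=alpha,
                          instance_loss=ins_sum / max(n_anchors, 1),
                          cluster_loss=clus_sum / max(n_anchors, 1),
                          skipped_anchors=skipped_total))
    model = TrainedModel(net, stats, list(ds.class_names))
    return FitResult(model=model, trace=trace)


def _encode_features(net: SupConNet, values: np.ndarray, mask: np.ndarray | None,
                     chunk: int = 128) -> np.ndarray:
    net.eval()
    out = []
    for start in range(0, len(values), chunk):
        sl = slice(start, start + chunk)
        m = mask[sl] if mask is not None else None
        out.append(net.encode(net._prep(values[sl], m)).data)
    return np.concatenate(out, axis=0)


def train_classifier(ds: MtscDataset, pretrained: FitResult | None,
                     cfg: TrainConfig) -> FitResult:
    """Stage 2, or the CE-only baseline when ``cfg.with_supcon`` is off.

    With a pretrained result: the encoder is frozen (its weights are
    bit-identical before and after) and only the classifier MLP is
    trained, full-batch, on the pooled features.  Without: a fresh
    encoder + classifier are trained jointly with cross-entropy.
    """
    cfg.validate()
    if cfg.with_supcon:
        if pretrained is None:
            raise ValueError("with_supcon=True requires a pretrained representation")
        model = pretrained.model
        if model.net.cfg.in_channels != ds.m:
            raise ValueError("checkpoint channel count does not match dataset")
        if model.net.cfg.n_classes != ds.n_classes:
            raise ValueError("checkpoint class count does not match dataset")
        net = model.net
        x = model._normalize(ds.values, ds.mask)
        h = _encode_features(net, x, ds.mask)
        h_t = Tensor(h)
        opt = Adam(net.classifier_parameters(), lr=cfg.stage2_lr)
        trace = []
        for epoch in range(1, cfg.stage2_epochs + 1):
            logits = net.clf2(net.clf1(h_t).relu())
            loss = _cross_entropy(logits, ds.labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(dict(epoch=epoch, loss=float(loss.data)))
        return FitResult(model=model, trace=list(pretrained.trace), stage2_trace=trace)

    # ---- ablation baseline: joint cross-entropy training from scratch ----
    enc_cfg = replace(cfg.encoder, in_channels=ds.m, n_classes=ds.n_classes)
    ds_n, stats = znormalize(ds)
    net = build_network(enc_cfg, seed=child_seed(cfg.seed, "baseline-init"))
    params = net.encoder_parameters() + net.classifier_parameters()
    opt = Adam(params, lr=cfg.lr)
    rng = stream_rng(cfg.seed, "baseline-shuffle")
    trace = []
    for epoch in range(1, cfg.n_baseline_epochs + 1):
        net.train()
        epoch_loss, n_seen = 0.0, 0
        for idx in _iter_batches(ds_n.n, cfg.batch_size, rng, drop_last=False):
            logits = net.classifier_logits(net.encode(net._prep(
                ds_n.values[idx], ds_n.mask[idx])))
            loss = _cross_entropy(logits, ds_n.labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            n_seen += len(idx)
        trace.append(dict(epoch=epoch, loss=epoch_loss / max(n_seen, 1)))
    model = TrainedModel(net, stats, list(ds.class_names))
    return FitResult(model=model, stage2_trace=trace)


def fit_two_stage(ds: MtscDataset, cfg: TrainConfig) -> FitResult:
    """Full pipeline: contrastive pre-training then classifier (or baseline)."""
    if cfg.with_supcon:
        pre = pretrain_representation(ds, cfg)
        return train_classifier(ds, pre, cfg)
    return train_classifier(ds, None, cfg)


def kfold_ensemble(ds_train: MtscDataset, cfg: TrainConfig) -> list[FitResult]:
    """One full two-stage model per stratified fold, with fold accuracies."""
    from sklearn.model_selection import StratifiedKFold

    if cfg.k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    counts = np.bincount(ds_train.labels, minlength=ds_train.n_classes)
    for k, cnt in enumerate(counts):
        if cnt < cfg.k_folds:
            raise ValueError(f"class {ds_train.class_names[k]!r} has {cnt} members, "
                             f"fewer than k_folds={cfg.k_folds}")
    skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True,
                          random_state=child_seed(cfg.seed, "folds") % (2 ** 31))
    results = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(ds_train.values, ds_train.labels)):
        fold_cfg = replace(cfg, seed=child_seed(cfg.seed, f"fold{fold}"))
        res = fit_two_stage(ds_train.subset(tr_idx), fold_cfg)
        va = ds_train.subset(va_idx)
        pred = res.model.predict(va.values, va.mask)
        res.fold_id = fold
        res.val_accuracy = float((pred == va.labels).mean())
        results.append(res)
    return results


def predict_ensemble(models: list[TrainedModel], values: np.ndarray,
                     mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of the models' softmax outputs, then argmax.

    Ties break toward the lowest class id.  All models must share one
    class mapping.
    """
    if not models:
        raise ValueError("no models given")
    names = models[0].class_names
    for m in models[1:]:
        if m.class_names != names:
            raise ValueError("models have inconsistent class mappings")
    probs = np.mean([m.predict_proba(values, mask) for m in models], axis=0)
    return np.argmax(probs, axis=1), probs
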