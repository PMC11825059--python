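"""Instance-level and cluster-level supervised contrastive losses.

Instance level: each source-view anchor is contrasted against all N
target-view embeddings of the batch (the anchor's own target view is a
positive, so every anchor has at least one positive).  Cluster level:
the anchor is contrasted against the historical per-class cluster
centers held in the memory bank.  The combined objective sums the two
over anchors, with the cluster term gated off during the warm-up epochs.

All softmax denominators are computed with a subtracted per-anchor max
logit (log-sum-exp stabilization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .bank import ClusterMemoryBank
from .model import EmbeddingBatch

__all__ = ["LossConfig", "instance_supcon_loss", "cluster_centers",
           "cluster_supcon_loss", "alpha_schedule", "combined_loss"]


@dataclass
class LossConfig:
    tau: float = 0.1
    warmup_epochs: int = 0
    reduction: str = "sum"  # "sum" (per the objective) or "mean"
    renormalize_centers: bool = False

    def validate(self) -> None:
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


def _row_log_softmax(logits: Tensor) -> Tensor:
    shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    return shift - shift.exp().sum(axis=1, keepdims=True).log()


def _weighted_nll(logprob: Tensor, weights: np.ndarray) -> tuple[Tensor, Tensor]:
    """Per-anchor -(weights * logprob).sum(1) and its sum."""
    per_anchor = -(Tensor(weights) * logprob).sum(axis=1)
    return per_anchor, per_anchor.sum()


def instance_supcon_loss(z_source, z_target=None, labels=None, tau: float = 0.1
                         ) -> tuple[np.ndarray, Tensor]:
    """Instance-level supervised contrastive loss.

    For anchor k: the comparison set is all N target embeddings; the
    positive set is the targets sharing the anchor's label (including
    k itself); the per-anchor loss averages the negative log softmax
    probability over positives.  Accepts an ``EmbeddingBatch`` or the
    (z_source, z_target, labels) triple, as arrays or Tensors.  Returns
    (per-anchor losses as a plain array, differentiable total).
    """
    if isinstance(z_source, EmbeddingBatch):
        z_source, z_target, labels = z_source.z_source, z_source.z_target, z_source.labels
    zs, zt = as_tensor(z_source), as_tensor(z_target)
    labels = np.asarray(labels)
    n = zs.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    logits = (zs @ zt.transpose()) * (1.0 / tau)
    logprob = _row_log_softmax(logits)
    pos = (labels[:, None] == labels[None, :]).astype(float)
    weights = pos / pos.sum(axis=1, keepdims=True)
    per_anchor, total = _weighted_nll(logprob, weights)
    return per_anchor.data.copy(), total


def cluster_centers(z_target: np.ndarray, labels,
                    renormalize: bool = False) -> list[tuple[int, np.ndarray]]:
    """Per-label arithmetic means of target embeddings, sorted by label.

    Centers are plain means — not re-normalized to the unit sphere by
    default (``renormalize`` opts in, since dot products with non-unit
    centers change the effective temperature of the cluster loss).
    """
    z = np.asarray(z_target, dtype=float)
    labels = np.asarray(labels)
    out = []
    for lab in np.unique(labels):
        center = z[labels == lab].mean(axis=0)
        if renormalize:
            center = center / max(np.linalg.norm(center), 1e-12)
        out.append((int(lab), center))
    return out


def cluster_supcon_loss(z_source, labels, bank: ClusterMemoryBank,
                        tau: float = 0.1) -> tuple[np.ndarray, Tensor, int]:
    """Cluster-level supervised contrastive loss against the memory bank.

    Anchors whose label has no center in the bank contribute 0 and are
    counted in the returned ``skipped`` diagnostic; an empty bank gives
    total 0 with every anchor skipped.
    """
    zs = as_tensor(z_source)
    labels = np.asarray(labels)
    n = zs.shape[0]
    if tau <= 0:
        raise ValueError("tau must be > 0")
    bank_labels, centers = bank.view()
    if len(bank_labels) == 0:
        return np.zeros(n), Tensor(0.0), n
    logits = (zs @ Tensor(centers.T)) * (1.0 / tau)
    logprob = _row_log_softmax(logits)
    pos = (labels[:, None] == bank_labels[None, :]).astype(float)
    counts = pos.sum(axis=1)
    skipped = int((counts == 0).sum())
    weights = np.divide(pos, counts[:, None], out=np.zeros_like(pos), where=counts[:, None] > 0)
    per_anchor, total = _weighted_nll(logprob, weights)
    return per_anchor.data.copy(), total, skipped


def alpha_schedule(epoch: int, warmup_epochs: int) -> int:
    """Cluster-term gate: 0 during warm-up (epoch <= N_w), 1 afterwards."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    return 0 if epoch <= warmup_epochs else 1


def combined_loss(batch: EmbeddingBatch, bank: ClusterMemoryBank,
                  tau: float, epoch: int, warmup_epochs: int) -> float:
    """L = sum_k [ L^ins_k + alpha * L^clus_k ], alpha from the schedule."""
    _, ins_total = instance_supcon_loss(batch.z_source, batch.z_target, batch.labels, tau)
    alpha = alpha_schedule(epoch, warmup_epochs)
    total = float(ins_total.data)
    if alpha:
        _, clus_total, _ = cluster_supcon_loss(batch.z_source, batch.labels, bank, tau)
        total += float(clus_total.data)
    return total
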