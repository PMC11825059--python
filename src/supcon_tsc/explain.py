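"""Grad-CAM time-step attribution for the 1D residual encoder.

The class score is the pre-softmax logit (the convention that avoids
vanishing gradients at saturated softmax).  Its gradient is taken with
respect to the final convolutional feature maps; each map's weight is
the gradient averaged over the temporal units (Z = l, no pooling
ambiguity since the encoder preserves length), and the relevance at
time t is the ReLU-clamped weighted sum of activations.  Attribution
runs through the stage-2 path: encoder + classifier, projection head
not involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .model import SupConNet
from .trainer import TrainedModel

__all__ = ["AttributionMap", "gradcam_weights", "gradcam_map", "attribute"]


@dataclass
class AttributionMap:
    """Per-time-step non-negative relevance for one case and one class."""

    relevance: np.ndarray  # (l,) >= 0
    class_id: int
    case_id: int | None = None

    def __post_init__(self):
        self.relevance = np.asarray(self.relevance, dtype=float)
        if self.relevance.ndim != 1:
            raise ValueError("relevance must be a 1-D time profile")
        if (self.relevance < 0).any():
            raise ValueError("relevance must be non-negative")

    def scaled(self) -> np.ndarray:
        """Min-max scaled copy in [0, 1] for display (raw map unchanged)."""
        r = self.relevance
        span = r.max() - r.min()
        return (r - r.min()) / span if span > 0 else np.zeros_like(r)


def gradcam_weights(gradients: np.ndarray) -> np.ndarray:
    """Per-map weights: the (K, l) logit gradients averaged over time."""
    g = np.asarray(gradients, dtype=float)
    if g.ndim != 2:
        raise ValueError("gradients must be (K, l)")
    return g.mean(axis=1)


def gradcam_map(activations: np.ndarray, weights: np.ndarray,
                class_id: int = 0, case_id: int | None = None) -> AttributionMap:
    """relevance(t) = ReLU( sum_k w_k * A_k(t) )."""
    a = np.asarray(activations, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.ndim != 2 or w.shape != (a.shape[0],):
        raise ValueError("activations (K, l) and weights (K,) must agree")
    return AttributionMap(np.maximum(w @ a, 0.0), class_id=class_id, case_id=case_id)


def attribute(model: TrainedModel | SupConNet, x: np.ndarray, class_id: int,
              mask: np.ndarray | None = None, case_id: int | None = None
              ) -> AttributionMap:
    """Grad-CAM attribution of one case toward one class.

    ``x`` is a single (m, l) case; a ``TrainedModel`` applies its stored
    normalization first, a bare network assumes pre-normalized input.
    """
    if mask is not None:
        mask = np.asarray(mask)[None]
    if isinstance(model, TrainedModel):
        net = model.net
        x = model._normalize(np.asarray(x, dtype=float)[None], mask)
    else:
        net = model
        x = np.asarray(x, dtype=float)[None]
    if class_id < 0 or class_id >= net.cfg.n_classes:
        raise ValueError(f"class_id {class_id} out of range")
    net.eval()
    xt = net._prep(Tensor(x), mask)
    maps = net.feature_maps(xt)  # (1, K, l), retained in the graph
    h = maps.mean(axis=2)
    logits = net.classifier_logits(h)
    onehot = np.zeros(logits.shape)
    onehot[0, class_id] = 1.0
    score = (logits * Tensor(onehot)).sum()
    for p in net.parameters():
        p.grad = None
    score.backward()
    grads = maps.grad[0]  # (K, l)
    weights = gradcam_weights(grads)
    amap = gradcam_map(maps.data[0], weights, class_id=class_id, case_id=case_id)
    for p in net.parameters():
        p.grad = None
    return amap
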