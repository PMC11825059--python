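"""Jittering augmentation: the strong (source) and weak (target) views.

The method relies on a single augmentation family — additive Gaussian
noise, i.i.d. across channels and time — applied with high variance for
the source branch and low variance for the target branch.  No cropping,
warping or permutation: the representation is learned without those
inductive biases.  Masked (padded/missing) positions are never jittered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentationSpec", "jitter", "make_views"]


@dataclass
class AugmentationSpec:
    """Noise scales of the two views, on z-normalized channels.

    sigma_strong is the source-view jitter sd, sigma_weak the target-view
    sd; the defaults keep them an order of magnitude apart to
    operationalize "high-variance" vs "low-variance".
    """

    sigma_strong: float = 0.5
    sigma_weak: float = 0.05

    def validate(self) -> None:
        if self.sigma_weak < 0 or self.sigma_strong <= 0:
            raise ValueError("need sigma_strong > 0 and sigma_weak >= 0")
        if self.sigma_strong < self.sigma_weak:
            raise ValueError("sigma_strong must be >= sigma_weak")


def jitter(x: np.ndarray, sigma: float, mask: np.ndarray | None = None,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """x + N(0, sigma^2) on observed entries; masked entries untouched."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    x = np.asarray(x, dtype=float)
    if sigma == 0:
        return x.copy()
    if rng is None:
        rng = np.random.default_rng()
    noise = rng.normal(0.0, sigma, x.shape)
    if mask is not None:
        noise = noise * np.asarray(mask)
    return x + noise


def make_views(x: np.ndarray, spec: AugmentationSpec,
               mask: np.ndarray | None = None,
               rng: np.random.Generator | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """(strong source view, weak target view) with independent noise draws."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng()
    x_strong = jitter(x, spec.sigma_strong, mask, rng)
    x_weak = jitter(x, spec.sigma_weak, mask, rng)
    return x_strong, x_weak
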