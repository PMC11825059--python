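"""Class-structured synthetic multivariate time series and embedding fixtures.

The generator emulates the statistical structure the contrastive method
assumes: each class has a per-channel motif (a mixture of sinusoids with
class-specific frequencies and phases), classes can be blended toward a
shared motif to raise inter-class similarity, classes can contain several
sub-cluster "modes" to create intra-class multimodality, cases carry
additive Gaussian amplitude noise, and a fraction of cases can be
truncated to exercise padding and masking.  It makes no attempt to mimic
real physiological waveforms (exercise bouts, recovery kinetics) — only
the geometry (within-class spread, between-class overlap) that the
instance- and cluster-level losses respond to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import stream_rng
from .io_ts import MtscDataset, pad_and_mask
from .model import EmbeddingBatch

__all__ = ["SyntheticSpec", "make_mtsc", "class_motifs", "make_embedding_fixture",
           "make_localized_mtsc"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dataset generator.

    intra_var is the sd of additive Gaussian noise on each observed point
    (within-class spread); inter_sim in [0, 1) blends every class motif
    toward one shared motif (between-class similarity); n_modes_per_class
    creates sub-clusters with distinct motif variants inside each class;
    ragged_frac truncates that fraction of cases to a random length in
    [l/2, l) to exercise padding.
    """

    n_classes: int = 2
    n_per_class: int = 50
    m: int = 3
    l: int = 64
    intra_var: float = 0.3
    inter_sim: float = 0.0
    n_modes_per_class: int = 1
    ragged_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2 or self.n_per_class < 1 or self.m < 1 or self.l < 2:
            raise ValueError("invalid synthetic spec sizes")
        if not (0.0 <= self.inter_sim < 1.0):
            raise ValueError("inter_sim must be in [0, 1)")
        if self.intra_var < 0 or not (0.0 <= self.ragged_frac <= 1.0):
            raise ValueError("invalid noise/ragged parameters")
        if self.n_modes_per_class < 1:
            raise ValueError("n_modes_per_class must be >= 1")


def class_motifs(spec: SyntheticSpec) -> np.ndarray:
    """Base motifs, shape (n_classes, n_modes, m, l), deterministic in seed.

    Each (class, mode, channel) motif is a sum of two sinusoids whose
    frequencies and phases are drawn per class (and perturbed per mode),
    then blended toward a class-independent shared motif by inter_sim.
    """
    rng = stream_rng(spec.seed, "motifs")
    t = np.linspace(0.0, 1.0, spec.l)
    shared = np.empty((spec.m, spec.l))
    for j in range(spec.m):
        f1, f2 = rng.uniform(1.0, 6.0, 2)
        p1, p2 = rng.uniform(0.0, 2 * np.pi, 2)
        shared[j] = np.sin(2 * np.pi * f1 * t + p1) + 0.5 * np.sin(2 * np.pi * f2 * t + p2)
    motifs = np.empty((spec.n_classes, spec.n_modes_per_class, spec.m, spec.l))
    for k in range(spec.n_classes):
        for j in range(spec.m):
            f1, f2 = rng.uniform(1.0, 6.0, 2)
            p1, p2 = rng.uniform(0.0, 2 * np.pi, 2)
            for mode in range(spec.n_modes_per_class):
                # modes shift phase and modulate the secondary frequency
                dp = 0.0 if mode == 0 else rng.uniform(0.5 * np.pi, 1.5 * np.pi)
                df = 0.0 if mode == 0 else rng.uniform(0.5, 2.0)
                base = (np.sin(2 * np.pi * f1 * t + p1 + dp)
                        + 0.5 * np.sin(2 * np.pi * (f2 + df) * t + p2))
                motifs[k, mode, j] = (1 - spec.inter_sim) * base + spec.inter_sim * shared[j]
    return motifs


def make_mtsc(spec: SyntheticSpec) -> MtscDataset:
    """Generate a labelled dataset satisfying all MtscDataset invariants."""
    spec.validate()
    motifs = class_motifs(spec)
    rng = stream_rng(spec.seed, "cases")
    n = spec.n_classes * spec.n_per_class
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    modes = rng.integers(0, spec.n_modes_per_class, size=n)
    cases = []
    for i in range(n):
        x = motifs[labels[i], modes[i]].copy()
        if spec.intra_var > 0:
            x = x + rng.normal(0.0, spec.intra_var, x.shape)
        if spec.ragged_frac > 0 and rng.random() < spec.ragged_frac:
            li = int(rng.integers(spec.l // 2, spec.l))
            x = x[:, :li]
        cases.append(x)
    order = rng.permutation(n)
    values, mask = pad_and_mask([cases[i] for i in order])
    ds = MtscDataset(values, labels[order], mask,
                     class_names=[f"class_{k}" for k in range(spec.n_classes)])
    return ds.finalize()


def make_localized_mtsc(n_per_class: int, m: int, l: int,
                        window: tuple[int, int] = (20, 30),
                        amplitude: float = 1.5, noise_sd: float = 0.3,
                        seed: int = 0) -> MtscDataset:
    """Two classes identical except inside ``window`` = [t0, t1).

    Both classes share one smooth background signal per channel; class 1
    additionally carries a bump (half-sine) of the given amplitude inside
    the window.  Used to probe whether time-step attribution localizes
    the only discriminative region.
    """
    rng = stream_rng(seed, "localized")
    t = np.linspace(0.0, 1.0, l)
    background = np.empty((m, l))
    for j in range(m):
        f = rng.uniform(1.0, 3.0)
        p = rng.uniform(0.0, 2 * np.pi)
        background[j] = np.sin(2 * np.pi * f * t + p)
    t0, t1 = window
    bump = np.zeros(l)
    bump[t0:t1] = amplitude * np.sin(np.linspace(0.0, np.pi, t1 - t0))
    cases, labels = [], []
    for k in (0, 1):
        for _ in range(n_per_class):
            x = background + rng.normal(0.0, noise_sd, (m, l))
            if k == 1:
                x = x + bump[None, :]
            cases.append(x)
            labels.append(k)
    order = rng.permutation(len(cases))
    values, mask = pad_and_mask([cases[i] for i in order])
    ds = MtscDataset(values, np.array(labels)[order], mask,
                     class_names=["baseline", "bump"])
    return ds.finalize()


def make_embedding_fixture(n: int, d: int, n_classes: int,
                           separation: float, seed: int = 0) -> EmbeddingBatch:
    """Unit-norm embedding pairs clustered by class on the hypersphere.

    Class axes are orthonormal; each case's latent point (and its paired
    source/target views) is the class axis perturbed by isotropic noise of
    scale 1/separation, then renormalized.  separation = inf gives exact
    class axes, so same-class dot products are 1 and cross-class 0.
    """
    if n < n_classes or d < 2 or d < n_classes:
        raise ValueError("need n >= n_classes and d >= max(2, n_classes)")
    rng = stream_rng(seed, "embfix")
    basis, _ = np.linalg.qr(rng.normal(size=(d, d)))
    axes = basis[:, :n_classes].T  # orthonormal class axes
    labels = np.arange(n) % n_classes
    sigma = 0.0 if np.isinf(separation) else 1.0 / separation

    def draw(center):
        v = center + sigma * rng.normal(size=d)
        return v / np.linalg.norm(v)

    z_s = np.empty((n, d))
    z_t = np.empty((n, d))
    for i in range(n):
        latent = draw(axes[labels[i]])
        z_s[i] = draw(latent)
        z_t[i] = draw(latent)
    return EmbeddingBatch(z_s, z_t, labels)
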