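"""Desk-scale validation studies run entirely on synthetic data.

Each study fixes its dataset conditions (sample sizes, noise levels,
class-overlap) and reruns the full pipeline over several seeds; they are
used by the acceptance checks and the example scripts.  Architecture
sizes here are deliberately smaller than the package defaults so a study
completes in minutes on one CPU; the localization study additionally
uses short kernels so the encoder's receptive field is commensurate with
the 10-step discriminative window.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.metrics import silhouette_score
from sklearn.model_selection import train_test_split

from ._rng import child_seed
from .explain import attribute
from .model import EncoderConfig
from .synthetic import SyntheticSpec, make_localized_mtsc, make_mtsc
from .trainer import TrainConfig, fit_two_stage

__all__ = ["study_encoder_config", "study_train_config", "synthetic_recovery_study",
           "ablation_direction_study", "localization_study"]


def study_encoder_config(kernel_sizes=(8, 5, 3)) -> EncoderConfig:
    return EncoderConfig(block_filters=(16, 32, 32), kernel_sizes=kernel_sizes,
                         proj_dim=32, proj_hidden=64, clf_hidden=64)


def study_train_config(seed: int, **kw) -> TrainConfig:
    defaults = dict(batch_size=30, epochs=15, tau=0.1, stage2_epochs=100,
                    encoder=study_encoder_config(), seed=seed)
    defaults.update(kw)
    return TrainConfig(**defaults)


def _split(ds, seed, test_size=0.2):
    idx = np.arange(ds.n)
    tr, te = train_test_split(idx, test_size=test_size, stratify=ds.labels,
                              random_state=seed % (2 ** 31))
    return tr, te


def synthetic_recovery_study(base_seed: int = 0, n_seeds: int = 5) -> dict:
    """Held-out accuracy and embedding silhouette on the 3-class generator
    dataset (n=150, m=3, l=64, intra_var 0.3, inter_sim 0.2), per seed."""
    accs, sil_emb, sil_raw = [], [], []
    for i in range(n_seeds):
        spec = SyntheticSpec(n_classes=3, n_per_class=50, m=3, l=64, intra_var=0.3,
                             inter_sim=0.2, seed=child_seed(base_seed, f"data{i}"))
        ds = make_mtsc(spec)
        cfg = study_train_config(seed=child_seed(base_seed, f"train{i}"))
        tr, te = _split(ds, child_seed(base_seed, f"split{i}"))
        res = fit_two_stage(ds.subset(tr), cfg)
        pred = res.model.predict(ds.values[te], ds.mask[te])
        accs.append(float((pred == ds.labels[te]).mean()))
        emb = res.model.embeddings(ds.values[te], ds.mask[te])
        sil_emb.append(float(silhouette_score(emb, ds.labels[te])))
        sil_raw.append(float(silhouette_score(ds.values[te].reshape(len(te), -1),
                                              ds.labels[te])))
    return dict(accuracies=accs, median_accuracy=float(np.median(accs)),
                silhouette_embedding=sil_emb, silhouette_raw=sil_raw,
                median_silhouette_gain=float(np.median(np.array(sil_emb)
                                                       - np.array(sil_raw))))


def ablation_direction_study(base_seed: int = 0, n_seeds: int = 5) -> dict:
    """Contrastive pre-training vs cross-entropy-only on multi-modal classes
    (n_modes_per_class=2, inter_sim=0.5): per-seed win-or-tie of the full model."""
    rows = []
    for i in range(n_seeds):
        spec = SyntheticSpec(n_classes=3, n_per_class=50, m=3, l=64, intra_var=0.3,
                             inter_sim=0.5, n_modes_per_class=2,
                             seed=child_seed(base_seed, f"abl-data{i}"))
        ds = make_mtsc(spec)
        cfg = study_train_config(seed=child_seed(base_seed, f"abl-train{i}"))
        tr, te = _split(ds, child_seed(base_seed, f"abl-split{i}"))
        res_on = fit_two_stage(ds.subset(tr), cfg)
        acc_on = float((res_on.model.predict(ds.values[te], ds.mask[te])
                        == ds.labels[te]).mean())
        res_off = fit_two_stage(ds.subset(tr), replace(cfg, with_supcon=False))
        acc_off = float((res_off.model.predict(ds.values[te], ds.mask[te])
                         == ds.labels[te]).mean())
        rows.append(dict(acc_with=acc_on, acc_without=acc_off,
                         win_or_tie=acc_on >= acc_off))
    return dict(per_seed=rows, wins=int(sum(r["win_or_tie"] for r in rows)),
                n_seeds=n_seeds)


def localization_study(base_seed: int = 0, n_seeds: int = 5,
                       window: tuple[int, int] = (20, 30)) -> dict:
    """Grad-CAM relevance inside vs outside the only discriminative window
    of a two-class dataset (classes differ solely in t in [20, 30))."""
    t0, t1 = window
    ratios, accs = [], []
    for i in range(n_seeds):
        ds = make_localized_mtsc(n_per_class=60, m=3, l=64, window=window,
                                 seed=child_seed(base_seed, f"loc-data{i}"))
        cfg = study_train_config(seed=child_seed(base_seed, f"loc-train{i}"),
                                 encoder=study_encoder_config(kernel_sizes=(5, 3, 3)))
        tr, te = _split(ds, child_seed(base_seed, f"loc-split{i}"), test_size=0.25)
        res = fit_two_stage(ds.subset(tr), cfg)
        pred = res.model.predict(ds.values[te], ds.mask[te])
        accs.append(float((pred == ds.labels[te]).mean()))
        inside, outside = [], []
        for j in te:
            r = attribute(res.model, ds.values[j], int(ds.labels[j])).relevance
            inside.append(r[t0:t1].mean())
            outside.append(np.concatenate([r[:t0], r[t1:]]).mean())
        ratios.append(float(np.mean(inside) / max(np.mean(outside), 1e-12)))
    return dict(inside_outside_ratios=ratios,
                median_ratio=float(np.median(ratios)),
                accuracies=accs)
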