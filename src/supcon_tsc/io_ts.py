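"""Reading and preparing multivariate time-series classification datasets.

Supports the sktime/UEA ".ts" dialect (hand-written reader: header lines
``@problemName`` … ``@classLabel``, then ``@data`` with ':'-separated
dimensions per case and the class label last), flat ARFF (univariate rows
with a class attribute; the relational multivariate ARFF encoding is not
supported), and a long CSV format (case_id, channel, t, value, label).

Variable-length series are padded to the longest case; a binary mask
records observed (1) versus padded-or-missing (0) positions.  Missing
interior observations (NaN or '?') also get mask 0.  After
``MtscDataset.finalize`` every masked position holds the fill value 0,
never NaN, so downstream convolutions see inert inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MtscDataset", "ParseError", "read_ts_file", "write_ts_file",
           "read_csv_long", "pad_and_mask", "znormalize", "save_npz", "load_npz"]

FILL_VALUE = 0.0


class ParseError(ValueError):
    """Malformed dataset file; message names the offending line."""


@dataclass
class MtscDataset:
    """n cases x m channels x l time steps with labels and observation mask."""

    values: np.ndarray  # (n, m, l) float
    labels: np.ndarray  # (n,) int in 0..c-1
    mask: np.ndarray  # (n, m, l) binary
    class_names: list[str] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.mask = np.asarray(self.mask)
        if self.values.ndim != 3:
            raise ValueError("values must be (n, m, l)")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal number of cases")
        if not self.class_names:
            self.class_names = [str(k) for k in range(int(self.labels.max(initial=-1)) + 1)]
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels must index class_names")
        if not self.channel_names:
            self.channel_names = [f"ch{j}" for j in range(self.values.shape[1])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def l(self) -> int:
        return self.values.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def finalize(self, fill: float = FILL_VALUE) -> "MtscDataset":
        """Replace every masked position with the sentinel fill value."""
        values = np.where(self.mask.astype(bool), self.values, fill)
        return MtscDataset(values, self.labels, self.mask,
                           list(self.class_names), list(self.channel_names))

    def subset(self, index) -> "MtscDataset":
        index = np.asarray(index)
        return MtscDataset(self.values[index], self.labels[index], self.mask[index],
                           list(self.class_names), list(self.channel_names))


def pad_and_mask(ragged: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pad per-case (m, l_i) arrays to a common length and build the mask.

    Positions beyond a case's own length, and interior NaNs, get mask 0;
    padded/missing values are NaN until ``finalize`` replaces them.
    """
    if not ragged:
        raise ValueError("empty case list")
    ragged = [np.atleast_2d(np.asarray(r, dtype=float)) for r in ragged]
    m = ragged[0].shape[0]
    for i, r in enumerate(ragged):
        if r.shape[0] != m:
            raise ValueError(f"case {i} has {r.shape[0]} channels, expected {m}")
        if r.shape[1] < 1:
            raise ValueError(f"case {i} has zero length")
    l_max = max(r.shape[1] for r in ragged)
    n = len(ragged)
    values = np.full((n, m, l_max), np.nan)
    mask = np.zeros((n, m, l_max), dtype=np.int8)
    for i, r in enumerate(ragged):
        li = r.shape[1]
        values[i, :, :li] = r
        mask[i, :, :li] = ~np.isnan(r)
        values[i, :, :li][np.isnan(r)] = np.nan
    return values, mask


def znormalize(ds: MtscDataset, stats: tuple[np.ndarray, np.ndarray] | None = None
               ) -> tuple[MtscDataset, tuple[np.ndarray, np.ndarray]]:
    """Per-channel standardization over observed positions only.

    Padded/missing positions are excluded from the statistics and set to
    the fill value 0 (the post-normalization channel mean) afterwards.
    Pass the returned ``stats`` to normalize a test split with training
    statistics.  A constant channel is protected by a std floor of 1e-8.
    """
    obs = ds.mask.astype(bool)
    if stats is None:
        mean = np.empty(ds.m)
        std = np.empty(ds.m)
        for j in range(ds.m):
            vals = ds.values[:, j, :][obs[:, j, :]]
            mean[j] = vals.mean() if vals.size else 0.0
            std[j] = vals.std() if vals.size else 1.0
        std = np.maximum(std, 1e-8)
    else:
        mean, std = stats
        if len(mean) != ds.m:
            raise ValueError("stats channel count does not match dataset")
    values = (ds.values - mean[None, :, None]) / std[None, :, None]
    values = np.where(obs, values, FILL_VALUE)
    out = MtscDataset(values, ds.labels, ds.mask, list(ds.class_names), list(ds.channel_names))
    return out, (np.asarray(mean, dtype=float), np.asarray(std, dtype=float))


# ----------------------------------------------------------------- .ts reader
def _parse_value(tok: str, lineno: int) -> float:
    tok = tok.strip()
    if tok in ("?", "", "NaN", "nan"):
        return np.nan
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"line {lineno}: cannot parse value {tok!r}") from None


def _label_map(names: list[str]) -> dict[str, int]:
    return {name: i for i, name in enumerate(sorted(names))}


def read_ts_file(path, split_tag: str = "train",
                 class_names: list[str] | None = None) -> MtscDataset:
    """Read a ".ts" (sktime dialect) or flat ARFF file into a dataset.

    Class names map to integer ids in sorted lexicographic order, fixed
    across splits; for a test split pass the training ``class_names`` so
    an unseen label is a parse error rather than a silent new class.
    """
    if split_tag not in ("train", "test"):
        raise ValueError("split_tag must be 'train' or 'test'")
    with open(path) as fh:
        lines = fh.readlines()

    header_classes: list[str] | None = None
    data_start = None
    is_arff = False
    arff_attrs: list[str] = []
    for idx, raw in enumerate(lines):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            is_arff = True
        elif low.startswith("@attribute"):
            parts = line.split(None, 2)
            if len(parts) < 3:
                raise ParseError(f"line {idx + 1}: malformed @attribute")
            arff_attrs.append(parts[1] + " " + parts[2])
            if "{" in parts[2]:
                header_classes = [c.strip().strip("'\"")
                                  for c in parts[2].strip().strip("{}").split(",")]
        elif low.startswith("@classlabel"):
            toks = line.split()
            if len(toks) < 2:
                raise ParseError(f"line {idx + 1}: malformed @classLabel")
            if toks[1].lower() == "true":
                header_classes = [t.strip("'\"") for t in toks[2:]]
        elif low.startswith("@data"):
            data_start = idx + 1
            break
        elif low.startswith("@"):
            continue  # @problemName, @univariate, @seriesLength, ...
        else:
            # bare file without @data marker: treat as data from here on
            data_start = idx
            break
    if data_start is None:
        raise ParseError("no @data section found")

    cases: list[np.ndarray] = []
    raw_labels: list[str] = []
    expected_m = None
    for off, raw in enumerate(lines[data_start:]):
        lineno = data_start + off + 1
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("%"):
            continue
        if is_arff and ":" not in line:
            toks = [t.strip() for t in line.split(",")]
            if len(toks) < 2:
                raise ParseError(f"line {lineno}: ARFF row needs values and a label")
            channels = [np.array([_parse_value(t, lineno) for t in toks[:-1]])]
            label = toks[-1].strip("'\"")
        else:
            parts = line.split(":")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected ':'-separated dimensions and label")
            label = parts[-1].strip().strip("'\"")
            channels = [np.array([_parse_value(t, lineno) for t in dim.split(",")])
                        for dim in parts[:-1]]
        if expected_m is None:
            expected_m = len(channels)
        elif len(channels) != expected_m:
            raise ParseError(f"line {lineno}: case has {len(channels)} channels, "
                             f"expected {expected_m}")
        cases.append(np.vstack([np.atleast_1d(ch) for ch in channels])
                     if len({len(c) for c in channels}) == 1
                     else _ragged_stack(channels))
        raw_labels.append(label)
    if not cases:
        raise ParseError("file contains no data rows")

    known = class_names if class_names is not None else header_classes
    if known is None:
        known = sorted(set(raw_labels))
    lmap = _label_map(list(known))
    labels = []
    for i, lab in enumerate(raw_labels):
        if lab not in lmap:
            raise ParseError(f"unknown class label {lab!r} in {split_tag} split (case {i})")
        labels.append(lmap[lab])
    values, mask = pad_and_mask(cases)
    ds = MtscDataset(values, np.array(labels), mask, class_names=sorted(known))
    return ds.finalize()


def _ragged_stack(channels: list[np.ndarray]) -> np.ndarray:
    l_max = max(len(c) for c in channels)
    out = np.full((len(channels), l_max), np.nan)
    for j, c in enumerate(channels):
        out[j, : len(c)] = c
    return out


def write_ts_file(path, ds: MtscDataset, problem_name: str = "dataset") -> None:
    """Write a dataset in the ".ts" dialect (interior NaNs as '?')."""
    with open(path, "w") as fh:
        fh.write(f"@problemName {problem_name}\n")
        fh.write("@timeStamps false\n")
        fh.write(f"@univariate {'true' if ds.m == 1 else 'false'}\n")
        fh.write("@classLabel true " + " ".join(ds.class_names) + "\n")
        fh.write("@data\n")
        for i in range(ds.n):
            dims = []
            for j in range(ds.m):
                row_mask = ds.mask[i, j].astype(bool)
                li = int(np.max(np.nonzero(row_mask)) + 1) if row_mask.any() else 1
                toks = []
                for t in range(li):
                    toks.append(repr(float(ds.values[i, j, t])) if row_mask[t] else "?")
                dims.append(",".join(toks))
            fh.write(":".join(dims) + ":" + ds.class_names[ds.labels[i]] + "\n")


def read_csv_long(path) -> MtscDataset:
    """Long CSV: columns case_id, channel, t, value, label."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"case_id", "channel", "t", "value", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"CSV must have columns {sorted(required)}")
    channels = sorted(df["channel"].unique())
    cases = []
    raw_labels = []
    for cid, grp in df.groupby("case_id", sort=True):
        per_ch = []
        for ch in channels:
            sub = grp[grp["channel"] == ch].sort_values("t")
            per_ch.append(sub["value"].to_numpy(dtype=float))
        cases.append(_ragged_stack(per_ch) if len({len(c) for c in per_ch}) > 1
                     else np.vstack(per_ch))
        labs = grp["label"].unique()
        if len(labs) != 1:
            raise ParseError(f"case {cid} has multiple labels")
        raw_labels.append(str(labs[0]))
    lmap = _label_map(sorted(set(raw_labels)))
    values, mask = pad_and_mask(cases)
    ds = MtscDataset(values, np.array([lmap[x] for x in raw_labels]), mask,
                     class_names=sorted(lmap), channel_names=[str(c) for c in channels])
    return ds.finalize()


def save_npz(path, ds: MtscDataset) -> None:
    """Cache a dataset as a single NPZ archive (values, mask, labels, names)."""
    np.savez(path, values=ds.values, mask=ds.mask, labels=ds.labels,
             class_names=np.array(ds.class_names), channel_names=np.array(ds.channel_names))


def load_npz(path) -> MtscDataset:
    with np.load(path, allow_pickle=False) as f:
        return MtscDataset(f["values"], f["labels"], f["mask"],
                           [str(s) for s in f["class_names"]],
                           [str(s) for s in f["channel_names"]])
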