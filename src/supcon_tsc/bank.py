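"""FIFO cluster memory bank of per-class centers across recent batches.

Capacity is counted in batch snapshots: at most ``capacity_batches``
distinct batch indices are retained (so at most capacity x n_labels
entries), and eviction is strictly oldest-batch-first.  Entries are plain
numpy arrays — deliberately detached from any gradient computation, so
consuming a bank view never back-propagates into the encoder weights
that produced historical centers.
"""

from __future__ import annotations

from collections import deque

import numpy as np

__all__ = ["ClusterMemoryBank", "bank_update", "bank_view"]


class ClusterMemoryBank:
    def __init__(self, capacity_batches: int = 16, dim: int | None = None):
        if capacity_batches < 1:
            raise ValueError("capacity_batches must be >= 1")
        self.capacity_batches = capacity_batches
        self.dim = dim
        # each snapshot: (batch_index, [(label, center), ...]) in insertion order
        self._snapshots: deque[tuple[int, list[tuple[int, np.ndarray]]]] = deque()

    def __len__(self) -> int:
        return sum(len(entries) for _, entries in self._snapshots)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def update(self, centers: list[tuple[int, np.ndarray]], batch_index: int) -> "ClusterMemoryBank":
        """Append a batch's centers; evict the oldest batch beyond capacity."""
        checked = []
        for label, center in centers:
            center = np.asarray(center, dtype=float)
            if center.ndim != 1:
                raise ValueError("centers must be 1-D vectors")
            if self.dim is None:
                self.dim = center.shape[0]
            elif center.shape[0] != self.dim:
                raise ValueError(f"center dim {center.shape[0]} != bank dim {self.dim}")
            checked.append((int(label), center.copy()))
        if not checked:  # empty update leaves the bank unchanged
            return self
        if self._snapshots and self._snapshots[-1][0] == batch_index:
            self._snapshots[-1][1].extend(checked)
        else:
            self._snapshots.append((batch_index, checked))
        while len(self._snapshots) > self.capacity_batches:
            self._snapshots.popleft()
        return self

    def view(self) -> tuple[np.ndarray, np.ndarray]:
        """(labels, centers) snapshot in insertion order; an isolated copy."""
        labels = [lab for _, entries in self._snapshots for lab, _ in entries]
        d = self.dim if self.dim is not None else 0
        if not labels:
            return np.empty(0, dtype=int), np.empty((0, d))
        centers = np.stack([c for _, entries in self._snapshots for _, c in entries])
        return np.array(labels, dtype=int), centers.copy()

    def reset(self) -> None:
        self._snapshots.clear()


def bank_update(bank: ClusterMemoryBank, centers, batch_index: int) -> ClusterMemoryBank:
    return bank.update(centers, batch_index)


def bank_view(bank: ClusterMemoryBank) -> tuple[np.ndarray, np.ndarray]:
    return bank.view()
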