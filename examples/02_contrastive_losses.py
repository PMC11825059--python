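"""The instance-level and cluster-level supervised contrastive losses.

Builds a synthetic embedding batch on the hypersphere, evaluates both
losses, and shows how the cluster memory bank feeds the cluster term.
"""

import numpy as np

from supcon_tsc import (ClusterMemoryBank, cluster_centers, cluster_supcon_loss,
                        combined_loss, instance_supcon_loss, make_embedding_fixture)

# well-separated classes: low loss expected
tight = make_embedding_fixture(n=16, d=8, n_classes=4, separation=8.0, seed=0)
per, total = instance_supcon_loss(tight, tau=0.1)
print(f"instance loss, well-separated embeddings: {float(total.data):.4f} "
      f"(mean per anchor {per.mean():.4f})")

# overlapping classes: higher loss
loose = make_embedding_fixture(n=16, d=8, n_classes=4, separation=1.0, seed=0)
per, total = instance_supcon_loss(loose, tau=0.1)
print(f"instance loss, overlapping embeddings:    {float(total.data):.4f} "
      f"(mean per anchor {per.mean():.4f})")

# cluster term: anchors vs per-class centers held in the FIFO bank
bank = ClusterMemoryBank(capacity_batches=16)
for batch_index in range(3):
    b = make_embedding_fixture(n=16, d=8, n_classes=4, separation=3.0,
                               seed=batch_index)
    bank.update(cluster_centers(b.z_target, b.labels), batch_index)
labels, centers = bank.view()
print(f"bank holds {len(labels)} centers from 3 batches, "
      f"labels {sorted({int(l) for l in labels})}")

per_c, total_c, skipped = cluster_supcon_loss(loose.z_source, loose.labels, bank, tau=0.1)
print(f"cluster loss against the bank: {float(total_c.data):.4f} (skipped anchors: {skipped})")

# combined objective: the cluster term is gated off during warm-up
for epoch in (1, 5):
    L = combined_loss(loose, bank, tau=0.1, epoch=epoch, warmup_epochs=3)
    print(f"epoch {epoch}: combined loss {L:.4f} "
          f"({'instance only (warm-up)' if epoch <= 3 else 'instance + cluster'})")
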