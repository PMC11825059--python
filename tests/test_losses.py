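"""Contrastive loss oracles: closed forms, brute-force double loops,
invariances and gradient directions."""

import numpy as np
import pytest

from supcon_tsc import (ClusterMemoryBank, alpha_schedule, cluster_centers,
                        cluster_supcon_loss, combined_loss, instance_supcon_loss,
                        make_embedding_fixture)
from supcon_tsc.autodiff import Tensor
from supcon_tsc.model import EmbeddingBatch


# ------------------------------------------------------------------ oracles
def naive_instance_loss(zs, zt, labels, tau):
    """Literal double-loop transcription of the instance-level objective."""
    n = len(labels)
    out = np.zeros(n)
    for k in range(n):
        pos = [p for p in range(n) if labels[p] == labels[k]]
        total = 0.0
        for p in pos:
            den = sum(np.exp(zs[k] @ zt[a] / tau) for a in range(n))
            total += np.log(np.exp(zs[k] @ zt[p] / tau) / den)
        out[k] = -total / len(pos)
    return out


def naive_cluster_loss(zs, labels, bank_labels, centers, tau):
    n = len(labels)
    out = np.zeros(n)
    skipped = 0
    for k in range(n):
        pos = [p for p in range(len(bank_labels)) if bank_labels[p] == labels[k]]
        if not pos:
            skipped += 1
            continue
        total = 0.0
        for p in pos:
            den = sum(np.exp(zs[k] @ centers[a] / tau) for a in range(len(bank_labels)))
            total += np.log(np.exp(zs[k] @ centers[p] / tau) / den)
        out[k] = -total / len(pos)
    return out, skipped


def random_unit(rng, n, d):
    z = rng.normal(size=(n, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)


# ----------------------------------------------------------- instance level
class TestInstanceLoss:
    def test_singleton_batch_is_zero(self):
        per, total = instance_supcon_loss([[1.0, 0.0]], [[0.0, 1.0]], [0], tau=0.3)
        assert per[0] == pytest.approx(0.0, abs=1e-12)
        assert float(total.data) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.05, 0.5, 1.0])
    def test_identical_same_label_pair_gives_log2(self, tau):
        v = np.array([[1.0, 0.0]])
        z = np.repeat(v, 2, axis=0)
        per, _ = instance_supcon_loss(z, z, [0, 0], tau=tau)
        np.testing.assert_allclose(per, np.log(2.0), atol=1e-9)

    def test_two_point_closed_form(self):
        """Anchor aligned with its positive, orthogonal negative, tau=1:
        per-anchor loss is softplus(-1) = log(1 + e^-1)."""
        zs = np.array([[1.0, 0.0], [0.0, 1.0]])
        zt = np.array([[1.0, 0.0], [0.0, 1.0]])
        per, _ = instance_supcon_loss(zs, zt, [0, 1], tau=1.0)
        assert per[0] == pytest.approx(np.log(1 + np.exp(-1.0)), abs=1e-9)
        assert per[0] == pytest.approx(0.313262, abs=1e-6)

    def test_matches_double_loop_on_random_batches(self):
        rng = np.random.default_rng(1234)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(1, 17))
            d = int(rng.integers(2, 9))
            c = int(rng.integers(1, 5))
            tau = float(rng.uniform(0.05, 1.0))
            labels = rng.integers(0, c, size=n)
            zs, zt = random_unit(rng, n, d), random_unit(rng, n, d)
            per, total = instance_supcon_loss(zs, zt, labels, tau=tau)
            ref = naive_instance_loss(zs, zt, labels, tau)
            worst = max(worst, np.abs(per - ref).max())
            assert float(total.data) == pytest.approx(ref.sum(), abs=1e-6)
        assert worst < 1e-6

    def test_permutation_invariance_of_total(self):
        rng = np.random.default_rng(5)
        zs, zt = random_unit(rng, 8, 4), random_unit(rng, 8, 4)
        labels = np.array([0, 1, 0, 2, 1, 2, 0, 1])
        _, t1 = instance_supcon_loss(zs, zt, labels, tau=0.2)
        perm = rng.permutation(8)
        _, t2 = instance_supcon_loss(zs[perm], zt[perm], labels[perm], tau=0.2)
        assert float(t1.data) == pytest.approx(float(t2.data), abs=1e-12)

    def test_monotone_in_anchor_positive_alignment(self):
        """Swapping an aligned positive for an orthogonal one raises the loss."""
        zs = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        zt_aligned = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        zt_swapped = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        la = [0, 1]
        _, t_good = instance_supcon_loss(zs, zt_aligned, la, tau=0.1)
        _, t_bad = instance_supcon_loss(zs, zt_swapped, la, tau=0.1)
        assert float(t_good.data) < float(t_bad.data)

    def test_gradient_signs_pull_positives_push_negatives(self):
        """d loss / d s_pos <= 0 and d loss / d s_neg >= 0 on 2-point setups."""
        def loss_of(sim_pos, sim_neg, tau=0.5):
            # anchor [1,0]; target similarities set directly on the circle
            zs = np.array([[1.0, 0.0], [0.0, 1.0]])
            zt = np.array([[sim_pos, np.sqrt(1 - sim_pos ** 2)],
                           [sim_neg, np.sqrt(1 - sim_neg ** 2)]])
            per, _ = instance_supcon_loss(zs, zt, [0, 1], tau=tau)
            return per[0]

        eps = 1e-5
        for sp, sn in [(0.9, 0.1), (0.5, -0.5), (0.2, 0.0)]:
            assert loss_of(sp + eps, sn) <= loss_of(sp - eps, sn) + 1e-12
            assert loss_of(sp, sn + eps) >= loss_of(sp, sn - eps) - 1e-12

    def test_autodiff_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(17)
        zs = random_unit(rng, 5, 3)
        zt = random_unit(rng, 5, 3)
        labels = np.array([0, 1, 0, 1, 0])
        t = Tensor(zs, requires_grad=True)
        _, total = instance_supcon_loss(t, zt, labels, tau=0.3)
        total.backward()
        eps, idx = 1e-6, (2, 1)
        zp, zm = zs.copy(), zs.copy()
        zp[idx] += eps
        zm[idx] -= eps
        fp = naive_instance_loss(zp, zt, labels, 0.3).sum()
        fm = naive_instance_loss(zm, zt, labels, 0.3).sum()
        assert t.grad[idx] == pytest.approx((fp - fm) / (2 * eps), rel=1e-5)


# ------------------------------------------------------------ cluster level
class TestClusterCenters:
    def test_single_member_center_is_itself(self):
        z = random_unit(np.random.default_rng(0), 3, 4)
        centers = cluster_centers(z, [2, 0, 1])
        assert [lab for lab, _ in centers] == [0, 1, 2]  # sorted by label
        np.testing.assert_allclose(dict(centers)[2], z[0])

    def test_mean_of_two(self):
        centers = cluster_centers(np.array([[1.0, 0.0], [0.0, 1.0]]), [0, 0])
        np.testing.assert_allclose(centers[0][1], [0.5, 0.5])

    def test_matches_bruteforce_means(self):
        rng = np.random.default_rng(3)
        z = random_unit(rng, 8, 5)
        labels = rng.integers(0, 3, 8)
        for lab, center in cluster_centers(z, labels):
            np.testing.assert_allclose(center, z[labels == lab].mean(axis=0), atol=1e-12)

    def test_renormalized_centers_are_unit(self):
        z = random_unit(np.random.default_rng(4), 6, 3)
        for _, c in cluster_centers(z, [0, 0, 1, 1, 1, 0], renormalize=True):
            assert np.linalg.norm(c) == pytest.approx(1.0, abs=1e-12)


class TestClusterLoss:
    def test_single_matching_entry_is_zero(self):
        bank = ClusterMemoryBank(4).update([(0, np.array([0.3, 0.4]))], 0)
        per, total, skipped = cluster_supcon_loss([[1.0, 0.0]], [0], bank, tau=0.7)
        assert float(total.data) == pytest.approx(0.0, abs=1e-12)
        assert skipped == 0

    def test_two_entry_closed_form(self):
        bank = ClusterMemoryBank(4)
        bank.update([(0, np.array([1.0, 0.0])), (1, np.array([0.0, 1.0]))], 0)
        per, total, _ = cluster_supcon_loss([[1.0, 0.0]], [0], bank, tau=1.0)
        assert per[0] == pytest.approx(np.log(1 + np.exp(-1.0)), abs=1e-9)

    def test_empty_bank_all_skipped(self):
        per, total, skipped = cluster_supcon_loss(
            random_unit(np.random.default_rng(0), 4, 3), [0, 1, 0, 1],
            ClusterMemoryBank(2), tau=0.1)
        assert float(total.data) == 0.0 and skipped == 4
        np.testing.assert_array_equal(per, 0.0)

    def test_matches_double_loop_on_random_banks(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n, d, c = int(rng.integers(1, 17)), int(rng.integers(2, 9)), int(rng.integers(2, 5))
            tau = float(rng.uniform(0.05, 1.0))
            labels = rng.integers(0, c, n)
            zs = random_unit(rng, n, d)
            bank = ClusterMemoryBank(16)  # roomy: no eviction in this test
            n_entries = int(rng.integers(0, 10))
            bl = rng.integers(0, c, n_entries)
            centers = rng.normal(size=(n_entries, d))
            for i in range(n_entries):
                bank.update([(int(bl[i]), centers[i])], i)
            per, total, skipped = cluster_supcon_loss(zs, labels, bank, tau=tau)
            ref, ref_skipped = naive_cluster_loss(zs, labels, bl, centers, tau)
            assert np.abs(per - ref).max() < 1e-6
            assert skipped == ref_skipped


# ------------------------------------------------------- schedule + combined
@pytest.mark.parametrize("epoch,n_w,expected", [
    (1, 3, 0), (3, 3, 0), (4, 3, 1), (10, 3, 1), (1, 0, 1), (5, 0, 1),
])
def test_alpha_schedule(epoch, n_w, expected):
    assert alpha_schedule(epoch, n_w) == expected


class TestCombinedLoss:
    def _setup(self):
        b = make_embedding_fixture(8, 4, 2, separation=3.0, seed=2)
        bank = ClusterMemoryBank(4)
        for lab, c in cluster_centers(b.z_target, b.labels):
            bank.update([(lab, c)], 0)
        return b, bank

    def test_warmup_excludes_cluster_term(self):
        b, bank = self._setup()
        ins = instance_supcon_loss(b, tau=0.2)[1]
        assert combined_loss(b, bank, tau=0.2, epoch=2, warmup_epochs=5) == \
            pytest.approx(float(ins.data), abs=1e-12)

    def test_empty_bank_reduces_to_instance_sum(self):
        b, _ = self._setup()
        ins = instance_supcon_loss(b, tau=0.2)[1]
        assert combined_loss(b, ClusterMemoryBank(4), tau=0.2, epoch=9,
                             warmup_epochs=1) == pytest.approx(float(ins.data), abs=1e-12)

    def test_compositional_sum(self):
        b, bank = self._setup()
        ins = float(instance_supcon_loss(b, tau=0.2)[1].data)
        clus = float(cluster_supcon_loss(b.z_source, b.labels, bank, tau=0.2)[1].data)
        assert combined_loss(b, bank, tau=0.2, epoch=9, warmup_epochs=1) == \
            pytest.approx(ins + clus, abs=1e-12)


def test_embedding_batch_validates_shapes():
    with pytest.raises(ValueError):
        EmbeddingBatch(np.ones((3, 2)), np.ones((2, 2)), [0, 1, 0])
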