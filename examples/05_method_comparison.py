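"""Classifier-comparison statistics over the packaged benchmark tables.

Recomputes the win/tie headline counts from the shipped 29-dataset
accuracy table, runs the tie-corrected Friedman omnibus test, and the
pairwise Wilcoxon signed-rank tests with Holm correction.
"""

from supcon_tsc import (friedman_test, load_packaged_table, pairwise_wins,
                        wilcoxon_holm)

uea = load_packaged_table("uea")
print(f"table: {len(uea.datasets)} datasets x {len(uea.methods)} methods")

for other in ("LCEM", "MLSTM-FCN"):
    w, t, l = pairwise_wins(uea, "SupCon-TSC", other)
    print(f"SupCon-TSC vs {other}: {w} wins, {t} ties, {l} losses "
          f"-> wins-or-ties on {w + t}/29 datasets")

abl = load_packaged_table("ablation")
w, t, l = pairwise_wins(abl, "with-SupCon", "without-SupCon")
print(f"contrastive pre-training improves-or-ties on {w + t}/29 datasets")

fr = friedman_test(uea)
print(f"\nFriedman (complete rows only, {len(fr.excluded)} excluded: {fr.excluded})")
print(f"  chi-square {fr.statistic:.2f}, p = {fr.p_value:.3g}")
best = sorted(fr.mean_ranks.items(), key=lambda kv: kv[1])[:3]
print("  best mean ranks: " + ", ".join(f"{m} ({r:.2f})" for m, r in best))

wh = wilcoxon_holm(uea, alpha=0.05)
n_diff = int(wh.holm_reject.to_numpy().sum() // 2)
print(f"\nWilcoxon-Holm at alpha 0.05: {n_diff} method pairs significantly differ")
print("cliques of mutually non-distinguished methods:")
for grp in wh.cliques:
    print("  " + ", ".join(grp))
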