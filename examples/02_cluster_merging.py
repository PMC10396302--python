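"""Iterative cluster merging recovers planted cell types exactly.

Each planted type is split into two labels (emulating deliberate
over-clustering); the merge stage re-unites any pair separated by fewer
than 20 differentially expressed genes (Wilcoxon + Bonferroni + fold-change
filter), ranked by centroid correlation, until a fixed point.
"""

from sklearn.metrics import adjusted_rand_score

from larvatlas import (
    SimSpec,
    merge_iterate,
    normalize_log1p,
    simulate_counts,
    split_clusters,
)

spec = SimSpec(seed=1, n_cells=240, n_genes=2000, n_clusters=4)
cm, truth, _ = simulate_counts(spec)
em = normalize_log1p(cm)
split = split_clusters(truth, seed=1)
print(f"{truth.n_clusters()} planted types split into {split.n_clusters()} labels")

merged = merge_iterate(em, split)
ari = adjusted_rand_score(
    truth.labels_for(cm.cell_ids), merged.labels_for(cm.cell_ids)
)
print(f"after merging: {merged.n_clusters()} clusters, adjusted Rand vs truth = {ari}")
for rec in merged.merge_log:
    print(f"  pass {rec.pass_index}: {rec.cluster_absorbed} -> {rec.cluster_kept} "
          f"({rec.de_count} DE genes, r = {rec.correlation:.3f})")
# every logged merge has de_count < 20; an adjusted Rand of 1.0 means the
# planted partition was recovered exactly
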