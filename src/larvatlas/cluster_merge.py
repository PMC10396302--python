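"""Iterative merging of over-clustered labels into transcriptionally distinct clusters.

The over-clustering stage deliberately fragments cell types; this module
walks cluster pairs ranked by centroid Pearson correlation (highest first)
and merges any pair separated by fewer differentially expressed genes than a
threshold (default 20, Wilcoxon rank-sum with Bonferroni correction and a
minimum |log2 fold-change|), recomputing everything after each merge until a
full pass makes no merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._stats import bonferroni, log2_fold_change, wilcoxon_rank_sum
from .io_core import ClusterLabels, ExpressionMatrix, MergeRecord

__all__ = [
    "MergeParams",
    "cluster_centroids",
    "rank_cluster_pairs",
    "de_gene_count",
    "merge_iterate",
    "audit_no_mergeable_pairs",
]

# groups smaller than this are never tested (the rank-sum test is
# uninformative); such pairs are treated as non-mergeable
MIN_GROUP_SIZE = 3


@dataclass
class MergeParams:
    """Thresholds for the merge decision.

    A pair merges when its number of DE genes is strictly below
    ``de_gene_threshold``. A gene counts as DE when its Bonferroni-adjusted
    two-sided rank-sum p-value is below ``p_threshold`` and its
    |log2 fold-change| of group means is at least ``min_abs_log2fc``.
    """

    de_gene_threshold: int = 20
    p_threshold: float = 0.01
    min_abs_log2fc: float = 0.25

    def __post_init__(self) -> None:
        if self.de_gene_threshold < 1:
            raise ValueError("de_gene_threshold must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")


def cluster_centroids(
    em: ExpressionMatrix, labels: ClusterLabels
) -> pd.DataFrame:
    """Cluster x gene matrix of mean log-normalized expression."""
    lab = labels.labels_for(em.cell_ids)
    out = {}
    for cid in sorted(set(lab)):
        mask = lab == cid
        if not mask.any():
            raise ValueError(f"cluster {cid!r} is empty")
        out[cid] = em.values[mask].mean(axis=0)
    return pd.DataFrame.from_dict(out, orient="index", columns=em.gene_ids)


def rank_cluster_pairs(
    centroids: pd.DataFrame,
) -> list[tuple[str, str, float]]:
    """All unordered cluster pairs sorted by Pearson correlation, highest first.

    Ties break lexicographically by (c1, c2). A constant centroid has no
    defined correlation; its pairs are assigned r = 0 with a warning.
    """
    ids = sorted(centroids.index)
    if len(ids) < 2:
        raise ValueError("need at least two clusters to rank pairs")
    x = centroids.loc[ids].to_numpy(dtype=np.float64)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            "constant centroid(s) "
            f"{[i for i, c in zip(ids, constant) if c]}; correlations set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    out = []
    for i, j in combinations(range(len(ids)), 2):
        rij = 0.0 if (constant[i] or constant[j]) else float(r[i, j])
        out.append((ids[i], ids[j], rij))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def de_gene_count(
    em: ExpressionMatrix,
    cells_a: list[str] | np.ndarray,
    cells_b: list[str] | np.ndarray,
    params: MergeParams | None = None,
) -> tuple[int, pd.DataFrame]:
    """Number of differentially expressed genes between two cell groups.

    Per gene: two-sided Wilcoxon rank-sum (normal approximation, tie and
    continuity corrections), Bonferroni-adjusted across genes; DE requires
    adjusted p < p_threshold and |log2 fold-change| >= min_abs_log2fc.
    Returns the count plus the full per-gene table. Symmetric in its groups.
    """
    params = params or MergeParams()
    pos = {c: i for i, c in enumerate(em.cell_ids)}
    ia = [pos[c] for c in cells_a]
    ib = [pos[c] for c in cells_b]
    if len(ia) < MIN_GROUP_SIZE or len(ib) < MIN_GROUP_SIZE:
        raise ValueError(
            f"both groups need >= {MIN_GROUP_SIZE} cells "
            f"(got {len(ia)} and {len(ib)})"
        )
    x_a = em.values[ia]
    x_b = em.values[ib]
    _, p = wilcoxon_rank_sum(x_a, x_b)
    p_adj = bonferroni(p)
    lfc = log2_fold_change(x_a.mean(axis=0), x_b.mean(axis=0))
    is_de = (p_adj < params.p_threshold) & (np.abs(lfc) >= params.min_abs_log2fc)
    table = pd.DataFrame(
        {
            "gene_id": em.gene_ids,
            "p_value": p,
            "adjusted_p": p_adj,
            "log2fc": lfc,
            "is_de": is_de,
        }
    )
    return int(is_de.sum()), table


def _relabel(assignments: dict[str, str], absorbed: str, kept: str) -> dict[str, str]:
    return {c: (kept if k == absorbed else k) for c, k in assignments.items()}


def merge_iterate(
    em: ExpressionMatrix,
    labels: ClusterLabels,
    params: MergeParams | None = None,
) -> ClusterLabels:
    """Merge cluster pairs until every remaining pair is transcriptionally distinct.

    Each pass recomputes centroids, ranks pairs by correlation descending,
    and tests pairs in that order; the first pair whose DE-gene count falls
    strictly below the threshold is merged (the lexicographically smaller id
    survives), logged, and the pass restarts. Terminates when a full pass
    makes no merge; pairs with a group below the minimum size are never
    merged. The cluster count is non-increasing, so at most
    (initial clusters - 1) merges happen.
    """
    params = params or MergeParams()
    assignments = dict(labels.assignments)
    merge_log: list[MergeRecord] = list(labels.merge_log)
    lab_arr = np.array([assignments[c] for c in em.cell_ids])
    pass_index = 0
    while True:
        pass_index += 1
        current = ClusterLabels(assignments)
        if current.n_clusters() < 2:
            break
        centroids = cluster_centroids(em, current)
        ranked = rank_cluster_pairs(centroids)
        members = {
            cid: [c for c, l in zip(em.cell_ids, lab_arr) if l == cid]
            for cid in centroids.index
        }
        merged = False
        for c1, c2, r in ranked:
            if len(members[c1]) < MIN_GROUP_SIZE or len(members[c2]) < MIN_GROUP_SIZE:
                continue
            n_de, _ = de_gene_count(em, members[c1], members[c2], params)
            if n_de < params.de_gene_threshold:
                kept, absorbed = sorted([c1, c2])
                assignments = _relabel(assignments, absorbed, kept)
                lab_arr = np.array([assignments[c] for c in em.cell_ids])
                merge_log.append(
                    MergeRecord(kept, absorbed, n_de, r, pass_index)
                )
                merged = True
                break
        if not merged:
            break
    return ClusterLabels(assignments, merge_log)


def audit_no_mergeable_pairs(
    em: ExpressionMatrix,
    labels: ClusterLabels,
    params: MergeParams | None = None,
) -> bool:
    """Check the fixed-point property: no testable pair is still mergeable."""
    params = params or MergeParams()
    lab = labels.labels_for(em.cell_ids)
    members = {
        cid: [c for c, l in zip(em.cell_ids, lab) if l == cid]
        for cid in sorted(set(lab))
    }
    for c1, c2 in combinations(sorted(members), 2):
        if len(members[c1]) < MIN_GROUP_SIZE or len(members[c2]) < MIN_GROUP_SIZE:
            continue
        n_de, _ = de_gene_count(em, members[c1], members[c2], params)
        if n_de < params.de_gene_threshold:
            return False
    return True


def merge_log_table(labels: ClusterLabels) -> pd.DataFrame:
    """Merge history as a table (cluster_kept, cluster_absorbed, de_count, correlation, pass_index)."""
    return pd.DataFrame(
        [
            {
                "cluster_kept": m.cluster_kept,
                "cluster_absorbed": m.cluster_absorbed,
                "de_count": m.de_count,
                "correlation": m.correlation,
                "pass_index": m.pass_index,
            }
            for m in labels.merge_log
        ],
        columns=[
            "cluster_kept",
            "cluster_absorbed",
            "de_count",
            "correlation",
            "pass_index",
        ],
    )
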