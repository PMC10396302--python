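"""Cell-type-level phylostratigraphy: transcriptome age index and enrichment.

Each gene carries a phylostratum rank (1 = oldest lineage with detectable
homologs). The transcriptome age index (TAI) of a cluster is the
expression-weighted mean rank over its centroid of log-normalized
expression, so higher TAI = evolutionarily younger transcriptome. Marker
genes per cluster are then tested for phylostratum over-representation with
an upper-tail hypergeometric test against the expressed background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._stats import log2_fold_change, wilcoxon_rank_sum
from .cluster_merge import cluster_centroids
from .io_core import ClusterLabels, ExpressionMatrix, GeneAgeTable

__all__ = [
    "hypergeom_upper_tail",
    "cluster_tai",
    "tai_profile",
    "find_markers",
    "MarkerTable",
    "phylostratum_enrichment",
]

P_FLOOR = 1e-300


def hypergeom_upper_tail(k: int, n_total: int, n_in_stratum: int, n_drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): over-representation tail.

    k = 0 returns exactly 1 (the upper tail includes every outcome).
    """
    p = float(hypergeom.sf(k - 1, n_total, n_in_stratum, n_drawn))
    return min(max(p, 0.0), 1.0)


def cluster_tai(
    centroid_log_expr: dict[str, float] | pd.Series,
    ages: GeneAgeTable,
) -> tuple[float, int, int]:
    """TAI of one cluster: sum(rank_g * e_g) / sum(e_g) over aged, expressed genes.

    ``e_g`` is the log-transformed average expression of gene g in the
    cluster; genes with zero expression or no age assignment are excluded
    (the latter are counted, never imputed). Returns
    (tai, n_genes_used, n_genes_missing_age).
    """
    expr = pd.Series(centroid_log_expr, dtype=float)
    expressed = expr[expr > 0]
    present, missing = ages.subset(list(expressed.index))
    if not present:
        raise ValueError("no expressed gene has an age assignment")
    e = expressed[list(present)].to_numpy()
    ranks = np.array([present[g] for g in present], dtype=float)
    if np.all(ranks == ranks[0]):
        # weighted mean of a constant is that constant, exactly
        tai = float(ranks[0])
    else:
        tai = float((ranks * e).sum() / e.sum())
    return tai, len(present), len(missing)


def tai_profile(
    em: ExpressionMatrix,
    labels: ClusterLabels,
    ages: GeneAgeTable,
) -> pd.DataFrame:
    """Per-cluster TAI table (cluster_id, tai, n_genes_used, n_genes_missing_age).

    A cluster whose expressed genes all lack ages gets tai = NaN (missing,
    not zero).
    """
    centroids = cluster_centroids(em, labels)
    rows = []
    for cid in centroids.index:
        try:
            tai, used, missing = cluster_tai(centroids.loc[cid], ages)
        except ValueError:
            tai, used = np.nan, 0
            missing = int((centroids.loc[cid] > 0).sum())
        rows.append(
            {
                "cluster_id": cid,
                "tai": tai,
                "n_genes_used": used,
                "n_genes_missing_age": missing,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MarkerTable:
    """Per-cluster marker genes: cluster_id -> table (gene_id, adjusted_p, log2fc)."""

    per_cluster: dict[str, pd.DataFrame]

    def genes(self, cluster_id: str) -> list[str]:
        tab = self.per_cluster.get(cluster_id)
        return [] if tab is None else list(tab["gene_id"])

    def all_marker_genes(self) -> set[str]:
        return {g for cid in self.per_cluster for g in self.genes(cid)}


def find_markers(
    em: ExpressionMatrix,
    labels: ClusterLabels,
    p_threshold: float = 0.05,
    min_log2fc: float = 0.25,
) -> MarkerTable:
    """One-vs-rest marker genes per cluster.

    Two-sided Wilcoxon rank-sum per gene, Benjamini-Hochberg across genes
    within each cluster; a marker needs adjusted p < p_threshold,
    log2 fold-change >= min_log2fc, and higher mean inside the cluster than
    outside.
    """
    lab = labels.labels_for(em.cell_ids)
    cluster_ids = sorted(set(lab))
    if len(cluster_ids) < 2:
        raise ValueError("find_markers needs at least two clusters")
    out: dict[str, pd.DataFrame] = {}
    for cid in cluster_ids:
        mask = lab == cid
        x_in = em.values[mask]
        x_out = em.values[~mask]
        _, p = wilcoxon_rank_sum(x_in, x_out)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        lfc = log2_fold_change(x_in.mean(axis=0), x_out.mean(axis=0))
        higher = x_in.mean(axis=0) > x_out.mean(axis=0)
        is_marker = (p_adj < p_threshold) & (lfc >= min_log2fc) & higher
        tab = pd.DataFrame(
            {
                "gene_id": np.asarray(em.gene_ids)[is_marker],
                "adjusted_p": p_adj[is_marker],
                "log2fc": lfc[is_marker],
            }
        ).sort_values("adjusted_p", kind="stable").reset_index(drop=True)
        out[cid] = tab
    return MarkerTable(out)


def phylostratum_enrichment(
    markers: MarkerTable,
    ages: GeneAgeTable,
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of phylostrata among cluster markers.

    For cluster c and stratum s: N = aged background genes, K = those in s,
    n = markers of c (within the background), k = markers of c in s;
    p = P(X >= k) for X ~ Hypergeometric(N, K, n). k = 0 gives p = 1 exactly.
    Raw p is reported (floored at 1e-300 for the -log10 column) along with a
    Benjamini-Hochberg adjusted column across the whole grid.
    """
    bg = [g for g in background if g in ages]
    if not bg:
        raise ValueError("background contains no aged genes")
    bg_set = set(bg)
    n_total = len(bg_set)
    strata = sorted({ages.get(g) for g in bg_set})
    stratum_members = {
        s: {g for g in bg_set if ages.get(g) == s} for s in strata
    }
    rows = []
    for cid, tab in sorted(markers.per_cluster.items()):
        mk = [g for g in tab["gene_id"] if g in bg_set]
        n_mark = len(mk)
        for s in strata:
            k = sum(1 for g in mk if g in stratum_members[s])
            big_k = len(stratum_members[s])
            if n_mark == 0:
                p = 1.0
            else:
                p = hypergeom_upper_tail(k, n_total, big_k, n_mark)
            rows.append(
                {
                    "cluster_id": cid,
                    "phylostratum": s,
                    "n_markers": n_mark,
                    "k_in_stratum": k,
                    "K_background": big_k,
                    "p_value": p,
                    "neg_log10_p": -np.log10(max(p, P_FLOOR)),
                    "no_markers": n_mark == 0,
                }
            )
    grid = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(grid["p_value"], method="fdr_bh")
    grid["adjusted_p"] = p_adj
    return grid
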