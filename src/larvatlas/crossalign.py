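"""Cross-species cluster alignment through an ortholog map.

Two expression matrices from different species are collapsed onto a shared
feature axis (connected components of the ortholog graph, weight-averaged),
jointly embedded with PCA, and scored cluster-against-cluster by mutual
nearest cross-species neighbors: the alignment score of a cluster pair is
the average number of mutual cross-species neighbors of each cell relative
to the maximum possible number (k), symmetrized over the two directions.
Shared markers of an aligned pair are read straight off the ortholog map,
so many-to-many homology naturally yields unequal per-species gene counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .agemix import MarkerTable
from .io_core import ClusterLabels, ExpressionMatrix, OrthologMap
from .preprocess import Embedding, _fix_signs
from sklearn.decomposition import PCA

__all__ = [
    "collapse_to_ortholog_space",
    "joint_embedding",
    "JointEmbedding",
    "mutual_nn",
    "alignment_scores",
    "shared_markers",
    "SharedMarkerReport",
]


def collapse_to_ortholog_space(
    em_a: ExpressionMatrix,
    em_b: ExpressionMatrix,
    omap: OrthologMap,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Collapse both matrices onto shared ortholog-component features.

    Shared features are connected components of the ortholog graph that have
    member genes in both matrices; each species' feature value is the
    weight-normalized average of its member genes' expression (a gene's
    weight is the sum of its ortholog-edge weights inside the component).
    Records naming genes absent from either matrix are skipped with a
    warning; single-species components are dropped. Returns the two
    collapsed matrices plus an info dict with skip/drop counts.
    """
    idx_a = {g: j for j, g in enumerate(em_a.gene_ids)}
    idx_b = {g: j for j, g in enumerate(em_b.gene_ids)}
    rec = omap.records
    present = rec["gene_a"].isin(idx_a) & rec["gene_b"].isin(idx_b)
    n_skipped = int((~present).sum())
    if n_skipped:
        warnings.warn(
            f"{n_skipped} ortholog records reference genes absent from the "
            "matrices and were skipped"
        )
    rec = rec[present]
    if rec.empty:
        raise ValueError("no ortholog record touches both matrices")

    genes_a = sorted(set(rec["gene_a"]))
    genes_b = sorted(set(rec["gene_b"]))
    node_a = {g: i for i, g in enumerate(genes_a)}
    node_b = {g: len(genes_a) + i for i, g in enumerate(genes_b)}
    n_nodes = len(genes_a) + len(genes_b)
    rows = [node_a[g] for g in rec["gene_a"]]
    cols = [node_b[g] for g in rec["gene_b"]]
    adj = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    n_comp, comp = connected_components(adj, directed=False)

    # per-gene weight = sum of incident edge weights
    w_a = rec.groupby("gene_a")["weight"].sum()
    w_b = rec.groupby("gene_b")["weight"].sum()

    comp_members_a: dict[int, list[str]] = {}
    comp_members_b: dict[int, list[str]] = {}
    for g, i in node_a.items():
        comp_members_a.setdefault(comp[i], []).append(g)
    for g, i in node_b.items():
        comp_members_b.setdefault(comp[i], []).append(g)

    shared = sorted(
        (c for c in range(n_comp) if c in comp_members_a and c in comp_members_b),
        key=lambda c: min(comp_members_a[c]),
    )
    n_dropped = n_comp - len(shared)

    def build(em, members, weights, idx):
        cols_out = np.empty((em.n_cells, len(shared)))
        names = []
        for f, c in enumerate(shared):
            genes = sorted(members[c])
            w = np.array([weights[g] for g in genes])
            x = em.values[:, [idx[g] for g in genes]]
            cols_out[:, f] = (x * w).sum(axis=1) / w.sum()
            names.append("|".join(genes))
        return cols_out, names

    vals_a, _ = build(em_a, comp_members_a, w_a, idx_a)
    vals_b, _ = build(em_b, comp_members_b, w_b, idx_b)
    feat_names = [f"og{f:05d}" for f in range(len(shared))]
    info = {
        "n_features": len(shared),
        "n_skipped_records": n_skipped,
        "n_dropped_components": n_dropped,
    }
    return (
        ExpressionMatrix(em_a.cell_ids, feat_names, vals_a),
        ExpressionMatrix(em_b.cell_ids, feat_names, vals_b),
        info,
    )


@dataclass
class JointEmbedding:
    """Joint PCA coordinates for two species; species[i] is 'a' or 'b'."""

    cell_ids: list[str]
    species: np.ndarray
    coordinates: np.ndarray

    def split(self) -> tuple[Embedding, Embedding]:
        is_a = self.species == "a"
        return (
            Embedding(
                [c for c, m in zip(self.cell_ids, is_a) if m],
                self.coordinates[is_a],
            ),
            Embedding(
                [c for c, m in zip(self.cell_ids, is_a) if not m],
                self.coordinates[~is_a],
            ),
        )


def joint_embedding(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    d: int = 30,
) -> JointEmbedding:
    """Standardize each species' features, stack rows, and run sign-fixed PCA."""
    if mat_a.gene_ids != mat_b.gene_ids:
        raise ValueError("matrices must share the same feature axis")
    overlap = set(mat_a.cell_ids) & set(mat_b.cell_ids)
    ids_b = [f"b:{c}" if c in overlap else c for c in mat_b.cell_ids]

    def standardize(x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        z = (x - mean) / np.where(sd > 0, sd, 1.0)
        z[:, sd == 0] = 0.0
        return z

    stacked = np.vstack([standardize(mat_a.values), standardize(mat_b.values)])
    if d > min(stacked.shape):
        raise ValueError(f"d={d} exceeds min(total cells, features)")
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(stacked)
    _, scores = _fix_signs(pca.components_.copy(), scores)
    species = np.array(["a"] * mat_a.n_cells + ["b"] * mat_b.n_cells)
    return JointEmbedding(list(mat_a.cell_ids) + ids_b, species, scores)


def mutual_nn(emb: JointEmbedding, k: int = 20) -> set[tuple[str, str]]:
    """Mutual cross-species k-nearest-neighbor cell pairs.

    (x, y) is reported iff y is among x's k nearest cells of the other
    species and x is among y's k nearest of the other species (Euclidean in
    the joint embedding). Distance ties break deterministically by cell id.
    """
    emb_a, emb_b = emb.split()
    n_a, n_b = len(emb_a.cell_ids), len(emb_b.cell_ids)
    if n_a <= k or n_b <= k:
        raise ValueError(f"each species needs more than k={k} cells")
    dist = cdist(emb_a.coordinates, emb_b.coordinates)

    def knn_sets(d: np.ndarray, other_ids: list[str]) -> list[set[int]]:
        order_key = np.argsort(np.array(other_ids))
        rank_by_id = np.empty(len(other_ids), dtype=int)
        rank_by_id[order_key] = np.arange(len(other_ids))
        out = []
        for row in d:
            idx = np.lexsort((rank_by_id, row))[:k]
            out.append(set(idx.tolist()))
        return out

    nn_a = knn_sets(dist, emb_b.cell_ids)       # for each a-cell: b indices
    nn_b = knn_sets(dist.T, emb_a.cell_ids)     # for each b-cell: a indices
    pairs = set()
    for i in range(n_a):
        for j in nn_a[i]:
            if i in nn_b[j]:
                pairs.add((emb_a.cell_ids[i], emb_b.cell_ids[j]))
    return pairs


def alignment_scores(
    pairs: set[tuple[str, str]],
    labels_a: ClusterLabels,
    labels_b: ClusterLabels,
    k: int,
    prune_below: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-pair alignment scores from mutual-neighbor pairs.

    For clusters c (species A) and d (species B): s_c is the mean, over
    cells of c, of the number of mutual partners in d divided by k; s_d is
    the symmetric quantity; the score is (s_c + s_d) / 2 and lies in [0, 1].
    Returns (full matrix, pruned matrix with entries below ``prune_below``
    zeroed); rows are A clusters, columns B clusters.
    """
    clusters_a = sorted(set(labels_a.assignments.values()))
    clusters_b = sorted(set(labels_b.assignments.values()))
    size_a = {c: 0 for c in clusters_a}
    size_b = {c: 0 for c in clusters_b}
    for lab in labels_a.assignments.values():
        size_a[lab] += 1
    for lab in labels_b.assignments.values():
        size_b[lab] += 1

    counts = pd.DataFrame(0.0, index=clusters_a, columns=clusters_b)
    for x, y in pairs:
        counts.loc[labels_a.assignments[x], labels_b.assignments[y]] += 1.0

    full = pd.DataFrame(0.0, index=clusters_a, columns=clusters_b)
    for c in clusters_a:
        for d in clusters_b:
            s_c = counts.loc[c, d] / (size_a[c] * k)
            s_d = counts.loc[c, d] / (size_b[d] * k)
            full.loc[c, d] = 0.5 * (s_c + s_d)
    pruned = full.where(full >= prune_below, 0.0)
    return full, pruned


@dataclass
class SharedMarkerReport:
    cluster_a: str
    cluster_b: str
    records: pd.DataFrame  # gene_a, gene_b, weight
    n_genes_a: int
    n_genes_b: int


def shared_markers(
    markers_a: MarkerTable,
    markers_b: MarkerTable,
    omap: OrthologMap,
    cluster_pair: tuple[str, str],
) -> SharedMarkerReport:
    """Ortholog records linking markers of one cluster to markers of the other.

    Per-species counts are distinct genes, so a many-to-many map gives
    unequal counts by construction (the phenomenon behind '133 vs 112'
    style tallies).
    """
    ca, cb = cluster_pair
    set_a = set(markers_a.genes(ca))
    set_b = set(markers_b.genes(cb))
    rec = omap.records
    hit = rec[rec["gene_a"].isin(set_a) & rec["gene_b"].isin(set_b)]
    hit = hit.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return SharedMarkerReport(
        cluster_a=ca,
        cluster_b=cb,
        records=hit,
        n_genes_a=hit["gene_a"].nunique(),
        n_genes_b=hit["gene_b"].nunique(),
    )


def best_matches(full_scores: pd.DataFrame) -> dict[str, str]:
    """Row-wise argmax of the alignment-score matrix (A cluster -> B cluster)."""
    return {c: full_scores.loc[c].idxmax() for c in full_scores.index}
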