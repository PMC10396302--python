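"""Cell QC, normalization, variable-gene selection, PCA, and over-clustering.

These are the standard stages upstream of the iterative cluster-merging
algorithm: filter cells on detected genes / mitochondrial fraction / total
UMI, depth-normalize and log1p-transform, pick the top variable genes with a
vst-style mean-variance trend, embed with PCA, and over-cluster a shared
nearest-neighbor graph at high resolution (the merging stage corrects the
over-clustering afterwards).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_core import ClusterLabels, CountMatrix, ExpressionMatrix

__all__ = [
    "QCParams",
    "QCReport",
    "Embedding",
    "filter_cells",
    "normalize_log1p",
    "select_variable_genes",
    "embed_pca",
    "initial_clusters",
]


@dataclass
class QCParams:
    """Cell-filter thresholds.

    Defaults follow the oyster preset: discard cells with fewer than 200
    detected genes, more than 20% mitochondrial counts, or more than 5000
    total UMI. The flatworm preset raises the mitochondrial cutoff to 30%
    (``flatworm()``). The UMI bound side is configurable because an upper
    bound of 5000 sits oddly against droplet libraries averaging tens of
    thousands of UMIs per cell; the default keeps the upper reading.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.20
    umi_bound: int = 5000
    umi_bound_side: str = "upper"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.umi_bound < 0:
            raise ValueError("umi_bound must be >= 0")
        if self.umi_bound_side not in ("upper", "lower"):
            raise ValueError("umi_bound_side must be 'upper' or 'lower'")

    @classmethod
    def flatworm(cls) -> "QCParams":
        return cls(max_mito_fraction=0.30)


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    removed_low_genes: int
    removed_high_mito: int
    removed_umi_bound: int
    dropped_genes: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "removed_low_genes": self.removed_low_genes,
            "removed_high_mito": self.removed_high_mito,
            "removed_umi_bound": self.removed_umi_bound,
            "n_dropped_genes": len(self.dropped_genes),
        }


@dataclass
class Embedding:
    """Cells x d coordinate matrix, rows aligned with cell_ids."""

    cell_ids: list[str]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.shape[0] != len(self.cell_ids):
            raise ValueError("coordinate rows must align with cell ids")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]


def filter_cells(cm: CountMatrix, qc: QCParams | None = None) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells, then drop genes left with zero counts.

    A cell is removed when its detected-gene count is strictly below
    ``min_genes_per_cell``, its mitochondrial count fraction is strictly
    above ``max_mito_fraction``, or its total UMI is strictly beyond
    ``umi_bound`` on the configured side. The report counts removals per
    criterion (a cell can fail several) and lists the dropped genes.
    """
    qc = qc or QCParams()
    counts = cm.counts
    totals = np.asarray(counts.sum(axis=1)).ravel()
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito_counts = np.asarray(counts[:, cm.mito_flags].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low_genes = detected < qc.min_genes_per_cell
    high_mito = mito_frac > qc.max_mito_fraction
    if qc.umi_bound_side == "upper":
        bad_umi = totals > qc.umi_bound
    else:
        bad_umi = totals < qc.umi_bound
    keep = ~(low_genes | high_mito | bad_umi)
    if not np.any(keep):
        raise ValueError(
            "all cells removed by QC; review min_genes_per_cell / "
            "max_mito_fraction / umi_bound settings"
        )

    sub = cm.counts[keep]
    gene_keep = np.asarray((sub > 0).sum(axis=0)).ravel() > 0
    dropped_genes = [g for g, k in zip(cm.gene_ids, gene_keep) if not k]
    out = CountMatrix(
        [c for c, k in zip(cm.cell_ids, keep) if k],
        [g for g, k in zip(cm.gene_ids, gene_keep) if k],
        sub[:, gene_keep],
        cm.mito_flags[gene_keep],
    )
    report = QCReport(
        n_cells_in=cm.n_cells,
        n_cells_out=out.n_cells,
        removed_low_genes=int(low_genes.sum()),
        removed_high_mito=int(high_mito.sum()),
        removed_umi_bound=int(bad_umi.sum()),
        dropped_genes=dropped_genes,
    )
    return out, report


def normalize_log1p(cm: CountMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """Depth-normalize and log-transform: ln(1 + scale * count / cell_total)."""
    totals = np.asarray(cm.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = cm.cell_ids[int(np.argmax(totals == 0))]
        raise ValueError(
            f"cell {bad!r} has zero total counts; run filter_cells first"
        )
    scaled = sp.diags(scale / totals) @ cm.counts.astype(np.float64)
    values = np.asarray(scaled.log1p().todense())
    return ExpressionMatrix(cm.cell_ids, cm.gene_ids, values)


def _vst_standardized_variance(
    counts: np.ndarray, clip: float, span: float = 0.3
) -> np.ndarray:
    """Standardized variance per gene under a vst-style mean-variance trend.

    Raw-count mean and variance per gene; a lowess trend of log10 variance on
    log10 mean; each gene's counts standardized by the trend-expected sd with
    values clipped at ``clip``; the variance of the clipped values is the
    selection score. Zero-variance genes score 0.
    """
    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    score = np.zeros(counts.shape[1])
    eligible = var > 0
    if not np.any(eligible):
        return score
    log_mean = np.log10(mean[eligible])
    log_var = np.log10(var[eligible])
    if np.unique(log_mean).size < 2:
        fitted = np.full(log_mean.shape, log_var.mean())
    else:
        fitted = sm.nonparametric.lowess(
            log_var, log_mean, frac=span, return_sorted=False
        )
    exp_sd = np.sqrt(10.0**fitted)
    z = (counts[:, eligible] - mean[eligible]) / exp_sd
    z = np.clip(z, -clip, clip)
    score[eligible] = z.var(axis=0, ddof=1)
    return score


def select_variable_genes(cm: CountMatrix, n: int = 2000) -> list[str]:
    """Top-n variable genes by vst-standardized variance.

    Ties (including the all-zero score of constant genes, which can never
    outrank a varying gene) are broken deterministically by gene id. When
    fewer than n genes vary, all eligible genes are returned with a warning.
    """
    counts = cm.dense().astype(np.float64)
    clip = np.sqrt(cm.n_cells)
    score = _vst_standardized_variance(counts, clip=clip)
    eligible = score > 0
    n_eligible = int(eligible.sum())
    order = sorted(
        range(cm.n_genes), key=lambda j: (-score[j], cm.gene_ids[j])
    )
    if n_eligible < n:
        warnings.warn(
            f"only {n_eligible} genes have nonzero standardized variance "
            f"(requested {n}); returning all eligible genes"
        )
        return [cm.gene_ids[j] for j in order[:n_eligible]]
    return [cm.gene_ids[j] for j in order[:n]]


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Force the largest-magnitude loading of each axis to be positive."""
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    return components, scores


def embed_pca(
    em: ExpressionMatrix,
    genes: list[str] | None = None,
    d: int = 70,
    clip: float = 10.0,
) -> Embedding:
    """Scale the selected genes and project onto the top-d principal axes.

    Each gene is centered and unit-scaled with values clipped to +/-clip
    (zero-variance genes become zero columns). The per-axis sign ambiguity of
    PCA is resolved by forcing the largest-magnitude loading positive, so the
    embedding is fully deterministic.
    """
    if genes is None:
        genes = em.gene_ids
    idx = {g: j for j, g in enumerate(em.gene_ids)}
    missing = [g for g in genes if g not in idx]
    if missing:
        raise KeyError(f"genes not in expression matrix, e.g. {missing[0]!r}")
    cols = [idx[g] for g in genes]
    x = em.values[:, cols]
    if d > min(x.shape):
        raise ValueError(
            f"d={d} exceeds min(cells, genes) = {min(x.shape)}"
        )
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = np.clip((x - mean) / sd_safe, -clip, clip)
    z[:, sd == 0] = 0.0
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(z)
    _, scores = _fix_signs(pca.components_.copy(), scores)
    return Embedding(em.cell_ids, scores)


def snn_graph(
    coords: np.ndarray, k_neighbors: int = 20, prune: float = 1.0 / 15.0
) -> sp.csr_matrix:
    """Jaccard-weighted shared nearest-neighbor graph.

    Each cell's k-NN list (self included, Euclidean) is intersected with
    every other cell's; edge weight = |shared| / |union|; weights below
    ``prune`` are removed.
    """
    n = coords.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k + 1)
    member = sp.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (member @ member.T).toarray()
    denom = 2.0 * (k + 1) - shared
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.where(denom > 0, shared / denom, 0.0)
    np.fill_diagonal(jac, 0.0)
    jac[jac < prune] = 0.0
    return sp.csr_matrix(jac)


def initial_clusters(
    emb: Embedding,
    resolution: float = 10.0,
    k_neighbors: int = 20,
    seed: int = 0,
) -> ClusterLabels:
    """Partition the SNN graph with seeded Leiden community detection.

    Deliberately over-clusters at the default high resolution; the merging
    stage combines transcriptionally indistinct clusters afterwards.
    External labels may be supplied to downstream stages instead of calling
    this at all.
    """
    n = len(emb.cell_ids)
    if n < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={k_neighbors + 1} cells, got {n}"
        )
    adj = snn_graph(emb.coordinates, k_neighbors=k_neighbors)
    sources, targets = adj.nonzero()
    mask = sources < targets
    edges = list(zip(sources[mask].tolist(), targets[mask].tolist()))
    weights = np.asarray(adj[sources[mask], targets[mask]]).ravel().tolist()
    g = igraph.Graph(n=n, edges=edges)
    isolated = [v.index for v in g.vs if g.degree(v.index) == 0]
    if isolated:
        warnings.warn(
            f"{len(isolated)} isolated cells in the SNN graph become singletons"
        )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    width = len(str(max(membership.max() + 1, 1)))
    assignments = {
        cell: f"c{m:0{width}d}" for cell, m in zip(emb.cell_ids, membership)
    }
    return ClusterLabels(assignments)
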