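"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the statistical structure the analyses assume:
clustered negative-binomial UMI matrices with disjoint marker programs and a
mitochondrial fraction that pushes a small cell subset past QC; gene ages
with one cluster's markers drawn from the youngest phylostratum; a species
pair sharing a subset of cell-type programs through a partly many-to-many
ortholog map; and precursor proteins with planted signal peptides, cleavage
motifs, and amidation glycines. Every generator is a pure function of its
spec (seed included), and ground truth is returned (and written) alongside
the data so tests never re-derive it from generator internals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import (
    ClusterLabels,
    CountMatrix,
    GeneAgeTable,
    OrthologMap,
    write_labels,
    write_mtx_bundle,
    write_tsv_table,
)
from .np_scan import SignalCall

__all__ = [
    "SimSpec",
    "simulate_counts",
    "simulate_gene_ages",
    "simulate_species_pair",
    "simulate_precursors",
    "split_clusters",
    "write_counts_bundle",
    "write_fasta",
]

# residues safe to use inside planted peptides: no K/R (cleavage) and no G
# (amidation signal), so planted boundaries are unambiguous
_PEPTIDE_ALPHABET = "ADEFHILMNPQSTVWY"
_HYDROPHOBIC = "LIVFA"
_POLAR_TAIL = "ADESTQN"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimSpec:
    """Study conditions for all generators.

    Counts: ``n_clusters`` cell types over ``n_cells`` cells and ``n_genes``
    genes, disjoint marker programs of ``markers_per_cluster`` genes shifted
    up by ``marker_log2fc``, negative-binomial counts at ``nb_dispersion``
    (var = mu + a*mu^2), per-cell depth uniform in ``depth_range``.
    ``mito_gene_count`` mitochondrial genes give most cells a fraction in
    ``mito_fraction_range`` while ``mito_high_cell_frac`` of cells land in
    ``mito_high_fraction_range`` to exercise QC. Ages: uniform strata over
    1..``n_strata`` except markers of cluster ``young_cluster``, drawn from
    the youngest stratum with probability ``young_stratum_prob``.
    Cross-species: ``shared_types`` programs reused through an ortholog map
    over ``ortho_features`` ancestral features (``ortho_many_frac`` of them
    duplicated into many-to-many matches) plus ``private_types_per_species``
    types marked on unmapped genes. Precursors: ``n_precursors`` planted
    proteins of ``peptides_per_precursor`` similar peptides among
    ``n_decoys`` decoys.
    """

    seed: int = 0
    n_cells: int = 300
    n_genes: int = 2000
    n_clusters: int = 5
    markers_per_cluster: int = 20
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.5
    depth_range: tuple[int, int] = (1000, 3000)
    mito_gene_count: int = 10
    mito_fraction_range: tuple[float, float] = (0.01, 0.08)
    mito_high_cell_frac: float = 0.05
    mito_high_fraction_range: tuple[float, float] = (0.30, 0.50)
    n_strata: int = 8
    young_cluster: int = 0
    young_stratum_prob: float = 0.8
    shared_types: int = 3
    private_types_per_species: int = 1
    ortho_one_to_one_frac: float = 0.7
    ortho_many_frac: float = 0.3
    ortho_features: int = 400
    n_private_genes: int = 60
    n_precursors: int = 20
    peptides_per_precursor: int = 5
    n_decoys: int = 500
    amidation_frac: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "n_cells", "n_genes", "n_clusters", "markers_per_cluster",
            "n_strata", "ortho_features", "peptides_per_precursor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "mito_high_cell_frac", "ortho_one_to_one_frac",
            "ortho_many_frac", "amidation_frac", "young_stratum_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.markers_per_cluster * self.n_clusters > self.n_genes - self.mito_gene_count:
            raise ValueError(
                "markers_per_cluster * n_clusters exceeds available genes"
            )
        if not 0 <= self.young_cluster < self.n_clusters:
            raise ValueError("young_cluster must index a cluster")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; alpha = 0 degenerates to Poisson."""
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.maximum(mu, 1e-12))
    return rng.poisson(lam)


def _cluster_sizes(n_cells: int, n_clusters: int) -> list[int]:
    base = n_cells // n_clusters
    sizes = [base] * n_clusters
    for i in range(n_cells - base * n_clusters):
        sizes[i] += 1
    return sizes


def simulate_counts(spec: SimSpec) -> tuple[CountMatrix, ClusterLabels, dict[str, list[str]]]:
    """Clustered negative-binomial UMI matrix with planted marker programs.

    Returns the CountMatrix, the true per-cell labels (cluster ids
    ``t0..t{k-1}``), and the marker map cluster id -> marker gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    n_mito = spec.mito_gene_count
    gene_ids = [f"mt-g{j:04d}" for j in range(n_mito)] + [
        f"g{j:04d}" for j in range(spec.n_genes - n_mito)
    ]
    mito_flags = np.array([True] * n_mito + [False] * (spec.n_genes - n_mito))

    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes - n_mito)
    # marker genes get baseline expression at or above the pool median
    # (the lognormal median, 1): a planted program whose genes are hardly
    # ever observed at sequencing depth is not a marker program
    n_marked = spec.n_clusters * spec.markers_per_cluster
    base[:n_marked] = np.maximum(base[:n_marked], 1.0)
    marker_map: dict[str, list[str]] = {}
    cluster_props = np.empty((spec.n_clusters, spec.n_genes - n_mito))
    for c in range(spec.n_clusters):
        prop = base.copy()
        lo = c * spec.markers_per_cluster
        hi = lo + spec.markers_per_cluster
        prop[lo:hi] *= 2.0**spec.marker_log2fc
        cluster_props[c] = prop / prop.sum()
        marker_map[f"t{c}"] = [gene_ids[n_mito + j] for j in range(lo, hi)]

    mito_w = rng.lognormal(0.0, 0.3, size=n_mito) if n_mito else np.empty(0)
    if n_mito:
        mito_w = mito_w / mito_w.sum()

    sizes = _cluster_sizes(spec.n_cells, spec.n_clusters)
    cell_cluster = np.repeat(np.arange(spec.n_clusters), sizes)
    depth = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=spec.n_cells)
    high = rng.random(spec.n_cells) < spec.mito_high_cell_frac
    mito_frac = np.where(
        high,
        rng.uniform(*spec.mito_high_fraction_range, size=spec.n_cells),
        rng.uniform(*spec.mito_fraction_range, size=spec.n_cells),
    )
    if n_mito == 0:
        mito_frac = np.zeros(spec.n_cells)

    mu = np.empty((spec.n_cells, spec.n_genes))
    for i in range(spec.n_cells):
        mu[i, :n_mito] = depth[i] * mito_frac[i] * mito_w
        mu[i, n_mito:] = depth[i] * (1.0 - mito_frac[i]) * cluster_props[cell_cluster[i]]
    counts = _nb_sample(rng, mu, spec.nb_dispersion)

    cell_ids = [f"cell{i:05d}" for i in range(spec.n_cells)]
    cm = CountMatrix(cell_ids, gene_ids, sp.csr_matrix(counts), mito_flags)
    labels = ClusterLabels(
        {cell_ids[i]: f"t{cell_cluster[i]}" for i in range(spec.n_cells)}
    )
    return cm, labels, marker_map


def simulate_gene_ages(
    spec: SimSpec,
    gene_ids: list[str],
    marker_map: dict[str, list[str]],
) -> GeneAgeTable:
    """Gene ages with the planted young cluster's markers skewed young.

    Background genes draw phylostratum ranks uniformly over 1..n_strata;
    markers of cluster ``t{young_cluster}`` take the youngest stratum
    (rank n_strata) with probability ``young_stratum_prob``.
    """
    rng = np.random.default_rng([spec.seed, 7])
    young_id = f"t{spec.young_cluster}"
    if young_id not in marker_map:
        raise ValueError(f"marker map lacks the young cluster {young_id!r}")
    young_markers = set(marker_map[young_id])
    ranks: dict[str, int] = {}
    for g in gene_ids:
        r = int(rng.integers(1, spec.n_strata + 1))
        if g in young_markers and rng.random() < spec.young_stratum_prob:
            r = spec.n_strata
        ranks[g] = r
    return GeneAgeTable(ranks)


def simulate_species_pair(
    spec: SimSpec,
) -> tuple[CountMatrix, CountMatrix, OrthologMap, dict]:
    """Two species sharing cell-type programs through an ortholog map.

    ``shared_types`` types reuse marker programs defined on ancestral
    features that both species carry (a fraction of features duplicated into
    many-to-many ortholog matches); each species additionally has
    ``private_types_per_species`` types marked on unmapped, species-private
    genes. Returns both CountMatrices, the OrthologMap, and a truth dict
    with per-species labels, the shared-type correspondence, and the private
    type ids.
    """
    rng = np.random.default_rng([spec.seed, 11])
    n_feat = spec.ortho_features
    n_types = spec.shared_types + spec.private_types_per_species
    mpc = spec.markers_per_cluster
    # shared programs plus one species-specific signature block per private
    # type and species (private types must be geometrically private in
    # ortholog space, not merely background-like, or the two species'
    # private types would spuriously match each other)
    sig_width = 3 * mpc
    n_sig_feat = spec.shared_types * mpc + 2 * spec.private_types_per_species * sig_width
    if n_sig_feat > n_feat:
        raise ValueError("not enough ortholog features for the marker programs")
    if spec.private_types_per_species * mpc > spec.n_private_genes:
        raise ValueError("not enough private genes for the private marker programs")

    # gene complements: per feature, each species holds 1 gene, or 2 paralogs
    # for a many-to-many feature
    dup_a = rng.random(n_feat) < spec.ortho_many_frac
    dup_b = rng.random(n_feat) < spec.ortho_many_frac

    def build_genes(tag: str, dup: np.ndarray) -> tuple[list[str], list[list[int]]]:
        genes: list[str] = []
        by_feat: list[list[int]] = []
        for f in range(n_feat):
            n_copies = 2 if dup[f] else 1
            idx = []
            for c in range(n_copies):
                idx.append(len(genes))
                genes.append(f"{tag}f{f:04d}_{c}")
            by_feat.append(idx)
        for j in range(spec.n_private_genes):
            genes.append(f"{tag}priv{j:04d}")
        return genes, by_feat

    genes_a, feat_a = build_genes("ga_", dup_a)
    genes_b, feat_b = build_genes("gb_", dup_b)

    records = []
    for f in range(n_feat):
        for ia in feat_a[f]:
            for ib in feat_b[f]:
                records.append((genes_a[ia], genes_b[ib], 1.0))
    omap = OrthologMap(pd.DataFrame(records, columns=["gene_a", "gene_b", "weight"]))

    base_feat = rng.lognormal(0.0, 1.0, size=n_feat)
    base_priv = rng.lognormal(0.0, 1.0, size=spec.n_private_genes)
    shift = 2.0**spec.marker_log2fc

    def species_counts(
        tag: str,
        genes: list[str],
        by_feat: list[list[int]],
        rng_s: np.random.Generator,
        sig_offset: int,
    ) -> tuple[CountMatrix, ClusterLabels, dict[str, list[str]]]:
        n_genes = len(genes)
        type_ids = [f"s{t}" for t in range(spec.shared_types)] + [
            f"p{tag}{t}" for t in range(spec.private_types_per_species)
        ]
        props = np.empty((n_types, n_genes))
        marker_map: dict[str, list[str]] = {}
        for t, tid in enumerate(type_ids):
            feat_expr = base_feat.copy()
            priv_expr = base_priv.copy()
            if t < spec.shared_types:
                lo, hi = t * mpc, (t + 1) * mpc
                feat_expr[lo:hi] *= shift
                marker_map[tid] = [
                    genes[i] for f in range(lo, hi) for i in by_feat[f]
                ]
            else:
                p = t - spec.shared_types
                lo, hi = p * mpc, (p + 1) * mpc
                priv_expr[lo:hi] *= shift
                marker_map[tid] = [
                    genes[n_genes - spec.n_private_genes + j] for j in range(lo, hi)
                ]
                # species-specific signature over mapped features that no
                # type of the other species up-regulates
                s_lo = spec.shared_types * mpc + (sig_offset + p) * sig_width
                feat_expr[s_lo : s_lo + sig_width] *= shift
            gene_expr = np.empty(n_genes)
            for f in range(n_feat):
                share = feat_expr[f] / len(by_feat[f])
                for i in by_feat[f]:
                    gene_expr[i] = share
            gene_expr[n_genes - spec.n_private_genes :] = priv_expr
            props[t] = gene_expr / gene_expr.sum()

        sizes = _cluster_sizes(spec.n_cells, n_types)
        cell_type = np.repeat(np.arange(n_types), sizes)
        depth = rng_s.integers(
            spec.depth_range[0], spec.depth_range[1] + 1, size=spec.n_cells
        )
        mu = depth[:, None] * props[cell_type]
        counts = _nb_sample(rng_s, mu, spec.nb_dispersion)
        cell_ids = [f"{tag}cell{i:05d}" for i in range(spec.n_cells)]
        cm = CountMatrix(
            cell_ids, genes, sp.csr_matrix(counts), np.zeros(n_genes, bool)
        )
        labels = ClusterLabels(
            {cell_ids[i]: type_ids[cell_type[i]] for i in range(spec.n_cells)}
        )
        return cm, labels, marker_map

    cm_a, labels_a, markers_a = species_counts(
        "a", genes_a, feat_a, np.random.default_rng([spec.seed, 12]), 0
    )
    cm_b, labels_b, markers_b = species_counts(
        "b", genes_b, feat_b, np.random.default_rng([spec.seed, 13]),
        spec.private_types_per_species,
    )
    truth = {
        "labels_a": labels_a,
        "labels_b": labels_b,
        "marker_map_a": markers_a,
        "marker_map_b": markers_b,
        "shared_pairs": [(f"s{t}", f"s{t}") for t in range(spec.shared_types)],
        "private_a": [f"pa{t}" for t in range(spec.private_types_per_species)],
        "private_b": [f"pb{t}" for t in range(spec.private_types_per_species)],
    }
    return cm_a, cm_b, omap, truth


def simulate_precursors(
    spec: SimSpec,
) -> tuple[list[tuple[str, str]], pd.DataFrame, dict[str, SignalCall]]:
    """Proteome with planted neuropeptide precursors among random decoys.

    Planted precursors are a signal peptide followed by similar peptide
    repeats separated by dibasic KR sites, a fraction preceded by an
    amidation glycine, and a polar tail. Decoys are random-composition
    proteins, half with a signal-peptide-like N terminus. Returns the
    (id, sequence) list, a truth table of exact planted peptide intervals
    (1-based, post-trimming), and ground-truth signal calls for every
    protein.
    """
    rng = np.random.default_rng([spec.seed, 17])
    proteins: list[tuple[str, str]] = []
    truth_rows = []
    calls: dict[str, SignalCall] = {}

    def draw(alphabet: str, k: int) -> str:
        return "".join(rng.choice(list(alphabet), size=k))

    for i in range(spec.n_precursors):
        pid = f"prec{i:03d}"
        signal = "M" + draw("KR", 1) + draw(_HYDROPHOBIC, 10) + draw("SQTN", 4)
        signal_end = len(signal)  # 1-based index of last signal residue
        base_len = int(rng.integers(8, 13))
        base_pep = draw(_PEPTIDE_ALPHABET, base_len)
        seq = signal
        for _ in range(spec.peptides_per_precursor):
            pep = list(base_pep)
            pos = int(rng.integers(0, base_len))
            pep[pos] = draw(_PEPTIDE_ALPHABET, 1)
            pep = "".join(pep)
            start = len(seq) + 1
            seq += pep
            end = len(seq)
            amidated = bool(rng.random() < spec.amidation_frac)
            if amidated:
                seq += "G"
            seq += "KR"
            truth_rows.append(
                {
                    "protein_id": pid,
                    "start": start,
                    "end": end,
                    "sequence": pep,
                    "amidated": amidated,
                }
            )
        seq += draw(_POLAR_TAIL, 10)
        proteins.append((pid, seq))
        calls[pid] = SignalCall(pid, True, signal_end)

    for i in range(spec.n_decoys):
        pid = f"decoy{i:04d}"
        body = draw(_AA20, int(rng.integers(80, 201)))
        if i % 2 == 0:
            seq = "M" + draw("KR", 1) + draw(_HYDROPHOBIC, 9) + "SS" + body
            calls[pid] = SignalCall(pid, True, 13)
        else:
            seq = "M" + body
            calls[pid] = SignalCall(pid, False)
        proteins.append((pid, seq))

    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "start", "end", "sequence", "amidated"]
    )
    return proteins, truth, calls


def split_clusters(
    labels: ClusterLabels, seed: int, pieces: int = 2
) -> ClusterLabels:
    """Randomly split every cluster into ``pieces`` initial labels.

    Used to emulate over-clustering with known ground truth: the merge
    stage should undo exactly these splits.
    """
    rng = np.random.default_rng([seed, 23])
    assignments: dict[str, str] = {}
    for cid in labels.cluster_ids():
        members = sorted(labels.members(cid))
        perm = rng.permutation(len(members))
        for rank, idx in enumerate(perm):
            part = rank % pieces
            assignments[members[idx]] = f"{cid}_{part}"
    return ClusterLabels(assignments)


def write_counts_bundle(
    cm: CountMatrix, labels: ClusterLabels, out_dir: str | os.PathLike
) -> None:
    """Write matrix.mtx + barcodes.tsv + features.tsv + truth labels."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_mtx_bundle(
        cm,
        os.path.join(out_dir, "matrix.mtx"),
        os.path.join(out_dir, "barcodes.tsv"),
        os.path.join(out_dir, "features.tsv"),
    )
    write_labels(labels, os.path.join(out_dir, "true_labels.tsv"))


def write_fasta(records: list[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_gene_ages(ages: GeneAgeTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        sorted(ages.ranks.items()), columns=["gene_id", "phylostratum_rank"]
    )
    write_tsv_table(df, path)


def write_ortholog_map(omap: OrthologMap, path: str | os.PathLike) -> None:
    write_tsv_table(omap.records, path)


def write_signal_calls(calls: dict[str, SignalCall], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "is_secreted": int(c.is_secreted),
                "cleavage_pos": c.cleavage_pos if c.cleavage_pos is not None else "",
            }
            for c in calls.values()
        ]
    )
    write_tsv_table(df, path)
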