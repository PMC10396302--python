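"""Readers, writers, and the shared in-memory data model.

All external formats are plain text: MatrixMarket MTX plus barcode/feature
TSVs for UMI counts (10x convention: genes x cells on disk), TSV for gene
ages, ortholog maps, labels and result tables, and FASTA for proteins.
In memory every matrix is cells x genes; the transpose happens exactly once,
at the reader boundary.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GeneAgeTable",
    "OrthologMap",
    "ClusterLabels",
    "MergeRecord",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_tsv_table",
    "write_tsv_table",
    "read_fasta",
    "read_gene_ages",
    "read_ortholog_map",
    "read_labels",
    "write_labels",
    "fold_coverage",
]

# Amino-acid alphabet accepted in protein FASTA; X = unknown residue.
_AA_OK = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class CountMatrix:
    """Cells x genes UMI count matrix with mitochondrial gene flags.

    `counts` is stored sparse (CSR, integer); `mito_flags[j]` is True when
    gene j is mitochondrial. Row i corresponds to ``cell_ids[i]``, column j
    to ``gene_ids[j]``.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix
    mito_flags: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.mito_flags) != n_genes:
            raise ValueError("mito_flags length must equal number of genes")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of log1p-scaled normalized expression (dense)."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


class GeneAgeTable:
    """Map from gene id to phylostratum rank (1 = oldest).

    Genes absent from the table are reported, never silently imputed.
    """

    def __init__(
        self,
        ranks: dict[str, int],
        stratum_names: dict[str, str] | None = None,
    ) -> None:
        for g, r in ranks.items():
            if int(r) < 1:
                raise ValueError(f"phylostratum rank must be >= 1, got {r} for {g}")
        self.ranks = {g: int(r) for g, r in ranks.items()}
        self.stratum_names = dict(stratum_names or {})

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.ranks

    def __len__(self) -> int:
        return len(self.ranks)

    def get(self, gene_id: str) -> int | None:
        return self.ranks.get(gene_id)

    def subset(self, gene_ids) -> tuple[dict[str, int], list[str]]:
        """Ranks for the requested genes plus the list of genes without age."""
        present = {g: self.ranks[g] for g in gene_ids if g in self.ranks}
        missing = [g for g in gene_ids if g not in self.ranks]
        return present, missing

    def max_rank(self) -> int:
        return max(self.ranks.values())


class OrthologMap:
    """Weighted bipartite gene map between two species (many-to-many allowed)."""

    def __init__(self, records: pd.DataFrame) -> None:
        required = ["gene_a", "gene_b", "weight"]
        if list(records.columns[:3]) != required:
            records = records.rename(
                columns=dict(zip(records.columns[:3], required))
            )
        records = records[required].copy()
        records["weight"] = records["weight"].astype(float)
        if records.duplicated(["gene_a", "gene_b"]).any():
            dup = records[records.duplicated(["gene_a", "gene_b"])].iloc[0]
            raise ValueError(
                f"duplicate ortholog pair ({dup.gene_a!r}, {dup.gene_b!r})"
            )
        w = records["weight"].to_numpy()
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("ortholog weights must lie in (0, 1]")
        self.records = records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.records["gene_a"], self.records["gene_b"]))


@dataclass
class MergeRecord:
    cluster_kept: str
    cluster_absorbed: str
    de_count: int
    correlation: float
    pass_index: int = 0


@dataclass
class ClusterLabels:
    """Per-cell cluster assignment plus the history of merges that produced it."""

    assignments: dict[str, str]
    merge_log: list[MergeRecord] = field(default_factory=list)

    def cluster_ids(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def members(self, cluster_id: str) -> list[str]:
        return [c for c, k in self.assignments.items() if k == cluster_id]

    def labels_for(self, cell_ids: list[str]) -> np.ndarray:
        missing = [c for c in cell_ids if c not in self.assignments]
        if missing:
            raise KeyError(f"cells without cluster label, e.g. {missing[0]!r}")
        return np.array([self.assignments[c] for c in cell_ids])

    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))


def _read_lines(path: str | os.PathLike) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip() != ""]


def read_mtx_bundle(
    matrix_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    features_path: str | os.PathLike,
    mito_prefix: str = "mt-",
) -> CountMatrix:
    """Read a 10x-style MTX bundle into a cells x genes CountMatrix.

    On disk the matrix is genes x cells (10x convention); it is transposed
    here so the rest of the package never sees that orientation. A gene is
    flagged mitochondrial when its feature name starts with ``mito_prefix``
    (case-insensitive); feature files may carry one column (id) or several
    (id, name, ...), in which case the name column drives the flag.
    """
    mat = scipy.io.mmread(os.fspath(matrix_path))
    barcodes = _read_lines(barcodes_path)
    feature_rows = [ln.split("\t") for ln in _read_lines(features_path)]
    gene_ids = [row[0] for row in feature_rows]
    gene_names = [row[1] if len(row) > 1 else row[0] for row in feature_rows]

    n_genes_disk, n_cells_disk = mat.shape
    if n_genes_disk != len(gene_ids) or n_cells_disk != len(barcodes):
        raise ValueError(
            "dimension mismatch: matrix declares "
            f"{n_genes_disk} genes x {n_cells_disk} cells but features file has "
            f"{len(gene_ids)} entries and barcodes file has {len(barcodes)} entries"
        )
    data = np.asarray(mat.data if sp.issparse(mat) else mat)
    if data.size and (np.any(data < 0) or not np.allclose(data, np.round(data))):
        raise ValueError("matrix entries must be non-negative integers")

    counts = sp.csr_matrix(mat.T)
    prefix = mito_prefix.lower()
    mito = np.array([name.lower().startswith(prefix) for name in gene_names])
    return CountMatrix(barcodes, gene_ids, counts, mito)


def write_mtx_bundle(
    cm: CountMatrix,
    matrix_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    features_path: str | os.PathLike,
) -> None:
    """Write a CountMatrix back to disk in the 10x genes x cells convention."""
    scipy.io.mmwrite(
        os.fspath(matrix_path), sp.coo_matrix(cm.counts.T), field="integer"
    )
    with open(barcodes_path, "w", encoding="utf-8") as fh:
        fh.writelines(b + "\n" for b in cm.cell_ids)
    with open(features_path, "w", encoding="utf-8") as fh:
        fh.writelines(g + "\t" + g + "\n" for g in cm.gene_ids)


def write_tsv_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a rectangular table as UTF-8 TSV with one header row.

    String and integer columns round-trip bit-exactly through
    :func:`read_tsv_table`; reals are written at 6 significant digits.
    """
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_tsv_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read protein FASTA as (id, sequence) pairs.

    Ids are the first whitespace-delimited token after '>'. Sequences are
    upper-cased and trailing '*' stop characters stripped; any residue
    outside the amino-acid alphabet (X allowed) is an error naming the record.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - _AA_OK
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def read_gene_ages(path: str | os.PathLike) -> GeneAgeTable:
    """Read a gene-age TSV (gene_id, phylostratum_rank[, stratum_name])."""
    df = read_tsv_table(path)
    if "gene_id" not in df.columns or "phylostratum_rank" not in df.columns:
        raise ValueError("gene-age table needs gene_id and phylostratum_rank columns")
    ranks = dict(zip(df["gene_id"].astype(str), df["phylostratum_rank"].astype(int)))
    names = (
        dict(zip(df["gene_id"].astype(str), df["stratum_name"].astype(str)))
        if "stratum_name" in df.columns
        else None
    )
    return GeneAgeTable(ranks, names)


def read_ortholog_map(path: str | os.PathLike) -> OrthologMap:
    """Read an ortholog map TSV (gene_a, gene_b[, weight]); weight defaults to 1."""
    df = read_tsv_table(path)
    if "weight" not in df.columns:
        df["weight"] = 1.0
    return OrthologMap(df[["gene_a", "gene_b", "weight"]])


def read_labels(path: str | os.PathLike) -> ClusterLabels:
    df = read_tsv_table(path)
    return ClusterLabels(
        dict(zip(df["cell_id"].astype(str), df["cluster_id"].astype(str)))
    )


def write_labels(labels: ClusterLabels, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        sorted(labels.assignments.items()), columns=["cell_id", "cluster_id"]
    )
    write_tsv_table(df, path)


def fold_coverage(n_cells_captured: int, n_cells_per_animal: int) -> float:
    """How many times over a single animal's cell complement was sampled.

    With 8597 captured cells and fewer than 500 cells per trochophore larva
    this is ~17-fold, i.e. even rare cell types are expected in the atlas.
    """
    if n_cells_per_animal <= 0:
        raise ValueError("cells per animal must be positive")
    return n_cells_captured / n_cells_per_animal
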