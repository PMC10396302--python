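"""QC boundary semantics, normalization identities, variable genes, PCA, SNN clustering."""

import warnings

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.spatial.distance import pdist

from larvatlas import (
    CountMatrix,
    ExpressionMatrix,
    QCParams,
    embed_pca,
    filter_cells,
    initial_clusters,
    normalize_log1p,
    select_variable_genes,
)
from larvatlas.preprocess import Embedding


def _cm(counts, mito=None, cells=None, genes=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    return CountMatrix(
        cells or [f"c{i}" for i in range(n_cells)],
        genes or [f"g{j}" for j in range(n_genes)],
        sp.csr_matrix(counts),
        mito if mito is not None else np.zeros(n_genes, bool),
    )


class TestFilterCells:
    def test_detected_gene_boundary_is_strict(self):
        # 199 detected genes -> removed; 200 -> kept (default threshold 200)
        counts = np.zeros((2, 210), dtype=int)
        counts[0, :199] = 1
        counts[1, :200] = 1
        out, report = filter_cells(_cm(counts), QCParams())
        assert out.cell_ids == ["c1"]
        assert report.removed_low_genes == 1

    def test_mito_fraction_oyster_vs_flatworm_presets(self):
        counts = np.array([[25, 75], [10, 90]])
        cm = _cm(counts, mito=np.array([True, False]))
        qc = QCParams(min_genes_per_cell=1)
        out, report = filter_cells(cm, qc)
        assert out.cell_ids == ["c1"] and report.removed_high_mito == 1
        out2, _ = filter_cells(cm, QCParams(min_genes_per_cell=1, max_mito_fraction=0.30))
        assert out2.cell_ids == ["c0", "c1"]

    def test_umi_bound_exact_value_kept_upper_strict(self):
        counts = np.array([[5000], [5001], [10]])
        out, report = filter_cells(_cm(counts), QCParams(min_genes_per_cell=0))
        assert out.cell_ids == ["c0", "c2"]
        assert report.removed_umi_bound == 1

    def test_umi_bound_lower_side(self):
        counts = np.array([[400], [600]])
        qc = QCParams(min_genes_per_cell=0, umi_bound=500, umi_bound_side="lower")
        out, _ = filter_cells(_cm(counts), qc)
        assert out.cell_ids == ["c1"]

    def test_zero_count_genes_dropped_and_listed(self):
        counts = np.array([[3, 0, 1], [2, 0, 5]])
        out, report = filter_cells(_cm(counts), QCParams(min_genes_per_cell=0))
        assert out.gene_ids == ["g0", "g2"]
        assert report.dropped_genes == ["g1"]

    def test_idempotent(self):
        counts = np.array([[5000], [5001], [10], [0]])
        cm = _cm(counts)
        once, _ = filter_cells(cm, QCParams(min_genes_per_cell=0))
        twice, rep = filter_cells(once, QCParams(min_genes_per_cell=0))
        assert twice.cell_ids == once.cell_ids
        assert twice.gene_ids == once.gene_ids
        assert (twice.dense() == once.dense()).all()

    def test_all_removed_is_an_error(self):
        with pytest.raises(ValueError, match="review"):
            filter_cells(_cm(np.array([[1]])), QCParams(min_genes_per_cell=5))


class TestNormalize:
    def test_hand_value_ln_5001(self):
        em = normalize_log1p(_cm(np.array([[1, 1]])))
        assert np.allclose(em.values, np.log(5001.0))
        assert em.values[0, 0] == pytest.approx(8.5174, abs=1e-3)

    def test_within_cell_scale_invariance(self, rng):
        counts = rng.integers(0, 20, size=(3, 8))
        counts[:, 0] += 1
        em1 = normalize_log1p(_cm(counts))
        em2 = normalize_log1p(_cm(counts * 7))
        assert np.allclose(em1.values, em2.values)

    def test_all_zero_gene_stays_zero(self):
        em = normalize_log1p(_cm(np.array([[2, 0], [3, 0]])))
        assert (em.values[:, 1] == 0).all()

    def test_zero_total_cell_is_an_error(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_log1p(_cm(np.array([[0, 0], [1, 2]])))


class TestVariableGenes:
    def test_constant_gene_never_beats_varying_gene(self, rng):
        counts = rng.poisson(5.0, size=(50, 10))
        counts[:, 3] = 7  # constant
        counts[:, 0] += 1
        cm = _cm(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            picked = select_variable_genes(cm, n=9)
        assert "g3" not in picked

    def test_planted_high_dispersion_genes_recovered(self, rng):
        n_cells, n_genes = 200, 1000
        means = rng.lognormal(1.0, 0.5, size=n_genes)
        counts = rng.poisson(means, size=(n_cells, n_genes)).astype(float)
        planted = rng.choice(n_genes, size=50, replace=False)
        # mean-preserving gamma multiplier -> far larger dispersion
        mult = rng.gamma(shape=0.25, scale=4.0, size=(n_cells, 50))
        counts[:, planted] = rng.poisson(means[planted] * mult)
        cm = _cm(counts.astype(int))
        top100 = set(select_variable_genes(cm, n=100))
        recovered = sum(1 for j in planted if f"g{j}" in top100)
        assert recovered == 50

    def test_requesting_more_than_available_warns_and_returns_all(self):
        counts = np.array([[1, 5, 5], [2, 5, 5], [3, 5, 5]])
        with pytest.warns(UserWarning, match="eligible"):
            picked = select_variable_genes(_cm(counts), n=3)
        assert picked == ["g0"]


def _em(values, cells=None):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        cells or [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        values,
    )


class TestEmbedPCA:
    def test_rank_two_data_embeds_losslessly(self, rng):
        basis = rng.normal(size=(2, 10))
        weights = rng.normal(size=(40, 2))
        x = weights @ basis
        x = x - x.min()  # shift non-negative; centered data still rank <= 2
        em = _em(x)
        emb = embed_pca(em, d=2, clip=50.0)
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        z = (x - mean) / np.where(sd > 0, sd, 1.0)
        assert np.allclose(pdist(emb.coordinates), pdist(z), atol=1e-8)

    def test_sign_convention_flips_with_data(self, rng):
        x = rng.uniform(0, 4, size=(30, 6))
        emb1 = embed_pca(_em(x), d=3, clip=50.0)
        emb2 = embed_pca(_em(x.max() - x), d=3, clip=50.0)
        assert np.allclose(emb1.coordinates, -emb2.coordinates, atol=1e-8)

    def test_identical_cells_identical_rows(self, rng):
        x = rng.uniform(0, 2, size=(10, 5))
        x[3] = x[7]
        emb = embed_pca(_em(x), d=2)
        assert np.allclose(emb.coordinates[3], emb.coordinates[7])

    def test_d_too_large_errors(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            embed_pca(_em(rng.uniform(0, 1, size=(4, 6))), d=5)


class TestInitialClusters:
    @staticmethod
    def _two_blobs(rng, n=80, sep=20.0):
        a = rng.normal(0, 1, size=(n, 5))
        b = rng.normal(0, 1, size=(n, 5))
        b[:, 0] += sep
        coords = np.vstack([a, b])
        ids = [f"c{i:03d}" for i in range(2 * n)]
        truth = np.array([0] * n + [1] * n)
        return Embedding(ids, coords), truth

    def test_two_blobs_resolution_one_gives_two_clusters(self, rng):
        emb, truth = self._two_blobs(rng)
        labels = initial_clusters(emb, resolution=1.0, seed=0)
        assert labels.n_clusters() == 2
        lab = labels.labels_for(emb.cell_ids)
        for cid in set(lab):
            assert len(set(truth[lab == cid])) == 1

    def test_same_seed_same_labels(self, rng):
        emb, _ = self._two_blobs(rng)
        l1 = initial_clusters(emb, resolution=4.0, seed=7)
        l2 = initial_clusters(emb, resolution=4.0, seed=7)
        assert l1.assignments == l2.assignments

    def test_high_resolution_refines_but_never_straddles_blobs(self, rng):
        emb, truth = self._two_blobs(rng)
        labels = initial_clusters(emb, resolution=10.0, seed=0)
        assert labels.n_clusters() >= 2
        lab = labels.labels_for(emb.cell_ids)
        for cid in set(lab):
            assert len(set(truth[lab == cid])) == 1

    def test_too_few_cells_errors(self, rng):
        emb = Embedding(["a", "b"], rng.normal(size=(2, 2)))
        with pytest.raises(ValueError, match="k_neighbors"):
            initial_clusters(emb, k_neighbors=20)
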