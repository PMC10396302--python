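"""Centroids, pair ranking, DE counting (with exact oracles), and iterative merging."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from larvatlas import (
    ClusterLabels,
    ExpressionMatrix,
    MergeParams,
    SimSpec,
    audit_no_mergeable_pairs,
    cluster_centroids,
    de_gene_count,
    merge_iterate,
    normalize_log1p,
    rank_cluster_pairs,
    simulate_counts,
    split_clusters,
)
from larvatlas._stats import mannwhitney_u


def _em(values):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        values,
    )


def _labels(assignment_list):
    return ClusterLabels({f"c{i}": lab for i, lab in enumerate(assignment_list)})


class TestCentroids:
    def test_singleton_and_two_cell_means(self):
        em = _em([[2.0, 1.0], [4.0, 1.0], [9.0, 9.0]])
        cent = cluster_centroids(em, _labels(["a", "a", "b"]))
        assert cent.loc["a"].tolist() == [3.0, 1.0]
        assert cent.loc["b"].tolist() == [9.0, 9.0]

    def test_matches_brute_force_on_random_fixture(self, rng):
        values = rng.uniform(0, 5, size=(20, 10))
        labs = rng.choice(["x", "y", "z"], size=20).tolist()
        cent = cluster_centroids(_em(values), _labels(labs))
        for cid in set(labs):
            rows = [i for i, l in enumerate(labs) if l == cid]
            expected = np.array([np.mean([values[i, j] for i in rows]) for j in range(10)])
            assert np.allclose(cent.loc[cid].to_numpy(), expected)

    def test_empty_cluster_errors(self):
        em = _em([[1.0, 2.0]])
        with pytest.raises(KeyError):
            cluster_centroids(em, ClusterLabels({"other": "a"}))


class TestRankPairs:
    def test_identical_first_negated_last(self):
        cent = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0],
                "b": [1.0, 2.0, 3.0],
                "c": [3.0, 2.0, 1.0],
            }
        ).T
        ranked = rank_cluster_pairs(cent)
        assert ranked[0][:2] == ("a", "b") and ranked[0][2] == pytest.approx(1.0)
        assert ranked[-1][2] == pytest.approx(-1.0)

    def test_matches_brute_force_correlation_sort(self, rng):
        cent = pd.DataFrame(
            rng.normal(size=(4, 12)), index=["p", "q", "r", "s"]
        )
        ranked = rank_cluster_pairs(cent)
        expected = []
        for c1, c2 in combinations(sorted(cent.index), 2):
            r = np.corrcoef(cent.loc[c1], cent.loc[c2])[0, 1]
            expected.append((c1, c2, r))
        expected.sort(key=lambda t: (-t[2], t[0], t[1]))
        assert [t[:2] for t in ranked] == [t[:2] for t in expected]
        assert np.allclose([t[2] for t in ranked], [t[2] for t in expected])

    def test_constant_centroid_gets_zero_correlation_with_warning(self):
        cent = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 3.0]}).T
        with pytest.warns(UserWarning, match="constant"):
            ranked = rank_cluster_pairs(cent)
        assert ranked[0][2] == 0.0


class TestDEGeneCount:
    def test_null_groups_yield_zero_de(self, rng):
        x = rng.gamma(2.0, 1.0, size=(40, 500))
        em = _em(x)
        n_de, _ = de_gene_count(em, em.cell_ids[:20], em.cell_ids[20:])
        assert n_de == 0

    def test_planted_disjoint_support_all_detected(self, rng):
        x = rng.gamma(2.0, 1.0, size=(40, 500)) + 0.5
        x[:20, :30] = 5.0
        x[20:, :30] = 0.0
        em = _em(x)
        n_de, table = de_gene_count(em, em.cell_ids[:20], em.cell_ids[20:])
        assert n_de == 30
        assert set(table[table["is_de"]]["gene_id"]) == {f"g{j}" for j in range(30)}

    def test_symmetric_in_groups(self, rng):
        x = rng.gamma(1.0, 2.0, size=(16, 80))
        em = _em(x)
        a, b = em.cell_ids[:7], em.cell_ids[7:]
        assert de_gene_count(em, a, b)[0] == de_gene_count(em, b, a)[0]

    def test_identical_constant_groups_zero(self):
        em = _em(np.ones((8, 20)))
        assert de_gene_count(em, em.cell_ids[:4], em.cell_ids[4:])[0] == 0

    def test_small_group_rejected(self):
        em = _em(np.ones((5, 3)))
        with pytest.raises(ValueError, match=">= 3"):
            de_gene_count(em, em.cell_ids[:2], em.cell_ids[2:])


class TestWilcoxonOracle:
    def test_u_statistic_matches_pairwise_enumeration(self, rng):
        """U from the rank formula equals the defining count over all (a, b) pairs."""
        for _ in range(200):
            n_a = int(rng.integers(3, 7))
            n_b = int(rng.integers(3, 7))
            # integer values force ties
            a = rng.integers(0, 5, size=n_a).astype(float)
            b = rng.integers(0, 5, size=n_b).astype(float)
            u = mannwhitney_u(a[:, None], b[:, None])[0]
            brute = sum(
                1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
            )
            assert u == pytest.approx(brute)

    def test_agrees_with_scipy_mannwhitneyu(self, rng):
        for _ in range(50):
            a = rng.normal(size=(6, 1))
            b = rng.normal(size=(5, 1))
            u = mannwhitney_u(a, b)[0]
            assert u == pytest.approx(mannwhitneyu(a.ravel(), b.ravel()).statistic)


class TestMergeIterate:
    def test_distinct_clusters_are_a_fixed_point(self, planted_dataset):
        _, cm, em, truth, _ = planted_dataset
        merged = merge_iterate(em, truth)
        assert merged.assignments == truth.assignments
        assert merged.merge_log == []

    def test_single_planted_split_merges_once(self):
        spec = SimSpec(seed=5, n_cells=120, n_genes=800, n_clusters=2)
        cm, truth, _ = simulate_counts(spec)
        em = normalize_log1p(cm)
        # split only the first type
        assignments = dict(truth.assignments)
        t0_cells = sorted(truth.members("t0"))
        for c in t0_cells[: len(t0_cells) // 2]:
            assignments[c] = "t0_bis"
        merged = merge_iterate(em, ClusterLabels(assignments))
        assert merged.n_clusters() == 2
        assert len(merged.merge_log) == 1
        rec = merged.merge_log[0]
        assert rec.de_count < MergeParams().de_gene_threshold

    def test_all_types_split_fully_recovered(self):
        spec = SimSpec(seed=11, n_cells=180, n_genes=2000, n_clusters=3)
        cm, truth, _ = simulate_counts(spec)
        em = normalize_log1p(cm)
        merged = merge_iterate(em, split_clusters(truth, seed=11))
        assert merged.n_clusters() == 3
        ari = adjusted_rand_score(
            truth.labels_for(cm.cell_ids), merged.labels_for(cm.cell_ids)
        )
        assert ari == 1.0
        assert audit_no_mergeable_pairs(em, merged)

    def test_merge_count_bounded_by_initial_clusters(self, planted_dataset):
        _, cm, em, truth, _ = planted_dataset
        split = split_clusters(truth, seed=1)
        merged = merge_iterate(em, split)
        assert len(merged.merge_log) <= split.n_clusters() - 1
        assert merged.n_clusters() <= split.n_clusters()

    def test_kept_cluster_takes_smaller_id(self):
        spec = SimSpec(seed=5, n_cells=100, n_genes=500, n_clusters=2, marker_log2fc=0.0)
        cm, truth, _ = simulate_counts(spec)
        em = normalize_log1p(cm)
        merged = merge_iterate(em, truth)
        assert merged.n_clusters() == 1
        assert set(merged.assignments.values()) == {"t0"}
        for rec in merged.merge_log:
            assert rec.cluster_kept < rec.cluster_absorbed
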