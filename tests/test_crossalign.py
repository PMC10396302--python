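"""Ortholog-space collapse, joint embedding, mutual neighbors, alignment scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from larvatlas import (
    ClusterLabels,
    ExpressionMatrix,
    MarkerTable,
    OrthologMap,
    SimSpec,
    alignment_scores,
    best_matches,
    collapse_to_ortholog_space,
    joint_embedding,
    mutual_nn,
    normalize_log1p,
    shared_markers,
    simulate_species_pair,
)


def _em(values, prefix="c", genes=None):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(values.shape[0])],
        genes or [f"g{j}" for j in range(values.shape[1])],
        values,
    )


def _omap(pairs, weight=1.0):
    return OrthologMap(
        pd.DataFrame(
            [(a, b, weight) for a, b in pairs],
            columns=["gene_a", "gene_b", "weight"],
        )
    )


class TestCollapse:
    def test_one_to_one_identity_is_column_subset(self, rng):
        x = rng.uniform(0, 3, size=(5, 4))
        em_a = _em(x, "a")
        em_b = _em(rng.uniform(0, 3, size=(6, 4)), "b")
        omap = _omap([(f"g{j}", f"g{j}") for j in range(3)])
        ma, mb, info = collapse_to_ortholog_space(em_a, em_b, omap)
        assert info["n_features"] == 3
        # each shared feature is exactly one original column
        recovered = {tuple(ma.values[:, f]) for f in range(3)}
        original = {tuple(x[:, j]) for j in range(3)}
        assert recovered == original

    def test_many_to_one_weight_average(self):
        em_a = _em(np.array([[2.0, 4.0]]), "a", genes=["g1", "g2"])
        em_b = _em(np.array([[7.0]]), "b", genes=["h"])
        ma, mb, _ = collapse_to_ortholog_space(
            em_a, em_b, _omap([("g1", "h"), ("g2", "h")])
        )
        assert ma.values[0, 0] == pytest.approx(3.0)  # mean(2, 4)
        assert mb.values[0, 0] == pytest.approx(7.0)

    def test_absent_gene_records_skipped_with_warning(self, rng):
        em_a = _em(rng.uniform(0, 1, size=(3, 2)), "a")
        em_b = _em(rng.uniform(0, 1, size=(3, 2)), "b")
        omap = _omap([("g0", "g0"), ("missing", "g1")])
        with pytest.warns(UserWarning, match="skipped"):
            _, _, info = collapse_to_ortholog_space(em_a, em_b, omap)
        assert info["n_skipped_records"] == 1

    def test_empty_intersection_errors(self, rng):
        em_a = _em(rng.uniform(0, 1, size=(3, 2)), "a")
        em_b = _em(rng.uniform(0, 1, size=(3, 2)), "b")
        with pytest.raises(ValueError, match="no ortholog record"):
            with pytest.warns(UserWarning):
                collapse_to_ortholog_space(em_a, em_b, _omap([("zz", "qq")]))


class TestJointEmbedding:
    def test_duplicate_dataset_gives_identical_paired_coordinates(self, rng):
        x = rng.uniform(0, 5, size=(25, 8))
        em = _em(x)
        joint = joint_embedding(em, em, d=4)
        emb_a, emb_b = joint.split()
        assert np.allclose(emb_a.coordinates, emb_b.coordinates)
        assert emb_b.cell_ids == [f"b:{c}" for c in em.cell_ids]

    def test_cell_permutation_permutes_rows(self, rng):
        x = rng.uniform(0, 5, size=(12, 6))
        em_a = _em(x, "a")
        em_b = _em(rng.uniform(0, 5, size=(12, 6)), "b")
        joint = joint_embedding(em_a, em_b, d=3)
        perm = rng.permutation(12)
        em_a2 = ExpressionMatrix(
            [em_a.cell_ids[i] for i in perm], em_a.gene_ids, x[perm]
        )
        joint2 = joint_embedding(em_a2, em_b, d=3)
        assert np.allclose(joint.coordinates[perm], joint2.coordinates[:12])


class TestMutualNN:
    def test_duplicate_dataset_k1_yields_twin_pairs(self, rng):
        x = rng.uniform(0, 5, size=(30, 6))
        em = _em(x)
        joint = joint_embedding(em, em, d=4)
        pairs = mutual_nn(joint, k=1)
        assert pairs == {(c, f"b:{c}") for c in em.cell_ids}

    def test_matches_brute_force_scan(self, rng):
        x = rng.normal(size=(90, 5))
        y = rng.normal(size=(110, 5))
        from larvatlas.crossalign import JointEmbedding

        ids = [f"a{i:03d}" for i in range(90)] + [f"b{i:03d}" for i in range(110)]
        species = np.array(["a"] * 90 + ["b"] * 110)
        joint = JointEmbedding(ids, species, np.vstack([x, y]))
        k = 7
        pairs = mutual_nn(joint, k=k)
        dist = cdist(x, y)
        nn_a = [set(np.argsort(dist[i])[:k]) for i in range(90)]
        nn_b = [set(np.argsort(dist[:, j])[:k]) for j in range(110)]
        brute = {
            (ids[i], ids[90 + j])
            for i in range(90)
            for j in nn_a[i]
            if i in nn_b[j]
        }
        assert pairs == brute

    def test_more_neighbors_never_fewer_pairs(self, rng):
        x = rng.normal(size=(40, 4))
        y = rng.normal(size=(40, 4))
        from larvatlas.crossalign import JointEmbedding

        ids = [f"a{i}" for i in range(40)] + [f"b{i}" for i in range(40)]
        joint = JointEmbedding(
            ids, np.array(["a"] * 40 + ["b"] * 40), np.vstack([x, y])
        )
        sizes = [len(mutual_nn(joint, k=k)) for k in (2, 5, 10, 20)]
        assert sizes == sorted(sizes)


class TestAlignmentScores:
    def test_self_alignment_identity(self, rng):
        x = rng.uniform(0, 5, size=(40, 10))
        em = _em(x)
        labs = ClusterLabels(
            {c: ("u" if i < 20 else "v") for i, c in enumerate(em.cell_ids)}
        )
        labs_b = ClusterLabels({f"b:{c}": l for c, l in labs.assignments.items()})
        joint = joint_embedding(em, em, d=5)
        pairs = mutual_nn(joint, k=1)
        full, pruned = alignment_scores(pairs, labs, labs_b, k=1)
        assert np.allclose(np.diag(full.to_numpy()), 1.0)
        assert full.to_numpy().sum() == pytest.approx(2.0)  # off-diagonal all zero

    def test_no_pairs_gives_zero_and_range_bound(self):
        labs_a = ClusterLabels({"a1": "x", "a2": "x"})
        labs_b = ClusterLabels({"b1": "y"})
        full, _ = alignment_scores(set(), labs_a, labs_b, k=3)
        assert (full.to_numpy() == 0).all()

    def test_planted_shared_types_recovered(self):
        spec = SimSpec(seed=2)
        cm_a, cm_b, omap, truth = simulate_species_pair(spec)
        ma, mb, _ = collapse_to_ortholog_space(
            normalize_log1p(cm_a), normalize_log1p(cm_b), omap
        )
        joint = joint_embedding(ma, mb, d=30)
        pairs = mutual_nn(joint, k=20)
        full, _ = alignment_scores(pairs, truth["labels_a"], truth["labels_b"], k=20)
        assert ((full.to_numpy() >= 0) & (full.to_numpy() <= 1)).all()
        bm = best_matches(full)
        for a, b in truth["shared_pairs"]:
            assert bm[a] == b
        for p in truth["private_a"]:
            assert full.loc[p].max() < 0.1


class TestSharedMarkers:
    @staticmethod
    def _markers(cid, genes):
        return MarkerTable(
            {
                cid: pd.DataFrame(
                    {"gene_id": genes, "adjusted_p": [0.01] * len(genes),
                     "log2fc": [1.0] * len(genes)}
                )
            }
        )

    def test_disjoint_marker_sets_empty_report(self):
        rep = shared_markers(
            self._markers("a", ["g1"]),
            self._markers("b", ["h9"]),
            _omap([("g2", "h2")]),
            ("a", "b"),
        )
        assert rep.records.empty and rep.n_genes_a == 0

    def test_many_to_one_gives_unequal_counts(self):
        rep = shared_markers(
            self._markers("a", ["g1", "g2"]),
            self._markers("b", ["h"]),
            _omap([("g1", "h"), ("g2", "h")]),
            ("a", "b"),
        )
        assert (rep.n_genes_a, rep.n_genes_b) == (2, 1)

    def test_report_is_subset_of_ortholog_map(self, rng):
        genes_a = [f"g{j}" for j in range(10)]
        genes_b = [f"h{j}" for j in range(10)]
        all_pairs = [(a, b) for a in genes_a for b in genes_b if rng.random() < 0.2]
        omap = _omap(all_pairs)
        rep = shared_markers(
            self._markers("a", genes_a[:5]),
            self._markers("b", genes_b[:5]),
            omap,
            ("a", "b"),
        )
        assert set(map(tuple, rep.records[["gene_a", "gene_b"]].values)) <= set(all_pairs)
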