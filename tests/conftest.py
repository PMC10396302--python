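import numpy as np
import pytest
import scipy.sparse as sp

from larvatlas import CountMatrix, SimSpec, normalize_log1p, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_counts():
    """4 cells x 5 genes with one mitochondrial gene, hand-checkable."""
    counts = np.array(
        [
            [5, 0, 1, 2, 0],
            [0, 3, 1, 0, 4],
            [1, 1, 1, 1, 1],
            [0, 0, 8, 0, 2],
        ]
    )
    return CountMatrix(
        ["c1", "c2", "c3", "c4"],
        ["mt-co1", "g1", "g2", "g3", "g4"],
        sp.csr_matrix(counts),
        np.array([True, False, False, False, False]),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Simulated 4-type dataset with normalized expression, shared per session."""
    spec = SimSpec(seed=42, n_cells=240, n_genes=1200, n_clusters=4)
    cm, labels, marker_map = simulate_counts(spec)
    em = normalize_log1p(cm)
    return spec, cm, em, labels, marker_map
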