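import dendropy
import numpy as np
import pytest
from hypothesis import settings

from cryodiv.io import DistanceMatrix, OtuTable, validate_tree

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def make_tree():
    """Parse a Newick string into a validated rooted tree."""

    def _make(newick: str):
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return validate_tree(tree)

    return _make


@pytest.fixture
def cherry_tree(make_tree):
    return make_tree("(A:1,B:2);")


@pytest.fixture
def make_distance_matrix():
    """Build a DistanceMatrix from a condensed (upper-triangle) vector."""

    def _make(labels, condensed):
        n = len(labels)
        mat = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        mat[iu] = condensed
        mat += mat.T
        return DistanceMatrix(labels, mat)

    return _make


@pytest.fixture
def random_distance_matrix():
    """Euclidean distances of random planar points (a generic, tie-free matrix)."""

    def _make(n, seed, labels=None):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return DistanceMatrix(labels or [f"s{i}" for i in range(n)], d)

    return _make


@pytest.fixture
def small_table():
    return OtuTable(
        ("s1", "s2"),
        ("A", "B", "C"),
        np.array([[10, 0, 5], [0, 10, 5]]),
    )
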