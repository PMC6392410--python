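"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (double loops, exhaustive
enumeration) and independent of the library's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from hummnet import BipartiteMatrix


def make_matrix(cells, order_mode="given"):
    cells = np.asarray(cells, dtype=np.int8)
    rows = [f"fam{i + 1:02d}" for i in range(cells.shape[0])]
    cols = [f"clade{j + 1:02d}" for j in range(cells.shape[1])]
    return BipartiteMatrix(rows, cols, cells, order_mode)


def random_matrix(rng, n_rows, n_cols, fill):
    """Random binary matrix without empty rows/columns."""
    while True:
        cells = (rng.random((n_rows, n_cols)) < fill).astype(np.int8)
        if cells.any(axis=1).all() and cells.any(axis=0).all():
            return make_matrix(cells)


def nodf_brute_force(cells) -> float:
    """Direct double-loop NODF on a matrix already in its operative order."""
    a = np.asarray(cells)

    def axis_terms(a):
        terms = []
        for u in range(a.shape[0]):
            for v in range(u + 1, a.shape[0]):
                du, dv = a[u].sum(), a[v].sum()
                if du <= dv:
                    terms.append(0.0)
                else:
                    overlap = int((a[u] & a[v]).sum())
                    terms.append(100.0 * overlap / dv)
        return terms

    terms = axis_terms(a) + axis_terms(a.T)
    return float(np.mean(terms))


def set_partitions(items):
    """All set partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def modularity_networkx(edges, communities, nodes=None):
    """Newman-Girvan modularity via networkx (independent implementation)."""
    import networkx as nx

    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return nx.algorithms.community.modularity(g, communities)


def best_partition_exhaustive(graph):
    """Exhaustive-maximum modularity via the networkx oracle."""
    best_m, best_p = -np.inf, None
    for part in set_partitions(list(graph.nodes)):
        m = modularity_networkx(graph.edges, [set(block) for block in part], graph.nodes)
        if m > best_m:
            best_m, best_p = m, part
    return best_m, best_p


@pytest.fixture
def rng():
    return np.random.default_rng(20190227)


@pytest.fixture
def nested_matrix():
    """5x5 strictly nested staircase."""
    return make_matrix(np.tril(np.ones((5, 5))), order_mode="degree")


@pytest.fixture
def two_triangles():
    from hummnet import Graph

    return Graph(
        tuple("abcdef"),
        (("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")),
    )
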