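import numpy as np
import pytest

from radiascan.io import MarkerMatrix


@pytest.fixture
def tiny_matrix() -> MarkerMatrix:
    """4 samples x 3 loci, no replicates."""
    calls = np.array([
        [1, 0, 1],
        [1, 1, 1],
        [0, 0, 0],
        [0, 1, 0],
    ], dtype=np.int8)
    return MarkerMatrix(["x1", "x2", "y1", "y2"], ["L1", "L2", "L3"], calls)


@pytest.fixture
def rep_matrix() -> MarkerMatrix:
    """3 samples, one replicated, 4 loci."""
    calls = np.array([
        [1, 0, 1, 0],
        [0, 1, 1, 0],
        [1, 1, 0, 0],
        [1, 0, 0, 0],
    ], dtype=np.int8)
    return MarkerMatrix(
        ["a", "b", "c", "a_rep1"],
        ["L1", "L2", "L3", "L4"],
        calls,
        {"a_rep1": "a"},
    )


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree as (edge list, leaf names); used as an
    independent oracle for NJ exactness.

    Returns (dist_matrix, newick-ish adjacency) where dist is the path-length
    matrix between leaves.
    """
    # node ids: 0..n_taxa-1 leaves; grow by random attachment
    import itertools
    edges = {}  # (u, v) -> length
    next_node = n_taxa
    # start with a 3-star
    center = next_node
    next_node += 1
    for leaf in range(3):
        edges[(center, leaf)] = rng.uniform(0.1, 1.0)
    for leaf in range(3, n_taxa):
        # pick a random existing edge, subdivide, hang the new leaf
        (u, v), ln = list(edges.items())[rng.integers(len(edges))]
        del edges[(u, v)]
        mid = next_node
        next_node += 1
        cut = rng.uniform(0.25, 0.75) * ln
        edges[(u, mid)] = cut
        edges[(mid, v)] = ln - cut
        edges[(mid, leaf)] = rng.uniform(0.1, 1.0)

    # all-pairs path lengths over the tree
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), ln in edges.items():
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))
    n_nodes = next_node
    dist = np.full((n_taxa, n_taxa), np.nan)
    for src in range(n_taxa):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, ln in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + ln
                    stack.append(y)
        for dst in range(n_taxa):
            dist[src, dst] = seen[dst]
    np.fill_diagonal(dist, 0.0)
    return dist, edges
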