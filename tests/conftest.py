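"""Shared fixtures and independent oracle helpers.

The helpers here deliberately avoid the ggkit implementations they are used
to check: brute-force pair distances enumerate genotype multisets directly,
random trees are built by edge splitting, and tree path lengths / splits
are recomputed by plain graph traversal.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from ggkit.genotype_io import GenotypeMatrix


# ---------------------------------------------------------------------------
# brute-force allele-difference oracle
# ---------------------------------------------------------------------------

def brute_pair_distance(matrix: GenotypeMatrix, i: int, j: int) -> tuple[int, int]:
    """(allele differences, loci compared) by direct multiset enumeration."""
    total = 0
    compared = 0
    for l in range(matrix.n_loci):
        a = matrix.calls[i, l]
        b = matrix.calls[j, l]
        if a[0] < 0 or b[0] < 0:
            continue
        compared += 1
        inter = sum((Counter(a.tolist()) & Counter(b.tolist())).values())
        total += 2 - inter
    return total, compared


# ---------------------------------------------------------------------------
# random additive trees (independent of ggkit.nj_phylogeny)
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree with branch lengths in [0.1, 2.0].

    Returns (adjacency, leaf_names): adjacency[u][v] = edge length, leaves
    are nodes 0..n_leaves-1 named 'T0'..'T{n-1}'.
    """
    assert n_leaves >= 3
    adj: dict[int, dict[int, float]] = {}
    nxt = n_leaves  # internal node ids

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    def blen():
        return float(rng.uniform(0.1, 2.0))

    hub = nxt
    nxt += 1
    for leaf in range(3):
        connect(leaf, hub, blen())
    for leaf in range(3, n_leaves):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid = nxt
        nxt += 1
        split = float(rng.uniform(0.2, 0.8))
        disconnect(u, v)
        connect(u, mid, w * split)
        connect(mid, v, w * (1 - split))
        connect(leaf, mid, blen())
    names = {i: f"T{i}" for i in range(n_leaves)}
    return adj, names


def tree_path_lengths(adj, leaves: list[int]) -> np.ndarray:
    """Leaf-to-leaf path lengths by BFS over the adjacency."""
    n = len(leaves)
    out = np.zeros((n, n))
    for a, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for b, dst in enumerate(leaves):
            out[a, b] = dist[dst]
    return out


def tree_splits(adj, names: dict[int, str]) -> set[frozenset]:
    """Canonical non-trivial bipartitions of an adjacency tree."""
    all_names = set(names.values())
    ref = min(all_names)
    out = set()
    for u in adj:
        for v in adj[u]:
            if u < v and u not in names and v not in names:
                side = set()
                seen = {u, v}
                stack = [v]
                while stack:
                    x = stack.pop()
                    if x in names:
                        side.add(names[x])
                    for y in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                if 2 <= len(side) <= len(all_names) - 2:
                    if ref in side:
                        side = all_names - side
                    out.add(frozenset(side))
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20180921)


@pytest.fixture
def small_matrix():
    """4 samples x 3 biallelic loci with one missing call."""
    import numpy as np

    calls = np.array(
        [
            [[0, 0], [0, 1], [1, 1]],
            [[0, 0], [1, 1], [1, 1]],
            [[-1, -1], [0, 1], [0, 0]],
            [[0, 1], [0, 0], [0, 1]],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix(
        ["s1", "s2", "s3", "s4"],
        ["L1", "L2", "L3"],
        calls,
        [("A", "B")] * 3,
    )
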