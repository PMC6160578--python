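"""Neighbor-joining trees with locus-resampling bootstrap support.

Saitou-Nei agglomeration with the Studier-Keppler Q criterion; ties in the
Q minimization are broken by the lexicographically smallest active index
pair so output is deterministic.  Negative branch lengths are clamped to
zero (the clamped deficit is logged).  Trees are unrooted and binary: N
leaves give N-2 internal nodes, the last of which is a degree-3 hub.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genotype_io import GenotypeMatrix
from .identity_matching import _pairwise_from_calls

logger = logging.getLogger(__name__)

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


@dataclass
class PhyloTree:
    """Unrooted tree: adjacency with branch lengths plus leaf names.

    ``adjacency[u][v]`` is the length of edge (u, v); ``leaf_names`` maps
    leaf node ids to sample ids.  ``supports`` maps a canonical bipartition
    (frozenset of leaf names on the side NOT containing the reference leaf,
    i.e. the lexicographically smallest name) to a bootstrap percentage.
    """

    adjacency: dict[int, dict[int, float]]
    leaf_names: dict[int, str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    # -- structure ----------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def internal_nodes(self) -> list[int]:
        return [u for u in self.adjacency if u not in self.leaf_names]

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaf names reachable from v when edge (u, v) is removed."""
        seen = {u, v}
        stack = [v]
        out = set()
        while stack:
            x = stack.pop()
            if x in self.leaf_names:
                out.add(self.leaf_names[x])
            for y in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return out

    def _canonical(self, side: set[str]) -> frozenset:
        ref = min(self.leaf_names.values())
        if ref in side:
            side = set(self.leaf_names.values()) - side
        return frozenset(side)

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions (internal edges only)."""
        out = set()
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if u < v and u not in self.leaf_names and v not in self.leaf_names:
                    side = self._side_leaves(u, v)
                    if 2 <= len(side) <= self.n_leaves - 2:
                        out.add(self._canonical(side))
        return out

    def leaf_distance_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Path-length distances between leaves (rows/cols in ``order``)."""
        order = order or sorted(self.leaf_names.values())
        node_of = {name: nid for nid, name in self.leaf_names.items()}
        n = len(order)
        out = np.zeros((n, n))
        for i, name in enumerate(order):
            dist = {node_of[name]: 0.0}
            stack = [node_of[name]]
            while stack:
                x = stack.pop()
                for y, w in self.adjacency[x].items():
                    if y not in dist:
                        dist[y] = dist[x] + w
                        stack.append(y)
            for j, other in enumerate(order):
                out[i, j] = dist[node_of[other]]
        return out

    # -- newick -------------------------------------------------------------

    def to_newick(self, support_format: str = "{:.0f}") -> str:
        """Newick string with branch lengths and integer support labels."""
        if not self.adjacency:
            return ";"
        internals = self.internal_nodes
        root = max(internals) if internals else next(iter(self.adjacency))

        def label(node: int) -> str:
            name = self.leaf_names.get(node)
            if name is None:
                return ""
            if _NEWICK_UNSAFE.search(name):
                return "'" + name.replace("'", "''") + "'"
            return name

        def render(node: int, parent: int | None) -> str:
            children = [v for v in sorted(self.adjacency[node]) if v != parent]
            if not children:
                return label(node)
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:.10g}" for c in children
            )
            lbl = label(node)
            if parent is not None and node not in self.leaf_names:
                side = self._canonical(self._side_leaves(parent, node))
                if side in self.supports:
                    lbl = support_format.format(self.supports[side])
            return f"({inner}){lbl}"

        return render(root, None) + ";"


def write_newick(tree: PhyloTree, path: str) -> str:
    """Write the tree as single-line newick; returns the string written."""
    text = tree.to_newick()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# NJ construction
# ---------------------------------------------------------------------------

def nj_build(distance_matrix: np.ndarray, names: list[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Requires a zero-diagonal symmetric matrix without NaN.  With fewer than
    3 taxa a trivial tree is returned with a warning.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = len(names)
    if d.shape != (n, n):
        raise ValidationError(f"matrix shape {d.shape} does not match {n} names")
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix is not symmetric")
    if len(set(names)) != n:
        raise ValidationError("duplicate taxon names")

    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_names = {i: names[i] for i in range(n)}
    clamped = 0.0

    def add_edge(u: int, v: int, w: float) -> None:
        nonlocal clamped
        if w < 0:
            clamped += -w
            w = 0.0
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    if n == 1:
        logger.warning("NJ on a single taxon: trivial tree")
        return PhyloTree(adjacency, leaf_names)
    if n == 2:
        logger.warning("NJ on two taxa: single-edge tree")
        add_edge(0, 1, float(d[0, 1]))
        return PhyloTree(adjacency, leaf_names)

    active = list(range(n))
    dd = d.copy()
    next_node = n
    while len(active) > 3:
        m = len(active)
        sub = dd[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin -> lexicographically smallest (i, j) tie-break
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        li = sub[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = sub[i, j] - li
        u = next_node
        next_node += 1
        add_edge(a, u, float(li))
        add_edge(b, u, float(lj))
        # distances from the new node to the remaining active nodes
        new_row = np.zeros(dd.shape[0] + 1)
        grown = np.zeros((dd.shape[0] + 1, dd.shape[0] + 1))
        grown[: dd.shape[0], : dd.shape[0]] = dd
        for k in active:
            if k in (a, b):
                continue
            new_row[k] = (dd[a, k] + dd[b, k] - dd[a, b]) / 2.0
        grown[u, : dd.shape[0]] = new_row[: dd.shape[0]]
        grown[: dd.shape[0], u] = new_row[: dd.shape[0]]
        dd = grown
        active = [k for k in active if k not in (a, b)] + [u]

    # final three-point join
    a, b, c = active
    hub = next_node
    la = (dd[a, b] + dd[a, c] - dd[b, c]) / 2.0
    lb = (dd[a, b] + dd[b, c] - dd[a, c]) / 2.0
    lc = (dd[a, c] + dd[b, c] - dd[a, b]) / 2.0
    add_edge(a, hub, float(la))
    add_edge(b, hub, float(lb))
    add_edge(c, hub, float(lc))
    if clamped > 0:
        logger.info("NJ clamped negative branch lengths (total deficit %.6g)", clamped)
    return PhyloTree(adjacency, leaf_names)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    matrix: GenotypeMatrix,
    n_reps: int = 500,
    seed: int = 0,
    metric: str = "normalized",
) -> tuple[PhyloTree, int]:
    """NJ tree from the full data with locus-resampling bootstrap supports.

    Each replicate resamples loci with replacement, recomputes pairwise
    distances and rebuilds the NJ tree; the support of an internal edge is
    the percentage of retained replicates containing the same leaf
    bipartition.  Replicates in which some pair has no comparable loci are
    discarded and counted (second return value).

    ``metric`` is ``normalized`` (per-allele difference proportion; robust
    to missing data across replicates) or ``raw`` (integer counts).
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if metric not in ("normalized", "raw"):
        raise ValidationError(f"unknown metric {metric!r}")

    def dist_from_calls(calls: np.ndarray) -> np.ndarray | None:
        diff, comp = _pairwise_from_calls(calls)
        if (comp == 0).any():
            return None
        vals = diff / (2.0 * comp) if metric == "normalized" else diff.astype(float)
        n = calls.shape[0]
        m = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        m[iu] = vals
        m[(iu[1], iu[0])] = vals
        return m

    base = dist_from_calls(matrix.calls)
    if base is None:
        raise ValidationError("some sample pair shares no comparable loci")
    tree = nj_build(base, list(matrix.sample_ids))

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    n_discarded = 0
    n_kept = 0
    n_loci = matrix.n_loci
    for _ in range(n_reps):
        idx = rng.integers(0, n_loci, size=n_loci)
        rep = dist_from_calls(matrix.calls[:, idx])
        if rep is None:
            n_discarded += 1
            continue
        n_kept += 1
        for bip in nj_build(rep, list(matrix.sample_ids)).bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    if n_kept == 0:
        raise ValidationError("all bootstrap replicates were discarded")
    tree.supports = {
        bip: 100.0 * counts.get(bip, 0) / n_kept for bip in tree.bipartitions()
    }
    return tree, n_discarded
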