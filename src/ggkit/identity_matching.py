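"""Pairwise multilocus matching, gap detection and redundancy grouping.

The per-locus distance between two diploid calls is the multiset allele
mismatch count, ``2 - |multiset intersection|``: AA vs AA -> 0, AA vs AB ->
1, AB vs AB -> 0, AA vs BB -> 2.  Pair totals sum over loci where both
calls are non-missing ("pairwise-complete"), so with complete data the
maximum distance over L loci is 2L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import MISSING, GenotypeMatrix, SampleMeta

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def _pairwise_from_calls(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Condensed (i<j, row-major) allele-difference and loci-compared counts.

    ``calls`` is an (N, L, 2) array of sorted allele-index pairs with
    missing = (-1, -1).  Works for any per-locus allele count: two sorted
    pairs share 2 alleles iff identical, else 1 iff any coordinate matches.
    """
    n = calls.shape[0]
    a0 = calls[..., 0]
    a1 = calls[..., 1]
    valid = a0 != MISSING
    diffs = []
    comps = []
    for i in range(n - 1):
        b0, b1 = a0[i + 1:], a1[i + 1:]
        both = valid[i] & valid[i + 1:]
        ident = (a0[i] == b0) & (a1[i] == b1)
        share = (a0[i] == b0) | (a0[i] == b1) | (a1[i] == b0) | (a1[i] == b1)
        per_locus = 2 - 2 * ident.astype(np.int64) - (share & ~ident)
        diffs.append(np.where(both, per_locus, 0).sum(axis=1))
        comps.append(both.sum(axis=1))
    if diffs:
        return np.concatenate(diffs), np.concatenate(comps)
    return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)


@dataclass
class PairDistanceSet:
    """Allele-difference counts for all unordered sample pairs.

    Condensed storage in row-major (i<j) order; ``n_allele_diff`` is only
    meaningful where ``n_loci_compared > 0`` (pairs with no comparable loci
    have an undefined distance and NaN ``normalized_diff``).
    """

    sample_ids: list[str]
    n_allele_diff: np.ndarray
    n_loci_compared: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        expect = n * (n - 1) // 2
        if len(self.n_allele_diff) != expect or len(self.n_loci_compared) != expect:
            raise ValidationError(
                f"pair arrays must have length N(N-1)/2 = {expect}"
            )
        if (self.n_allele_diff > 2 * self.n_loci_compared).any():
            raise ValidationError("n_allele_diff exceeds 2 * n_loci_compared")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.n_allele_diff)

    @property
    def defined(self) -> np.ndarray:
        return self.n_loci_compared > 0

    @property
    def normalized_diff(self) -> np.ndarray:
        out = np.full(self.n_pairs, np.nan)
        d = self.defined
        out[d] = self.n_allele_diff[d] / (2.0 * self.n_loci_compared[d])
        return out

    def pair_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col sample indices (i < j) aligned with the condensed arrays."""
        n = self.n_samples
        i_idx, j_idx = np.triu_indices(n, k=1)
        return i_idx, j_idx

    def square_matrix(self, kind: str = "raw") -> np.ndarray:
        """Full symmetric matrix; ``kind`` in {raw, normalized, squared}.

        Undefined pairs are NaN (raw/squared are float in that case).
        """
        if kind == "raw":
            vals = np.where(self.defined, self.n_allele_diff, np.nan)
        elif kind == "normalized":
            vals = self.normalized_diff
        elif kind == "squared":
            vals = np.where(self.defined, self.n_allele_diff.astype(float) ** 2, np.nan)
        else:
            raise ValueError(f"unknown matrix kind {kind!r}")
        n = self.n_samples
        m = np.zeros((n, n))
        i_idx, j_idx = self.pair_index()
        m[i_idx, j_idx] = vals
        m[j_idx, i_idx] = vals
        return m

    def get(self, a: str, b: str) -> int:
        """Raw allele-difference count for one named pair."""
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        if i == j:
            return 0
        i, j = min(i, j), max(i, j)
        n = self.n_samples
        flat = i * n - i * (i + 1) // 2 + (j - i - 1)
        return int(self.n_allele_diff[flat])

    def to_dataframe(self) -> pd.DataFrame:
        i_idx, j_idx = self.pair_index()
        ids = np.array(self.sample_ids)
        return pd.DataFrame(
            {
                "sample_a": ids[i_idx],
                "sample_b": ids[j_idx],
                "n_loci_compared": self.n_loci_compared,
                "n_allele_diff": self.n_allele_diff,
                "normalized_diff": self.normalized_diff,
                "defined": self.defined,
            }
        )


def pairwise_distances(matrix: GenotypeMatrix) -> PairDistanceSet:
    """Allele-difference distances for every unordered sample pair."""
    if matrix.n_samples < 2:
        raise ValidationError("pairwise matching needs at least 2 samples")
    diff, comp = _pairwise_from_calls(matrix.calls)
    n_undef = int((comp == 0).sum())
    if n_undef:
        logger.warning("%d pair(s) share no comparable loci; distance undefined", n_undef)
    return PairDistanceSet(list(matrix.sample_ids), diff, comp)


# ---------------------------------------------------------------------------
# gap detection
# ---------------------------------------------------------------------------

@dataclass
class GapResult:
    """Histogram of integer distances and the detected intra/inter gap.

    ``gap_interval`` is the longest run of unobserved consecutive integer
    distances (length >= ``min_gap_width``) between the smallest and largest
    observed values; ``intra_threshold`` is the largest observed distance
    below the gap.  Without a qualifying gap, ``is_bimodal`` is False and
    the threshold falls back to ``fallback_threshold``.
    """

    counts: np.ndarray
    intra_threshold: int
    gap_interval: tuple[int, int] | None
    is_bimodal: bool
    min_gap_width: int
    fallback_threshold: int

    def to_dataframe(self) -> pd.DataFrame:
        nz = np.nonzero(self.counts)[0]
        return pd.DataFrame({"n_allele_diff": nz, "n_pairs": self.counts[nz]})


def distance_histogram(
    pairs: PairDistanceSet,
    min_gap_width: int = 50,
    fallback_threshold: int = 10,
) -> GapResult:
    """Build the integer distance histogram and locate the separation gap."""
    d = pairs.n_allele_diff[pairs.defined]
    if d.size == 0:
        raise ValidationError("no defined pairwise distances")
    counts = np.bincount(d)
    observed = np.nonzero(counts)[0]
    best: tuple[int, int] | None = None
    for lo, hi in zip(observed[:-1], observed[1:]):
        width = hi - lo - 1  # empty integers strictly between
        if width >= min_gap_width and (best is None or width > best[1] - best[0] + 1):
            best = (int(lo) + 1, int(hi) - 1)
    if best is not None:
        return GapResult(counts, best[0] - 1, best, True, min_gap_width, fallback_threshold)
    return GapResult(counts, fallback_threshold, None, False, min_gap_width, fallback_threshold)


# ---------------------------------------------------------------------------
# redundancy grouping
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclass
class RedundancyGroup:
    group_id: str
    members: list[str]
    max_within_distance: int


@dataclass
class RedundancyReport:
    """Connected-component redundancy groups at a distance threshold.

    ``groups`` partition the samples having at least one within-threshold
    partner; ``unique_genotypes`` lists one representative per group (its
    first member in input order) plus every ungrouped sample.
    ``near_match_edges`` are within-threshold pairs at distance >= 1
    (putative somatic variants).
    """

    threshold: int
    groups: list[RedundancyGroup]
    unique_genotypes: list[str]
    near_match_edges: list[tuple[str, str, int]]
    n_undefined_pairs: int = 0

    @property
    def grouped_samples(self) -> list[str]:
        return [s for g in self.groups for s in g.members]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "group_id": g.group_id,
                "sample_id": s,
                "group_size": len(g.members),
                "max_within_distance": g.max_within_distance,
            }
            for g in self.groups
            for s in g.members
        ]
        return pd.DataFrame(rows, columns=["group_id", "sample_id", "group_size",
                                           "max_within_distance"])


def redundancy_groups(pairs: PairDistanceSet, threshold: int) -> RedundancyReport:
    """Group samples by connected components of the <=threshold match graph."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    n = pairs.n_samples
    uf = _UnionFind(n)
    i_idx, j_idx = pairs.pair_index()
    defined = pairs.defined
    n_undef = int((~defined).sum())
    if n_undef:
        logger.warning("%d undefined pair(s) treated as non-edges", n_undef)
    edge = defined & (pairs.n_allele_diff <= threshold)
    for a, b in zip(i_idx[edge], j_idx[edge]):
        uf.union(int(a), int(b))
    roots = np.array([uf.find(s) for s in range(n)])
    comp: dict[int, list[int]] = {}
    for s in range(n):
        comp.setdefault(int(roots[s]), []).append(s)
    # max defined within-component distance, vectorized over all pairs
    same = defined & (roots[i_idx] == roots[j_idx])
    max_within: dict[int, int] = {}
    for r, d in zip(roots[i_idx[same]], pairs.n_allele_diff[same]):
        r = int(r)
        if d > max_within.get(r, -1):
            max_within[r] = int(d)
    ids = pairs.sample_ids
    groups = []
    grouped = set()
    for root in sorted(comp):
        members = comp[root]
        if len(members) < 2:
            continue
        grouped.update(members)
        groups.append(
            RedundancyGroup(
                group_id=f"G{len(groups) + 1:03d}",
                members=[ids[m] for m in members],
                max_within_distance=max_within.get(root, 0),
            )
        )
    unique = [g.members[0] for g in groups] + [
        ids[s] for s in range(n) if s not in grouped
    ]
    near = [
        (ids[int(a)], ids[int(b)], int(d))
        for a, b, d in zip(i_idx[edge], j_idx[edge], pairs.n_allele_diff[edge])
        if d >= 1
    ]
    return RedundancyReport(threshold, groups, unique, near, n_undef)


# ---------------------------------------------------------------------------
# metadata annotation
# ---------------------------------------------------------------------------

def match_report(
    report: RedundancyReport, metas: Sequence[SampleMeta] | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label redundancy groups and flag homonymy candidates.

    Group labels: ``mutant-variant`` when the group contains near-match
    edges (distance >= 1); ``replicate-confirmation`` when all members share
    one accession name (replicates under different register numbers);
    ``synonymy-candidate`` when names differ; ``unannotated`` when metadata
    is missing.  Homonymy candidates: an accession name appearing in more
    than one component (group or singleton).
    """
    meta_by_id: dict[str, SampleMeta] = {m.sample_id: m for m in (metas or [])}
    near_pairs = {frozenset((a, b)) for a, b, _ in report.near_match_edges}
    rows = []
    comp_of_name: dict[str, set[str]] = {}

    def note_name(name: str | None, comp: str) -> None:
        if name:
            comp_of_name.setdefault(name, set()).add(comp)

    grouped = set(report.grouped_samples)
    for g in report.groups:
        names = []
        annotated = True
        for s in g.members:
            m = meta_by_id.get(s)
            if m is None or m.accession_name is None:
                annotated = False
            else:
                names.append(m.accession_name)
                note_name(m.accession_name, g.group_id)
        has_near = any(
            frozenset((a, b)) in near_pairs
            for i, a in enumerate(g.members)
            for b in g.members[i + 1:]
        )
        if not annotated:
            label = "unannotated"
        elif has_near:
            label = "mutant-variant"
        elif len(set(names)) == 1:
            label = "replicate-confirmation"
        else:
            label = "synonymy-candidate"
        rows.append(
            {
                "group_id": g.group_id,
                "label": label,
                "n_members": len(g.members),
                "members": ";".join(g.members),
                "accession_names": ";".join(sorted(set(names))),
                "max_within_distance": g.max_within_distance,
            }
        )
    for s, m in meta_by_id.items():
        if s not in grouped:
            note_name(m.accession_name, f"singleton:{s}")
    groups_df = pd.DataFrame(
        rows, columns=["group_id", "label", "n_members", "members",
                       "accession_names", "max_within_distance"]
    )
    hom_rows = [
        {"accession_name": name, "n_components": len(comps),
         "components": ";".join(sorted(comps))}
        for name, comps in sorted(comp_of_name.items())
        if len(comps) > 1
    ]
    homonymy_df = pd.DataFrame(
        hom_rows, columns=["accession_name", "n_components", "components"]
    )
    return groups_df, homonymy_df


def plot_histogram(gap: GapResult, path: str) -> None:
    """Write the distance histogram (with the detected gap shaded) to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    nz = np.nonzero(gap.counts)[0]
    ax.bar(nz, gap.counts[nz], width=1.0, color="steelblue")
    if gap.gap_interval:
        ax.axvspan(gap.gap_interval[0], gap.gap_interval[1], color="0.9")
    ax.set_xlabel("allele differences per pair")
    ax.set_ylabel("pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
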