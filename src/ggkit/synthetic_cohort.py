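"""Synthetic cohort generator with planted clonal/mutant/wild/progeny structure.

Generates genotype matrices whose statistical structure mirrors a germplasm
collection: clonal duplicate groups (0 allele differences), somatic-mutant
variants (a handful of single-allele flips), unrelated cultivars, a
differentiated wild pool (Balding-Nichols model) and Mendelian F1 progeny,
with optional missing-call injection.  Every sample carries truth labels so
downstream detection stages can be validated against the planted partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SpecError
from .genotype_io import MISSING, GenotypeMatrix, SampleMeta

# stable per-purpose stream offsets (python str hash is salted, so fixed ints)
_STREAMS = {"freq": 1, "cultivars": 2, "wild": 3, "progeny": 4, "missing": 5}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    """Independent deterministic stream per simulation purpose."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[purpose]]))


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``clone_group_sizes[i]`` is the total number of identical copies of
    founder ``i`` (a size of 1 means the founder alone); founders beyond the
    list get a single sample.  ``mutant_spec`` adds extra samples: each
    ``(parent, k)`` is a copy of founder ``parent`` with exactly ``k``
    single-allele flips at ``k`` distinct loci.
    """

    n_loci: int = 1043
    maf_range: tuple[float, float] = (0.06, 0.5)
    n_cultivars: int = 10
    clone_group_sizes: tuple[int, ...] = ()
    mutant_spec: tuple[tuple[int, int], ...] = ()
    n_wild: int = 0
    wild_fst: float = 0.39
    n_progeny: int = 0
    parent_pair: tuple[int, int] = (0, 1)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise SpecError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_loci < 1:
            raise SpecError("n_loci must be >= 1")
        if self.n_cultivars < 0 or self.n_wild < 0 or self.n_progeny < 0:
            raise SpecError("sample counts must be non-negative")
        if len(self.clone_group_sizes) > self.n_cultivars:
            raise SpecError("more clone groups than cultivars")
        if any(s < 1 for s in self.clone_group_sizes):
            raise SpecError("clone group sizes must be >= 1")
        for parent, k in self.mutant_spec:
            if not 0 <= parent < self.n_cultivars:
                raise SpecError(f"mutant parent index {parent} out of range")
            if not 1 <= k <= self.n_loci:
                raise SpecError(f"mutant flip count {k} out of range [1, n_loci]")
        if not 0 <= self.wild_fst < 1:
            raise SpecError(f"wild_fst must be in [0, 1), got {self.wild_fst}")
        if not 0 <= self.missing_rate < 1:
            raise SpecError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.n_progeny > 0:
            a, b = self.parent_pair
            if not (0 <= a < self.n_cultivars and 0 <= b < self.n_cultivars):
                raise SpecError("parent_pair indices out of range")

    @property
    def n_cultivated_samples(self) -> int:
        sizes = list(self.clone_group_sizes) + [1] * (
            self.n_cultivars - len(self.clone_group_sizes)
        )
        return sum(sizes) + len(self.mutant_spec)

    @property
    def n_samples(self) -> int:
        return self.n_cultivated_samples + self.n_wild + self.n_progeny


@dataclass
class CohortResult:
    """A generated cohort: genotypes, metadata, truth labels.

    ``truth`` has one row per sample: ``sample_id``, ``category``,
    ``founder`` (planted lineage id, NaN for wilds), ``n_flips``.
    ``truth_matrix`` is the cohort before missing-call injection.
    """

    matrix: GenotypeMatrix
    metas: list[SampleMeta]
    truth: pd.DataFrame
    truth_matrix: GenotypeMatrix
    founder_frequencies: np.ndarray


def draw_founder_frequencies(spec: CohortSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-locus frequency of allele index 1 in the founder (cultivated) pool.

    The minor allele frequency is uniform over ``spec.maf_range``; which
    allele is minor is chosen by a fair coin, so ``p`` is symmetric around
    0.5 while ``min(p, 1-p)`` stays inside the requested band.
    """
    rng = rng or _rng(spec.seed, "freq")
    low, high = spec.maf_range
    maf = rng.uniform(low, high, size=spec.n_loci)
    flip = rng.random(spec.n_loci) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def _hwe_dosages(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n individuals as Hardy-Weinberg dosages from frequencies p."""
    return rng.binomial(2, p, size=(n, p.shape[0])).astype(np.int8)


def simulate_cultivars(
    spec: CohortSpec, p: np.ndarray, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, list[SampleMeta], pd.DataFrame]:
    """Draw distinct founders, expand clone groups, append mutant variants.

    Clone-group members are exact copies of their founder; a mutant with
    flip count ``k`` differs from its parent by exactly ``k`` alleles (a
    hom->het or het->hom change at each of ``k`` distinct loci).
    """
    rng = rng or _rng(spec.seed, "cultivars")
    founders = _hwe_dosages(p, spec.n_cultivars, rng)
    sizes = list(spec.clone_group_sizes) + [1] * (
        spec.n_cultivars - len(spec.clone_group_sizes)
    )
    rows, ids, metas, truth = [], [], [], []
    reg = 1
    for f in range(spec.n_cultivars):
        name = f"CV{f:03d}"
        for r in range(sizes[f]):
            sid = name if sizes[f] == 1 else f"{name}_r{r}"
            rows.append(founders[f])
            ids.append(sid)
            metas.append(
                SampleMeta(sid, accession_name=name, register_number=f"R{reg:05d}",
                           category="cultivar", group_label="cultivated")
            )
            truth.append((sid, "cultivar", f, 0))
            reg += 1
    for m, (parent, k) in enumerate(spec.mutant_spec):
        d = founders[parent].copy()
        loci = rng.choice(spec.n_loci, size=k, replace=False)
        for l in loci:
            if d[l] == 1:
                d[l] = rng.choice([0, 2])
            else:
                d[l] = 1
        sid = f"CV{parent:03d}_mut{m}"
        rows.append(d)
        ids.append(sid)
        metas.append(
            SampleMeta(sid, accession_name=f"MUT{m:03d}", register_number=f"R{reg:05d}",
                       category="cultivar", group_label="cultivated")
        )
        truth.append((sid, "cultivar", parent, k))
        reg += 1
    matrix = GenotypeMatrix.from_dosage(ids, _locus_ids(spec.n_loci), np.array(rows))
    truth_df = pd.DataFrame(truth, columns=["sample_id", "category", "founder", "n_flips"])
    return matrix, metas, truth_df


def simulate_wild_pool(
    spec: CohortSpec, p: np.ndarray, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, list[SampleMeta], pd.DataFrame]:
    """Draw a wild pool differentiated from the founders by ``wild_fst``.

    Wild allele frequencies follow the Balding-Nichols distribution
    Beta(p(1-F)/F, (1-p)(1-F)/F); individuals are HWE draws from those
    frequencies.  At F=0 the wild frequencies equal the founder frequencies
    (the model's degenerate limit), so the two pools are exchangeable.
    """
    rng = rng or _rng(spec.seed, "wild")
    if spec.n_wild == 0:
        empty = GenotypeMatrix.from_dosage([], _locus_ids(spec.n_loci),
                                           np.empty((0, spec.n_loci), dtype=np.int8))
        return empty, [], pd.DataFrame(columns=["sample_id", "category", "founder", "n_flips"])
    f = spec.wild_fst
    if f == 0:
        pw = p
    else:
        scale = (1.0 - f) / f
        pw = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))
    dos = _hwe_dosages(pw, spec.n_wild, rng)
    ids = [f"WLD{i:03d}" for i in range(spec.n_wild)]
    metas = [
        SampleMeta(s, accession_name=s, register_number=f"W{i:05d}",
                   category="wild", group_label="wild")
        for i, s in enumerate(ids)
    ]
    truth = pd.DataFrame(
        {"sample_id": ids, "category": "wild", "founder": np.nan, "n_flips": 0}
    )
    return GenotypeMatrix.from_dosage(ids, _locus_ids(spec.n_loci), dos), metas, truth


def simulate_progeny(
    spec: CohortSpec,
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, list[SampleMeta], pd.DataFrame]:
    """Mendelian F1 progeny: one uniformly chosen allele from each parent
    per locus, independently across loci.  A missing parent call yields a
    missing progeny call at that locus."""
    rng = rng or _rng(spec.seed, "progeny")
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    n, l = spec.n_progeny, spec.n_loci
    ga = rng.random((n, l)) < parent_a / 2.0  # allele-1 gamete from parent a
    gb = rng.random((n, l)) < parent_b / 2.0
    dos = (ga.astype(np.int8) + gb.astype(np.int8))
    dos[:, (parent_a == MISSING) | (parent_b == MISSING)] = MISSING
    ids = [f"PRG{i:03d}" for i in range(n)]
    metas = [
        SampleMeta(s, accession_name=s, register_number=f"P{i:05d}",
                   category="progeny", group_label="cultivated")
        for i, s in enumerate(ids)
    ]
    truth = pd.DataFrame(
        {"sample_id": ids, "category": "progeny", "founder": np.nan, "n_flips": 0}
    )
    return GenotypeMatrix.from_dosage(ids, _locus_ids(l), dos), metas, truth


def inject_missing(
    matrix: GenotypeMatrix, rate: float, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Set each call MISSING independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise SpecError(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0:
        return matrix
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), "missing")
    mask = rng.random(matrix.shape) < rate
    calls = matrix.calls.copy()
    calls[mask] = MISSING
    return GenotypeMatrix(matrix.sample_ids, matrix.locus_ids, calls, matrix.alleles)


def build_cohort(spec: CohortSpec) -> CohortResult:
    """Generate the full cohort: cultivars (+clones/mutants), wilds, progeny,
    then inject missing calls.  Deterministic under ``spec.seed``."""
    p = draw_founder_frequencies(spec)
    cult, cult_meta, cult_truth = simulate_cultivars(spec, p)
    wild, wild_meta, wild_truth = simulate_wild_pool(spec, p)
    parts = [cult, wild]
    metas = cult_meta + wild_meta
    truths = [cult_truth, wild_truth]
    if spec.n_progeny > 0:
        a, b = spec.parent_pair
        dos = cult.dosage()
        # founders are the first sample of each clone group / singleton
        founder_rows = {}
        for sid, f in zip(cult_truth["sample_id"], cult_truth["founder"]):
            founder_rows.setdefault(int(f), cult.sample_ids.index(sid))
        prog, prog_meta, prog_truth = simulate_progeny(
            spec, dos[founder_rows[a]], dos[founder_rows[b]]
        )
        parts.append(prog)
        metas += prog_meta
        truths.append(prog_truth)
    calls = np.concatenate([m.calls for m in parts], axis=0)
    ids = [s for m in parts for s in m.sample_ids]
    full = GenotypeMatrix(ids, _locus_ids(spec.n_loci), calls, parts[0].alleles)
    truth = pd.concat(truths, ignore_index=True)
    observed = inject_missing(full, spec.missing_rate, spec.seed)
    return CohortResult(observed, metas, truth, full, p)


def _locus_ids(n_loci: int) -> list[str]:
    return [f"SNP{j:04d}" for j in range(n_loci)]
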