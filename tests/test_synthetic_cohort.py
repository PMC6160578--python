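import numpy as np
import pandas as pd
import pytest

from ggkit.errors import SpecError
from ggkit.genotype_io import MISSING
from ggkit.identity_matching import pairwise_distances
from ggkit.synthetic_cohort import (
    CohortSpec,
    build_cohort,
    draw_founder_frequencies,
    inject_missing,
    simulate_cultivars,
    simulate_progeny,
    simulate_wild_pool,
)


def hwe_pair_distance_moments(p: np.ndarray) -> tuple[float, float]:
    """Closed-form mean/variance of the allele-difference distance between
    two independent HWE individuals, by enumerating the 3x3 genotype-pair
    table per locus."""
    q = 1.0 - p
    g = np.stack([q**2, 2 * p * q, p**2])  # genotype probs by dosage, (3, L)
    d = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :])  # multiset mismatch
    e1 = np.einsum("al,ab,bl->l", g, d.astype(float), g)
    e2 = np.einsum("al,ab,bl->l", g, (d**2).astype(float), g)
    return float(e1.sum()), float((e2 - e1**2).sum())


class TestFounderFrequencies:
    def test_degenerate_range(self):
        spec = CohortSpec(n_loci=50, maf_range=(0.5, 0.5), seed=3)
        p = draw_founder_frequencies(spec)
        assert np.allclose(p, 0.5)

    def test_bounds_enforced(self):
        spec = CohortSpec(n_loci=2000, maf_range=(0.06, 0.5), seed=4)
        p = draw_founder_frequencies(spec)
        maf = np.minimum(p, 1 - p)
        assert maf.min() >= 0.06 and maf.max() <= 0.5

    def test_mean_maf_near_midpoint(self):
        # law of large numbers: uniform MAF over [0.06, 0.5] has mean 0.28
        spec = CohortSpec(n_loci=1043, maf_range=(0.06, 0.5), seed=5)
        maf = np.minimum(p := draw_founder_frequencies(spec), 1 - p)
        assert abs(maf.mean() - 0.28) < 0.03

    def test_invalid_range_rejected(self):
        with pytest.raises(SpecError):
            CohortSpec(maf_range=(0.0, 0.5))
        with pytest.raises(SpecError):
            CohortSpec(maf_range=(0.4, 0.2))


class TestCultivars:
    def test_clone_group_pairwise_zero(self):
        spec = CohortSpec(n_loci=400, n_cultivars=3, clone_group_sizes=(7,), seed=6)
        matrix, metas, truth = simulate_cultivars(spec, draw_founder_frequencies(spec))
        pairs = pairwise_distances(matrix)
        members = truth.loc[truth["founder"] == 0, "sample_id"]
        assert len(members) == 7
        for a in members:
            for b in members:
                if a != b:
                    assert pairs.get(a, b) == 0

    def test_mutant_distance_exact(self):
        spec = CohortSpec(n_loci=1043, n_cultivars=2, mutant_spec=((0, 10),), seed=7)
        matrix, _, truth = simulate_cultivars(spec, draw_founder_frequencies(spec))
        pairs = pairwise_distances(matrix)
        mutant = truth.loc[truth["n_flips"] == 10, "sample_id"].iloc[0]
        parent = truth.loc[(truth["founder"] == 0) & (truth["n_flips"] == 0),
                           "sample_id"].iloc[0]
        assert pairs.get(mutant, parent) == 10

    def test_unrelated_pair_distance_matches_enumeration(self):
        # 100 disjoint founder pairs vs the closed-form expectation
        spec = CohortSpec(n_loci=1043, n_cultivars=200, seed=8)
        p = draw_founder_frequencies(spec)
        matrix, _, _ = simulate_cultivars(spec, p)
        pairs = pairwise_distances(matrix)
        ids = matrix.sample_ids
        dists = [pairs.get(ids[2 * k], ids[2 * k + 1]) for k in range(100)]
        mean_expected, var_single = hwe_pair_distance_moments(p)
        se_mean = np.sqrt(var_single / 100)
        assert abs(np.mean(dists) - mean_expected) < 3 * se_mean

    def test_flip_count_out_of_range(self):
        with pytest.raises(SpecError):
            CohortSpec(n_loci=5, n_cultivars=1, mutant_spec=((0, 6),))


class TestWildPool:
    def test_fst_zero_uses_founder_frequencies(self):
        spec = CohortSpec(n_loci=500, n_cultivars=2, n_wild=40, wild_fst=0.0, seed=9)
        p = draw_founder_frequencies(spec)
        matrix, metas, _ = simulate_wild_pool(spec, p)
        assert matrix.n_samples == 40
        freqs = matrix.dosage().astype(float)
        freqs[freqs == MISSING] = np.nan
        observed = np.nanmean(freqs, axis=0) / 2
        # wild frequencies should track founder frequencies closely
        assert abs((observed - p).mean()) < 0.02

    def test_monomorphic_loci_appear_at_high_fst(self):
        spec = CohortSpec(n_loci=1043, n_cultivars=2, n_wild=89, wild_fst=0.3, seed=10)
        matrix, _, _ = simulate_wild_pool(spec, draw_founder_frequencies(spec))
        dosage = matrix.dosage()
        mono = ((dosage == 0).all(axis=0) | (dosage == 2).all(axis=0)).sum()
        assert mono > 0

    def test_empty_wild_pool(self):
        spec = CohortSpec(n_loci=20, n_cultivars=2, n_wild=0, seed=11)
        matrix, metas, truth = simulate_wild_pool(spec, draw_founder_frequencies(spec))
        assert matrix.n_samples == 0 and len(metas) == 0 and truth.empty

    def test_fst_bound(self):
        with pytest.raises(SpecError):
            CohortSpec(wild_fst=1.0)


class TestProgeny:
    def test_forced_segregation(self):
        spec = CohortSpec(n_loci=4, n_cultivars=2, n_progeny=3, seed=12)
        aa = np.zeros(4, dtype=np.int8)
        matrix, _, _ = simulate_progeny(spec, aa, aa)
        assert (matrix.dosage() == 0).all()

    def test_het_cross_ratio(self):
        spec = CohortSpec(n_loci=1, n_cultivars=2, n_progeny=10000, seed=13)
        het = np.ones(1, dtype=np.int8)
        matrix, _, _ = simulate_progeny(spec, het, het)
        dos = matrix.dosage()[:, 0]
        counts = np.bincount(dos, minlength=3)
        # 1:2:1 with binomial SE
        for k, frac in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            se = np.sqrt(frac * (1 - frac) / 10000)
            assert abs(counts[k] / 10000 - frac) < 3 * se

    def test_missing_parent_propagates(self):
        spec = CohortSpec(n_loci=3, n_cultivars=2, n_progeny=5, seed=14)
        a = np.array([0, MISSING, 2], dtype=np.int8)
        b = np.array([2, 1, MISSING], dtype=np.int8)
        matrix, _, _ = simulate_progeny(spec, a, b)
        dos = matrix.dosage()
        assert (dos[:, 1] == MISSING).all() and (dos[:, 2] == MISSING).all()
        assert (dos[:, 0] == 1).all()

    def test_progeny_far_from_unrelated_cultivars(self):
        spec = CohortSpec(n_loci=1043, n_cultivars=4, n_progeny=5,
                          parent_pair=(0, 1), seed=15)
        cohort = build_cohort(spec)
        pairs = pairwise_distances(cohort.matrix)
        prog = cohort.truth.loc[cohort.truth["category"] == "progeny", "sample_id"]
        unrelated = cohort.truth.loc[cohort.truth["founder"].isin([2, 3]), "sample_id"]
        for pr in prog:
            for cv in unrelated:
                assert pairs.get(pr, cv) >= 200


class TestMissingInjection:
    def test_rate_zero_identity(self, small_matrix):
        assert inject_missing(small_matrix, 0.0, 1) == small_matrix

    def test_rate_one_rejected(self, small_matrix):
        with pytest.raises(SpecError):
            inject_missing(small_matrix, 1.0, 1)

    def test_missing_count_binomial(self):
        spec = CohortSpec(n_loci=1043, n_cultivars=325, seed=16)
        matrix, _, _ = simulate_cultivars(spec, draw_founder_frequencies(spec))
        injected = inject_missing(matrix, 0.01, 17)
        total = 325 * 1043
        expected = 0.01 * total
        se = np.sqrt(total * 0.01 * 0.99)
        assert abs(injected.missing_mask().sum() - expected) < 3 * se


class TestCohortAssembly:
    def test_determinism(self):
        spec = CohortSpec(n_loci=120, n_cultivars=5, clone_group_sizes=(3,),
                          mutant_spec=((1, 2),), n_wild=6, n_progeny=4,
                          missing_rate=0.02, seed=18)
        c1, c2 = build_cohort(spec), build_cohort(spec)
        assert c1.matrix == c2.matrix
        assert c1.metas == c2.metas
        pd.testing.assert_frame_equal(c1.truth, c2.truth)

    def test_truth_label_completeness(self):
        spec = CohortSpec(n_loci=40, n_cultivars=3, clone_group_sizes=(2,),
                          n_wild=2, n_progeny=2, seed=19)
        cohort = build_cohort(spec)
        assert set(cohort.truth["sample_id"]) == set(cohort.matrix.sample_ids)
        assert set(cohort.truth["category"]) == {"cultivar", "wild", "progeny"}
        cult = cohort.truth[cohort.truth["category"] == "cultivar"]
        assert cult["founder"].notna().all()

    def test_sample_count_bookkeeping(self):
        spec = CohortSpec(n_loci=10, n_cultivars=6, clone_group_sizes=(4, 2),
                          mutant_spec=((0, 1), (5, 3)), n_wild=7, n_progeny=3,
                          seed=20)
        assert spec.n_samples == (4 + 2 + 4) + 2 + 7 + 3
        cohort = build_cohort(spec)
        assert cohort.matrix.n_samples == spec.n_samples
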