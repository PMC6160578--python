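import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_pair_distance
from ggkit.errors import ValidationError
from ggkit.genotype_io import GenotypeMatrix, SampleMeta
from ggkit.identity_matching import (
    PairDistanceSet,
    distance_histogram,
    match_report,
    pairwise_distances,
    redundancy_groups,
)


def random_matrix(rng, n, l, n_alleles=2, missing_rate=0.1):
    calls = np.sort(rng.integers(0, n_alleles, size=(n, l, 2)), axis=2).astype(np.int16)
    miss = rng.random((n, l)) < missing_rate
    calls[miss] = -1
    alleles = [tuple("ABCDEFGH"[:n_alleles])] * l
    return GenotypeMatrix([f"s{i}" for i in range(n)], [f"L{j}" for j in range(l)],
                          calls, alleles)


def pairs_from_distances(ids, dists):
    """Build a PairDistanceSet from a dict {(a, b): distance} assuming
    complete data over 1043 loci."""
    n = len(ids)
    flat = []
    for i in range(n):
        for j in range(i + 1, n):
            key = (ids[i], ids[j]) if (ids[i], ids[j]) in dists else (ids[j], ids[i])
            flat.append(dists[key])
    return PairDistanceSet(list(ids), np.array(flat), np.full(len(flat), 1043))


class TestPairwiseDistances:
    def test_identical_samples_zero(self, rng):
        matrix = random_matrix(rng, 1, 1043, missing_rate=0)
        twin = GenotypeMatrix(["a", "b"], matrix.locus_ids,
                              np.repeat(matrix.calls, 2, axis=0), matrix.alleles)
        pairs = pairwise_distances(twin)
        assert pairs.get("a", "b") == 0

    def test_opposite_homozygotes_full_panel(self):
        dosage = np.vstack([np.zeros(1043, dtype=np.int8), np.full(1043, 2, np.int8)])
        matrix = GenotypeMatrix.from_dosage(["a", "b"], [f"L{j}" for j in range(1043)],
                                            dosage)
        pairs = pairwise_distances(matrix)
        assert pairs.get("a", "b") == 2086

    @pytest.mark.parametrize(
        "call_a, call_b, expected",
        [((0, 0), (0, 0), 0), ((0, 0), (0, 1), 1), ((0, 1), (0, 1), 0),
         ((0, 0), (1, 1), 2), ((0, 1), (1, 1), 1)],
    )
    def test_single_locus_table(self, call_a, call_b, expected):
        calls = np.array([[call_a], [call_b]], dtype=np.int16)
        matrix = GenotypeMatrix(["a", "b"], ["L1"], calls, [("A", "B")])
        assert pairwise_distances(matrix).get("a", "b") == expected

    def test_matches_brute_force_biallelic(self, rng):
        matrix = random_matrix(rng, 8, 40)
        pairs = pairwise_distances(matrix)
        for i in range(8):
            for j in range(i + 1, 8):
                d, c = brute_pair_distance(matrix, i, j)
                assert pairs.get(f"s{i}", f"s{j}") == d
        i_idx, j_idx = pairs.pair_index()
        for k in range(pairs.n_pairs):
            d, c = brute_pair_distance(matrix, int(i_idx[k]), int(j_idx[k]))
            assert pairs.n_loci_compared[k] == c

    def test_matches_brute_force_multiallelic(self, rng):
        matrix = random_matrix(rng, 6, 30, n_alleles=4)
        pairs = pairwise_distances(matrix)
        for i in range(6):
            for j in range(i + 1, 6):
                d, _ = brute_pair_distance(matrix, i, j)
                assert pairs.get(f"s{i}", f"s{j}") == d

    def test_pair_count(self, rng):
        matrix = random_matrix(rng, 26, 5, missing_rate=0)
        assert pairwise_distances(matrix).n_pairs == 26 * 25 // 2

    def test_undefined_pair_flagged(self):
        calls = np.array([[[0, 0], [-1, -1]], [[-1, -1], [0, 1]]], dtype=np.int16)
        matrix = GenotypeMatrix(["a", "b"], ["L1", "L2"], calls, [("A", "B")] * 2)
        pairs = pairwise_distances(matrix)
        assert not pairs.defined[0]
        assert np.isnan(pairs.normalized_diff[0])

    def test_triangle_bound_complete_data(self, rng):
        matrix = random_matrix(rng, 6, 25, missing_rate=0)
        pairs = pairwise_distances(matrix)
        d = pairs.square_matrix("raw")
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    assert d[a, c] <= d[a, b] + d[b, c] + 1e-9

    def test_normalized_mean_stable_under_missing(self):
        from ggkit.synthetic_cohort import CohortSpec, build_cohort, inject_missing

        spec = CohortSpec(n_loci=1043, n_cultivars=30, seed=42)
        cohort = build_cohort(spec)
        full = pairwise_distances(cohort.truth_matrix)
        holey = pairwise_distances(inject_missing(cohort.truth_matrix, 0.05, 99))
        assert abs(np.nanmean(full.normalized_diff)
                   - np.nanmean(holey.normalized_diff)) < 0.005


class TestGapDetection:
    def test_reference_gap_structure(self):
        # left mode 0..10, right mode 200..680 -> gap [11, 199], threshold 10
        ids = [f"s{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        n = len(ids) * (len(ids) - 1) // 2
        left = rng.integers(0, 11, size=60)
        right = rng.integers(200, 681, size=n - 60)
        vals = np.concatenate([left, right, [0, 10, 200, 680]])[:n]
        vals[:4] = [0, 10, 200, 680]  # force the exact extremes
        pairs = PairDistanceSet(ids, vals, np.full(n, 1043))
        gap = distance_histogram(pairs)
        assert gap.is_bimodal
        assert gap.gap_interval == (11, 199)
        assert gap.intra_threshold == 10

    def test_all_zero_falls_back(self):
        ids = ["a", "b", "c"]
        pairs = PairDistanceSet(ids, np.zeros(3, dtype=int), np.full(3, 10))
        gap = distance_histogram(pairs)
        assert not gap.is_bimodal
        assert gap.intra_threshold == 10  # fallback default

    def test_three_point_example(self):
        # distances {0, 5, 300}: longest empty run is [6, 299] -> threshold 5
        ids = ["a", "b", "c"]
        pairs = PairDistanceSet(ids, np.array([0, 5, 300]), np.full(3, 1043))
        gap = distance_histogram(pairs, min_gap_width=50)
        assert gap.gap_interval == (6, 299)
        assert gap.intra_threshold == 5

    def test_narrow_gap_ignored(self):
        ids = ["a", "b", "c"]
        pairs = PairDistanceSet(ids, np.array([0, 20, 40]), np.full(3, 1043))
        gap = distance_histogram(pairs, min_gap_width=50, fallback_threshold=10)
        assert not gap.is_bimodal and gap.intra_threshold == 10

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 800), min_size=3, max_size=40))
    def test_no_observed_distance_inside_gap(self, values):
        k = len(values)
        # smallest n with n*(n-1)/2 >= k
        n = int(np.ceil((1 + np.sqrt(1 + 8 * k)) / 2))
        vals = np.array(values + [0] * (n * (n - 1) // 2 - k))
        pairs = PairDistanceSet([f"s{i}" for i in range(n)], vals,
                                np.full(len(vals), 1043))
        gap = distance_histogram(pairs)
        if gap.is_bimodal:
            lo, hi = gap.gap_interval
            assert hi - lo + 1 >= gap.min_gap_width
            assert not np.any((vals >= lo) & (vals <= hi))
            assert gap.intra_threshold == lo - 1


class TestRedundancyGroups:
    def test_seven_identical_samples(self):
        ids = [f"s{i}" for i in range(9)]
        dists = {}
        for i in range(9):
            for j in range(i + 1, 9):
                both_clone = i < 7 and j < 7
                dists[(ids[i], ids[j])] = 0 if both_clone else 400
        pairs = pairs_from_distances(ids, dists)
        report = redundancy_groups(pairs, 10)
        assert len(report.groups) == 1
        assert sorted(report.groups[0].members) == ids[:7]
        assert report.groups[0].max_within_distance == 0
        assert sorted(report.unique_genotypes) == ["s0", "s7", "s8"]

    def test_chained_near_matches_one_component(self):
        # A joins a clone group via distances 1 and 2; near pairs listed
        ids = ["f1", "f2", "m1", "m2", "other"]
        dists = {("f1", "f2"): 0, ("f1", "m1"): 1, ("f2", "m1"): 1,
                 ("f1", "m2"): 2, ("f2", "m2"): 2, ("m1", "m2"): 3,
                 ("f1", "other"): 500, ("f2", "other"): 500,
                 ("m1", "other"): 500, ("m2", "other"): 500}
        pairs = pairs_from_distances(ids, dists)
        report = redundancy_groups(pairs, 10)
        assert len(report.groups) == 1
        assert sorted(report.groups[0].members) == ["f1", "f2", "m1", "m2"]
        assert report.groups[0].max_within_distance == 3
        near = {(a, b): d for a, b, d in report.near_match_edges}
        assert near[("f1", "m1")] == 1 and near[("m1", "m2")] == 3

    def test_no_edges_all_unique(self):
        ids = ["a", "b", "c"]
        pairs = pairs_from_distances(
            ids, {("a", "b"): 300, ("a", "c"): 350, ("b", "c"): 320}
        )
        report = redundancy_groups(pairs, 10)
        assert report.groups == []
        assert report.unique_genotypes == ids

    def test_negative_threshold_rejected(self):
        ids = ["a", "b"]
        pairs = pairs_from_distances(ids, {("a", "b"): 5})
        with pytest.raises(ValidationError):
            redundancy_groups(pairs, -1)

    def test_groups_partition_grouped_samples(self, rng):
        matrix = random_matrix(rng, 12, 60, missing_rate=0)
        pairs = pairwise_distances(matrix)
        report = redundancy_groups(pairs, int(np.median(pairs.n_allele_diff)))
        grouped = report.grouped_samples
        assert len(grouped) == len(set(grouped))
        assert set(report.unique_genotypes) | set(grouped) == set(matrix.sample_ids)


class TestMatchReport:
    def _pairs(self):
        ids = ["r1", "r2", "syn1", "syn2", "mut1", "mut2", "h1", "h2"]
        dists = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                dists[(ids[i], ids[j])] = 500
        dists[("r1", "r2")] = 0
        dists[("syn1", "syn2")] = 0
        dists[("mut1", "mut2")] = 4
        return pairs_from_distances(ids, dists)

    def _metas(self):
        return [
            SampleMeta("r1", accession_name="Alpha", register_number="R1"),
            SampleMeta("r2", accession_name="Alpha", register_number="R2"),
            SampleMeta("syn1", accession_name="Beta", register_number="R3"),
            SampleMeta("syn2", accession_name="Gamma", register_number="R4"),
            SampleMeta("mut1", accession_name="Delta", register_number="R5"),
            SampleMeta("mut2", accession_name="DeltaRosso", register_number="R6"),
            SampleMeta("h1", accession_name="Manza", register_number="R7"),
            SampleMeta("h2", accession_name="Manza", register_number="R8"),
        ]

    def test_group_labels(self):
        report = redundancy_groups(self._pairs(), 10)
        groups_df, _ = match_report(report, self._metas())
        by_members = {row["members"]: row["label"] for _, row in groups_df.iterrows()}
        assert by_members["r1;r2"] == "replicate-confirmation"
        assert by_members["syn1;syn2"] == "synonymy-candidate"
        assert by_members["mut1;mut2"] == "mutant-variant"

    def test_homonymy_flagged(self):
        report = redundancy_groups(self._pairs(), 10)
        _, homonymy = match_report(report, self._metas())
        assert list(homonymy["accession_name"]) == ["Manza"]
        assert homonymy.iloc[0]["n_components"] == 2

    def test_missing_metadata_unannotated(self):
        report = redundancy_groups(self._pairs(), 10)
        groups_df, _ = match_report(report, None)
        assert set(groups_df["label"]) == {"unannotated"}
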