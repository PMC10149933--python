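import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casemerge.io import ClinicalCase
from casemerge.merge import (
    ClusterAssignments,
    MergeDecision,
    PairDistanceMatrix,
    bucket_distribution,
    build_merge_groups,
    direct_distance_baseline,
    hausdorff,
    merge_decision,
    metadata_as_subcategory,
    pairwise_cluster_distances,
)
from casemerge.vectorize import TermDocumentMatrix
import scipy.sparse as sp


def brute_force_hausdorff(A, B):
    """Independent double-loop oracle over all point pairs."""
    d_ab = max(min(np.linalg.norm(a - b) for b in B) for a in A)
    d_ba = max(min(np.linalg.norm(a - b) for a in A) for b in B)
    return max(d_ab, d_ba)


class TestHausdorff:
    def test_identical_sets(self):
        A = np.array([[0.0, 0.0], [1.0, 2.0]])
        assert hausdorff(A, A) == 0.0

    def test_singletons(self):
        assert hausdorff(np.array([[0.0]]), np.array([[3.0]])) == 3.0

    def test_asymmetric_spread(self):
        A = np.array([[0.0, 0.0], [0.0, 1.0]])
        B = np.array([[0.0, 0.0], [5.0, 0.0]])
        # directed distances are 1 (A->B) and 5 (B->A)
        assert hausdorff(A, B) == 5.0

    def test_empty_or_mismatched_inputs_rejected(self):
        A = np.array([[0.0, 0.0]])
        with pytest.raises(ValueError):
            hausdorff(A, np.empty((0, 2)))
        with pytest.raises(ValueError):
            hausdorff(A, np.array([[1.0, 2.0, 3.0]]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            d = int(rng.integers(1, 6))
            A = rng.normal(size=(int(rng.integers(1, 11)), d))
            B = rng.normal(size=(int(rng.integers(1, 11)), d))
            assert hausdorff(A, B) == pytest.approx(brute_force_hausdorff(A, B))

    def test_matches_scipy_directed_hausdorff(self):
        from scipy.spatial.distance import directed_hausdorff

        rng = np.random.default_rng(12)
        for _ in range(50):
            A = rng.normal(size=(6, 3))
            B = rng.normal(size=(8, 3))
            expected = max(directed_hausdorff(A, B)[0], directed_hausdorff(B, A)[0])
            assert hausdorff(A, B) == pytest.approx(expected)

    def test_metric_axioms(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            A = rng.normal(size=(4, 3))
            B = rng.normal(size=(5, 3))
            C = rng.normal(size=(3, 3))
            ab, ba = hausdorff(A, B), hausdorff(B, A)
            assert ab >= 0.0
            assert ab == pytest.approx(ba)
            assert hausdorff(A, B) <= hausdorff(A, C) + hausdorff(C, B) + 1e-9
            assert hausdorff(A, A) == 0.0


def _space_from(X):
    return TermDocumentMatrix(
        vocab=[f"t{j}" for j in range(X.shape[1])],
        row_ids=[f"r{i}" for i in range(X.shape[0])],
        weights=sp.csr_matrix(X),
    )


def _assignments(key, labels, offset=0):
    return ClusterAssignments(
        key=key, labels={f"r{i + offset}": lab for i, lab in enumerate(labels)}
    )


class TestPairwiseClusterDistances:
    def test_seven_by_twelve_yields_84(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 5))
        space = _space_from(X)
        la = [i % 7 + 1 for i in range(20)]
        lb = [i % 12 + 1 for i in range(20)]
        ca = _assignments("A", la)
        cb = _assignments("B", lb, offset=20)
        pdm = pairwise_cluster_distances(ca, cb, space)
        assert pdm.entries.shape == (7, 12)
        assert pdm.entries.size == 84

    def test_single_clusters_equal_full_set_distance(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(10, 3))
        space = _space_from(X)
        ca = _assignments("A", [1] * 5)
        cb = _assignments("B", [1] * 5, offset=5)
        pdm = pairwise_cluster_distances(ca, cb, space)
        assert pdm.entries.shape == (1, 1)
        assert pdm.entries[0, 0] == pytest.approx(hausdorff(X[:5], X[5:]))

    def test_swapping_sides_transposes(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(12, 4))
        space = _space_from(X)
        ca = _assignments("A", [1, 1, 2, 2, 3, 3])
        cb = _assignments("B", [1, 1, 1, 2, 2, 2], offset=6)
        ab = pairwise_cluster_distances(ca, cb, space).entries
        ba = pairwise_cluster_distances(cb, ca, space).entries
        np.testing.assert_allclose(ab, ba.T)


class TestBucketDistribution:
    def test_all_zero(self):
        pdm = PairDistanceMatrix(("a", "b"), np.zeros((2, 2)))
        assert bucket_distribution(pdm) == (1.0, 0.0, 0.0, 0.0, 0.0)

    def test_one_entry_per_bucket(self):
        pdm = PairDistanceMatrix(("a", "b"), np.array([[5.0, 15.0, 25.0, 35.0, 45.0]]))
        assert bucket_distribution(pdm) == (0.2, 0.2, 0.2, 0.2, 0.2)

    def test_boundary_value_in_lower_bucket(self):
        pdm = PairDistanceMatrix(("a", "b"), np.array([[10.0]]))
        assert bucket_distribution(pdm)[0] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(31)
        pdm = PairDistanceMatrix(("a", "b"), rng.uniform(0, 60, size=(6, 7)))
        assert sum(bucket_distribution(pdm)) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bucket_distribution(np.empty((0,)))


class TestMergeDecision:
    def test_ninety_percent_in_range_merges(self):
        entries = np.array([5.0] * 9 + [25.0]).reshape(2, 5)
        d = merge_decision(PairDistanceMatrix(("a", "b"), entries))
        assert d.in_range_fraction == pytest.approx(0.9)
        assert d.merged

    def test_seventy_percent_does_not_merge(self):
        entries = np.array([5.0] * 7 + [25.0] * 3).reshape(2, 5)
        assert not merge_decision(PairDistanceMatrix(("a", "b"), entries)).merged

    def test_exactly_eighty_percent_merges(self):
        entries = np.array([5.0] * 8 + [25.0] * 2).reshape(2, 5)
        d = merge_decision(PairDistanceMatrix(("a", "b"), entries))
        assert d.in_range_fraction == pytest.approx(0.8)
        assert d.merged  # threshold is inclusive ("minimum 80%")

    def test_all_zero_merges(self):
        assert merge_decision(PairDistanceMatrix(("a", "b"), np.zeros((3, 3)))).merged

    @given(st.lists(st.floats(0, 50), min_size=1, max_size=30),
           st.lists(st.floats(0, 10), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_in_in_range_entries(self, base, extra_in_range):
        d1 = merge_decision(PairDistanceMatrix(("a", "b"), np.array([base])))
        d2 = merge_decision(
            PairDistanceMatrix(("a", "b"), np.array([base + extra_in_range]))
        )
        if d1.merged:
            assert d2.merged


class TestBuildMergeGroups:
    @staticmethod
    def decision(a, b, merged):
        frac = 1.0 if merged else 0.0
        return MergeDecision((a, b), frac, merged, (frac, 0, 0, 0, 1 - frac))

    def test_transitive_closure(self):
        groups, unmerged = build_merge_groups(
            [self.decision("A", "B", True), self.decision("B", "C", True),
             self.decision("C", "D", False)]
        )
        assert [sorted(g.members) for g in groups] == [["A", "B", "C"]]
        assert unmerged == ["D"]

    def test_no_merges(self):
        groups, unmerged = build_merge_groups(
            [self.decision("A", "B", False)], all_keys=["A", "B", "C"]
        )
        assert groups == []
        assert unmerged == ["A", "B", "C"]

    def test_output_is_partition(self):
        decisions = [
            self.decision("A", "B", True), self.decision("C", "D", True),
            self.decision("A", "C", False), self.decision("E", "A", False),
        ]
        groups, unmerged = build_merge_groups(decisions)
        seen = [k for g in groups for k in g.members] + unmerged
        assert sorted(seen) == ["A", "B", "C", "D", "E"]
        assert len(seen) == len(set(seen))


class TestDirectBaseline:
    def test_identical_subcategories_zero(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(4, 3))
        space = _space_from(np.vstack([X, X]))
        a = [f"r{i}" for i in range(4)]
        b = [f"r{i + 4}" for i in range(4)]
        assert direct_distance_baseline(a, b, space) == pytest.approx(0.0)

    def test_equals_k1_cluster_distance(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(8, 3))
        space = _space_from(X)
        a = [f"r{i}" for i in range(4)]
        b = [f"r{i + 4}" for i in range(4)]
        ca = _assignments("A", [1] * 4)
        cb = _assignments("B", [1] * 4, offset=4)
        pdm = pairwise_cluster_distances(ca, cb, space)
        assert direct_distance_baseline(a, b, space) == pytest.approx(pdm.entries[0, 0])


class TestMetadataAsSubcategory:
    def test_single_label_becomes_document(self):
        sub = metadata_as_subcategory(
            [ClinicalCase("x1", "nihxray", {"finding_label": "effusion"})]
        )
        assert sub.documents == (("x1", "effusion"),)
        assert sub.source_id == "nihxray"

    def test_empty_metadata_excluded(self):
        sub = metadata_as_subcategory(
            [ClinicalCase("x1", "s", {}), ClinicalCase("x2", "s", {"a": "  "})]
        )
        assert sub is None

    def test_mixed_keys_joined_in_field_order(self):
        case = ClinicalCase("x1", "s", {"finding": "mass", "view": "pa"})
        sub = metadata_as_subcategory([case])
        assert sub.documents[0][1] == "mass pa"
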