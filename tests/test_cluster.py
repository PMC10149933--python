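import itertools
import warnings

import numpy as np
import pytest
import scipy.sparse as sp

from casemerge.cluster import (
    ClusterSelectConfig,
    cart_scree,
    hac_cluster,
    min_sqrt_kmax,
    resolve_k,
    select_k,
    select_k_cart,
    sqrt_threshold,
    two_stage_cluster,
    ward_linkage,
    ward_plateau,
)
from casemerge.vectorize import TermDocumentMatrix, build_tfidf

from conftest import make_block_docs


def matrix_from_points(X: np.ndarray) -> TermDocumentMatrix:
    X = np.asarray(X, dtype=float)
    return TermDocumentMatrix(
        vocab=[f"t{j}" for j in range(X.shape[1])],
        row_ids=[f"d{i}" for i in range(X.shape[0])],
        weights=sp.csr_matrix(X),
    )


def two_blobs(rng, n_per=4, sep=10.0):
    a = rng.normal(0.0, 0.3, size=(n_per, 2))
    b = rng.normal(sep, 0.3, size=(n_per, 2))
    return matrix_from_points(np.vstack([a, b]))


def within_cluster_ss(X, labels):
    total = 0.0
    for c in set(labels):
        pts = X[np.array(labels) == c]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


class TestHacCluster:
    def test_k_equals_n_gives_singletons(self):
        m = matrix_from_points(np.arange(10.0).reshape(5, 2))
        cs = hac_cluster(m, 5)
        assert sorted(cs.assignments.values()) == [1, 2, 3, 4, 5]

    def test_k_one_gives_single_cluster(self):
        m = matrix_from_points(np.arange(10.0).reshape(5, 2))
        cs = hac_cluster(m, 1)
        assert set(cs.assignments.values()) == {1}

    def test_recovers_blobs_and_minimizes_ward_objective(self):
        # compare against the exhaustive 2-partition minimizing within-SS
        rng = np.random.default_rng(0)
        m = two_blobs(rng, n_per=4)
        X = m.dense()
        cs = hac_cluster(m, 2)
        labels = [cs.assignments[r] for r in m.row_ids]
        best = min(
            within_cluster_ss(X, [1 if i in subset else 2 for i in range(8)])
            for r in range(1, 4 + 1)
            for subset in map(frozenset, itertools.combinations(range(8), r))
        )
        assert within_cluster_ss(X, labels) == pytest.approx(best)
        assert len({labels[i] for i in range(4)}) == 1
        assert labels[0] != labels[4]

    def test_k_out_of_range_rejected(self):
        m = matrix_from_points(np.arange(10.0).reshape(5, 2))
        for k in (0, 6):
            with pytest.raises(ValueError):
                hac_cluster(m, k)

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 8])
    def test_partition_property(self, k):
        rng = np.random.default_rng(1)
        m = matrix_from_points(rng.normal(size=(8, 3)))
        cs = hac_cluster(m, k)
        assert cs.k == k
        assert set(cs.assignments) == set(m.row_ids)
        members = cs.members()
        assert len(members) == k
        assert all(members.values())  # every cluster non-empty

    def test_nested_consistency(self):
        # cutting at k and k+1 differ by exactly one cluster split
        rng = np.random.default_rng(2)
        m = matrix_from_points(rng.normal(size=(10, 4)))
        Z = ward_linkage(m)
        for k in range(1, 9):
            a = hac_cluster(m, k, Z=Z).assignments
            b = hac_cluster(m, k + 1, Z=Z).assignments
            # map each finer cluster to the coarser cluster containing it
            parents = {}
            for doc, fine in b.items():
                parents.setdefault(fine, set()).add(a[doc])
            assert all(len(p) == 1 for p in parents.values())  # nesting
            split = [c for c in set(a.values())
                     if len({f for f, p in parents.items() if p == {c}}) == 2]
            assert len(split) == 1


class TestCartScree:
    def test_separated_blobs_highly_classifiable(self):
        rng = np.random.default_rng(3)
        m = two_blobs(rng, n_per=10)
        scree = cart_scree(m, (2, 4), ClusterSelectConfig(seed=0))
        assert scree[2] >= 0.95

    def test_covers_range_without_gaps(self):
        rng = np.random.default_rng(4)
        m = matrix_from_points(rng.normal(size=(12, 3)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scree = cart_scree(m, (2, 6), ClusterSelectConfig(seed=0))
        assert sorted(scree) == [2, 3, 4, 5, 6]
        assert all(0.0 <= v <= 1.0 for v in scree.values())

    def test_singleton_cluster_still_defined(self):
        # an outlier forces a singleton class; accuracy must still be reported
        X = np.vstack([np.zeros((5, 2)) + [[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1], [0.05, 0]],
                       [[50.0, 50.0]]])
        m = matrix_from_points(X)
        with pytest.warns(UserWarning):
            scree = cart_scree(m, (2, 2), ClusterSelectConfig(seed=0))
        assert 0.0 <= scree[2] <= 1.0


class TestSelectKCart:
    def test_cliff_rule(self):
        assert select_k_cart({2: 0.95, 3: 0.80, 4: 0.7}, drop=0.02) == 2

    def test_no_cliff_falls_back_to_argmax(self):
        assert select_k_cart({2: 0.97, 3: 0.96, 4: 0.91}, drop=0.10) == 2

    def test_engineered_cliff_mid_range(self):
        scree = {k: 0.97 - 0.001 * k for k in range(2, 7)}
        scree[7] = 0.7  # cliff when moving from 6 to 7
        assert select_k_cart(scree) == 6

    def test_empty_scree_rejected(self):
        with pytest.raises(ValueError):
            select_k_cart({})


class TestSqrtThreshold:
    @pytest.mark.parametrize("u, expected", [(1404, 37), (100, 10), (1, 1)])
    def test_values(self, u, expected):
        assert sqrt_threshold(u) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            sqrt_threshold(0)


def oracle_min_sqrt(m, k_range, threshold_offset=0):
    """Independent recount: per cut, rebuild per-cluster term sets from the
    token-presence matrix and apply the floor(sqrt(U)) rule."""
    X = m.dense() > 0
    U = int(X.any(axis=0).sum())
    T = int(np.floor(np.sqrt(U))) + threshold_offset
    Z = ward_linkage(m)
    from scipy.cluster.hierarchy import cut_tree

    lo, hi = k_range
    for k in range(hi, lo - 1, -1):
        labels = cut_tree(Z, n_clusters=k).flatten() if k > 1 else np.zeros(len(X), int)
        counts = [int(X[labels == c].any(axis=0).sum()) for c in np.unique(labels)]
        if min(counts) >= T:
            return k
    return lo


class TestMinSqrtKmax:
    def test_identical_documents_keep_full_vocab(self):
        from casemerge.text import TokenizedDoc

        docs = [TokenizedDoc(f"d{i}", ("a", "b", "c", "d")) for i in range(6)]
        m = build_tfidf(docs)
        assert min_sqrt_kmax(m, (2, 5)) == 5

    def test_agrees_with_recount_oracle(self, block_docs):
        docs, _ = block_docs
        m = build_tfidf(docs)
        assert min_sqrt_kmax(m, (2, 12)) == oracle_min_sqrt(m, (2, 12))

    def test_monotone_in_threshold(self, block_docs):
        # raising the required per-cluster term count never raises k
        docs, _ = block_docs
        m = build_tfidf(docs)
        ks = [oracle_min_sqrt(m, (2, 12), off) for off in (0, 3, 6)]
        assert ks == sorted(ks, reverse=True)

    def test_degenerate_range(self, block_docs):
        docs, _ = block_docs
        m = build_tfidf(docs)
        assert min_sqrt_kmax(m, (2, 2)) == 2


class TestWardPlateau:
    def test_duplicated_points_plateau_reaches_large_k(self):
        X = np.repeat(np.array([[0.0, 0.0], [10.0, 0.0]]), 5, axis=0)
        m = matrix_from_points(X)
        lo, hi = ward_plateau(m, (2, 8))
        assert hi >= 6  # zero-height merges make high cuts interchangeable

    def test_equally_spaced_collinear_points_narrow_plateau(self):
        m = matrix_from_points(np.array([[float(i), 0.0] for i in range(5)]))
        lo, hi = ward_plateau(m, (2, 4))
        assert hi - lo <= 1  # heights grow steadily; no wide flat stretch

    def test_fewer_than_three_rows_degenerate(self):
        m = matrix_from_points(np.array([[0.0], [1.0]]))
        assert ward_plateau(m, (2, 5)) == (1, 1)


class TestResolveK:
    def test_agreement_uses_sqrt_k(self):
        assert resolve_k(k_cart=3, k_sqrt=12, plateau=(6, 15)) == (12, True)

    def test_disagreement_takes_maximum(self):
        assert resolve_k(k_cart=8, k_sqrt=3, plateau=(4, 5)) == (8, False)

    def test_plateau_upper_end_can_win(self):
        assert resolve_k(k_cart=3, k_sqrt=2, plateau=(4, 9)) == (9, False)


class TestSelectK:
    def test_degenerate_input_yields_one_cluster(self):
        m = matrix_from_points(np.array([[0.0, 1.0], [2.0, 3.0]]))
        rep = select_k(m)
        assert rep.k_final == 1

    def test_recovers_group_count_on_structured_corpora(self):
        # t well-separated vocabulary groups -> k within +-1 of t
        t, hits = 6, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            docs, _ = make_block_docs(rng, t=t)
            m = build_tfidf(docs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = select_k(m, ClusterSelectConfig(k_range=(2, 12), seed=seed))
            hits += abs(rep.k_final - t) <= 1
        assert hits >= 18

    def test_report_invariants(self, block_docs):
        docs, _ = block_docs
        m = build_tfidf(docs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = select_k(m, ClusterSelectConfig(k_range=(2, 10), seed=0))
        assert rep.k_final >= 1
        assert sorted(rep.scree) == list(range(2, 11))
        if rep.agreed:
            assert rep.plateau[0] <= rep.k_sqrt <= rep.plateau[1]
            assert rep.k_final == rep.k_sqrt


def test_two_stage_clustering_partitions_documents():
    rng = np.random.default_rng(5)
    m = matrix_from_points(np.vstack([rng.normal(0, 0.5, (15, 2)),
                                      rng.normal(20, 0.5, (15, 2))]))
    cs = two_stage_cluster(m, n_initial=10, k=2)
    labels = [cs.assignments[r] for r in m.row_ids]
    assert set(labels) == {1, 2}
    assert len({labels[i] for i in range(15)}) == 1  # first blob intact
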