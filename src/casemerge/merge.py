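"""Hausdorff-distance comparison of cluster sets and the merge decision.

Two sub-categories are compared cluster-against-cluster (many-to-many) in a
shared TF-IDF space.  For each pair of clusters the Hausdorff distance

    d_H(A, B) = max( max_{a in A} min_{b in B} d(a, b),
                     max_{b in B} min_{a in A} d(a, b) )

is taken under the Euclidean point metric.  The resulting k_A x k_B distances
are bucketed into the ranges (0-10], (10-20], (20-30], (30-40], 40+; a pair of
sub-categories is merged when at least 80% of its cluster-pair distances fall
in the first bucket.  Merged pairs are closed transitively into merge groups
(connected components), each of which becomes one attribute of the
integrated schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .io import ClinicalCase, SubCategory
from .vectorize import TermDocumentMatrix

DEFAULT_BUCKET_EDGES = (10.0, 20.0, 30.0, 40.0)
DEFAULT_MERGE_THRESHOLD = 0.80


def hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Hausdorff distance between two non-empty point sets (Euclidean).

    Symmetric set distance: the largest distance from any point of one set to
    its nearest point in the other.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("hausdorff is undefined for empty point sets")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    D = cdist(A, B)
    return float(max(D.min(axis=1).max(), D.min(axis=0).max()))


@dataclass
class PairDistanceMatrix:
    """All cluster-pair Hausdorff distances between two sub-categories."""

    pair: tuple[str, str]
    entries: np.ndarray  # shape (k_A, k_B)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2:
            raise ValueError("entries must be a k_A x k_B matrix")
        if (self.entries < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class MergeDecision:
    pair: tuple[str, str]
    in_range_fraction: float
    merged: bool
    buckets: tuple[float, float, float, float, float]


@dataclass
class MergeGroup:
    """Sub-categories judged semantically similar; named by the schema step."""

    members: frozenset[str]
    attribute_name: str = ""


def pairwise_cluster_distances(
    ca: "ClusterAssignments",
    cb: "ClusterAssignments",
    space: TermDocumentMatrix,
) -> PairDistanceMatrix:
    """Many-to-many cluster distances between two sub-categories.

    ``ca`` / ``cb`` map cluster labels to row ids of ``space`` (the pooled
    TF-IDF matrix).  Entry (i, j) is the Hausdorff distance between cluster
    i of A and cluster j of B; a 7-cluster vs 12-cluster pair yields 84
    distances.
    """
    members_a = ca.members()
    members_b = cb.members()
    vec_a = {c: space.rows(ids) for c, ids in members_a.items()}
    vec_b = {c: space.rows(ids) for c, ids in members_b.items()}
    entries = np.zeros((len(vec_a), len(vec_b)))
    for i, c_a in enumerate(sorted(vec_a)):
        for j, c_b in enumerate(sorted(vec_b)):
            entries[i, j] = hausdorff(vec_a[c_a], vec_b[c_b])
    return PairDistanceMatrix(pair=(ca.key, cb.key), entries=entries)


def bucket_distribution(
    d: PairDistanceMatrix | np.ndarray,
    edges: Sequence[float] = DEFAULT_BUCKET_EDGES,
) -> tuple[float, ...]:
    """Fractions of distances in (-inf, e1], (e1, e2], ..., (e_last, inf).

    Boundary values belong to the lower bucket (a distance of exactly 10 is
    in range 0-10).  Fractions sum to 1.
    """
    values = d.entries if isinstance(d, PairDistanceMatrix) else np.asarray(d, dtype=float)
    values = values.ravel()
    if values.size == 0:
        raise ValueError("cannot bucket an empty distance matrix")
    bins = [-np.inf, *edges, np.inf]
    # right-closed bins: a value exactly on an edge falls in the lower bucket
    counts = np.array(
        [np.count_nonzero((values > lo) & (values <= hi)) for lo, hi in zip(bins[:-1], bins[1:])]
    )
    return tuple((counts / values.size).tolist())


def merge_decision(
    d: PairDistanceMatrix,
    threshold: float = DEFAULT_MERGE_THRESHOLD,
    edges: Sequence[float] = DEFAULT_BUCKET_EDGES,
) -> MergeDecision:
    """Merge iff at least ``threshold`` of the cluster-pair distances lie in
    the first bucket (0 to ``edges[0]``, inclusive)."""
    buckets = bucket_distribution(d, edges)
    in_range = buckets[0]
    return MergeDecision(
        pair=d.pair,
        in_range_fraction=in_range,
        merged=in_range >= threshold,
        buckets=tuple(buckets),
    )


def build_merge_groups(
    decisions: Iterable[MergeDecision],
    all_keys: Iterable[str] | None = None,
) -> tuple[list[MergeGroup], list[str]]:
    """Transitive closure of merged pairs.

    Returns (groups, unmerged): connected components of the merged-pair graph,
    plus every evaluated (or listed) sub-category with no merged edge.
    """
    decisions = list(decisions)
    keys: list[str] = []
    seen: set[str] = set()

    def _note(k: str) -> None:
        if k not in seen:
            seen.add(k)
            keys.append(k)

    graph = nx.Graph()
    for d in decisions:
        _note(d.pair[0])
        _note(d.pair[1])
        if d.merged:
            graph.add_edge(*d.pair)
    if all_keys is not None:
        for k in all_keys:
            _note(k)
    groups = [
        MergeGroup(members=frozenset(comp))
        for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    ]
    grouped = set().union(*(g.members for g in groups)) if groups else set()
    unmerged = [k for k in keys if k not in grouped]
    return groups, unmerged


def direct_distance_baseline(
    a_row_ids: Sequence[str], b_row_ids: Sequence[str], space: TermDocumentMatrix
) -> float:
    """Hausdorff distance between the *unclustered* full document sets.

    The baseline the clustering route is compared against: a single set
    distance per sub-category pair, dominated by each side's most atypical
    document.
    """
    return hausdorff(space.rows(a_row_ids), space.rows(b_row_ids))


def metadata_as_subcategory(
    cases: Iterable[ClinicalCase], caption: str = "metadata"
) -> SubCategory | None:
    """Render structured metadata fields as one pseudo-text sub-category.

    Image-only records often carry labels instead of narrative (e.g. an x-ray
    record with a finding label).  Each case's field values are space-joined
    in field order into one document; cases with no non-empty values are
    excluded.  Returns None if nothing survives.
    """
    docs: list[tuple[str, str]] = []
    source_id = None
    for case in cases:
        if source_id is None:
            source_id = case.source_id
        text = " ".join(v for v in case.fields.values() if v.strip())
        if text.strip():
            docs.append((case.case_id, text))
    if not docs or source_id is None:
        return None
    return SubCategory(source_id=source_id, caption=caption, documents=tuple(docs))


@dataclass
class ClusterAssignments:
    """Cluster labels mapped to row ids of a pooled space.

    Thin adapter between :class:`~casemerge.cluster.ClusterSet` (labels over a
    sub-category's own rows) and the shared pooled matrix whose row ids carry
    a side prefix.
    """

    key: str
    labels: dict[str, int]  # pooled row id -> cluster label

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for row_id, label in self.labels.items():
            out.setdefault(label, []).append(row_id)
        return out

    @classmethod
    def from_cluster_set(cls, cs, prefix: str) -> "ClusterAssignments":
        return cls(
            key=cs.key,
            labels={f"{prefix}::{doc_id}": lab for doc_id, lab in cs.assignments.items()},
        )
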