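"""Ward-linkage document clustering and cluster-number selection.

Each sub-category's TF-IDF rows are clustered by hierarchical agglomerative
clustering (Euclidean metric, Ward linkage).  The number of clusters k is
chosen by combining three diagnostics:

1. **CART scree** — for each candidate k, a decision tree (entropy splitting)
   is trained to predict the cluster labels from the TF-IDF features; the
   cross-validated accuracy is an auditor of cluster separability.  The
   selected k is the smallest well-classified k just before a significant
   accuracy drop.
2. **Minimum square-root criterion** — every cluster must retain at least
   floor(sqrt(U)) unique terms, where U is the sub-category's unique-term
   count; the largest k satisfying this is kept.
3. **Ward-distance plateau** — the widest contiguous range of k where
   successive dendrogram merge heights are nearly equal (many similar-scale
   merges indicate interchangeable cuts).

If the square-root k falls inside the plateau the two diagnostics agree and
that k is final; otherwise the maximum of the candidates is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .vectorize import TermDocumentMatrix


@dataclass
class ClusterSet:
    """A partition of one sub-category's documents into k clusters."""

    key: str
    k: int
    assignments: dict[str, int]  # document id -> cluster label in 1..k

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if labels != set(range(1, self.k + 1)):
            raise ValueError(f"labels {sorted(labels)} do not cover 1..{self.k}")

    def members(self) -> dict[int, list[str]]:
        """Per-cluster document-id lists, in assignment order."""
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for doc_id, label in self.assignments.items():
            out[label].append(doc_id)
        return out


@dataclass
class KSelectionReport:
    """Record of the three cluster-number diagnostics and the decision."""

    key: str
    scree: dict[int, float]
    k_cart: int
    k_sqrt: int
    plateau: tuple[int, int]
    k_final: int
    agreed: bool

    def to_dict(self) -> dict:
        return {
            "key": self.key,
            "scree": {str(k): v for k, v in self.scree.items()},
            "k_cart": self.k_cart,
            "k_sqrt": self.k_sqrt,
            "plateau": list(self.plateau),
            "k_final": self.k_final,
            "agreed": self.agreed,
        }


@dataclass(frozen=True)
class ClusterSelectConfig:
    k_range: tuple[int, int] | None = None  # default (2, min(15, n-1))
    cart_threshold: float = 0.90
    cart_drop: float = 0.02
    plateau_eps: float = 0.05
    cv_folds: int = 5
    min_samples_leaf: int = 2
    seed: int = 0
    two_stage: bool = False
    n_initial: int = 45


def ward_linkage(m: TermDocumentMatrix) -> np.ndarray:
    """Ward/Euclidean linkage matrix for the matrix rows (deterministic)."""
    return linkage(m.dense(), method="ward", metric="euclidean")


def _cut_labels(Z: np.ndarray, n_rows: int, k: int) -> np.ndarray:
    if k == n_rows:
        return np.arange(1, n_rows + 1)
    flat = cut_tree(Z, n_clusters=k).flatten()
    # relabel to 1..k in order of first appearance (deterministic)
    remap: dict[int, int] = {}
    labels = np.empty(n_rows, dtype=int)
    for i, c in enumerate(flat):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[i] = remap[c]
    return labels


def hac_cluster(m: TermDocumentMatrix, k: int, Z: np.ndarray | None = None, key: str = "") -> ClusterSet:
    """Cut the Ward dendrogram of the matrix rows at exactly k clusters."""
    n = len(m.row_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        Z = ward_linkage(m) if Z is None else Z
        labels = _cut_labels(Z, n, k)
    return ClusterSet(key=key, k=k, assignments=dict(zip(m.row_ids, labels.tolist())))


def cart_scree(
    m: TermDocumentMatrix,
    k_range: tuple[int, int],
    config: ClusterSelectConfig | None = None,
    Z: np.ndarray | None = None,
) -> dict[int, float]:
    """Cluster-separability scree: cross-validated decision-tree accuracy of
    predicting cluster labels from TF-IDF features, for each k in range."""
    config = config or ClusterSelectConfig()
    n = len(m.row_ids)
    lo, hi = k_range
    if not (2 <= lo <= hi <= n - 1):
        raise ValueError(f"k_range {k_range} must lie within [2, {n - 1}]")
    Z = ward_linkage(m) if Z is None else Z
    X = m.dense()
    scree: dict[int, float] = {}
    for k in range(lo, hi + 1):
        y = _cut_labels(Z, n, k)
        tree = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=config.min_samples_leaf,
            random_state=config.seed,
        )
        min_count = int(np.bincount(y)[1:].min())
        folds = min(config.cv_folds, min_count)
        if folds < 2:
            warnings.warn(
                f"k={k}: a cluster is a singleton; using resubstitution accuracy",
                stacklevel=2,
            )
            scree[k] = float(tree.fit(X, y).score(X, y))
            continue
        if folds < config.cv_folds:
            warnings.warn(
                f"k={k}: smallest cluster has {min_count} members; reducing to {folds} folds",
                stacklevel=2,
            )
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
        scree[k] = float(np.mean(cross_val_score(tree, X, y, cv=cv)))
    return scree


def select_k_cart(
    scree: Mapping[int, float], threshold: float = 0.90, drop: float = 0.02
) -> int:
    """Smallest k that is still well-classified (accuracy >= threshold) and
    followed by a significant accuracy drop at k+1; falls back to the argmax
    when no such cliff exists."""
    if not scree:
        raise ValueError("empty scree")
    ks = sorted(scree)
    for k in ks:
        if k + 1 in scree and scree[k] >= threshold and scree[k] - scree[k + 1] >= drop:
            return k
    return max(ks, key=lambda k: (scree[k], -k))


def sqrt_threshold(U: int) -> int:
    """Minimum unique terms a cluster must keep: floor(sqrt(U)) for a
    sub-category with U unique terms (e.g. U=1404 -> 37)."""
    if U < 1:
        raise ValueError("U must be >= 1")
    return int(np.floor(np.sqrt(U)))


def _cluster_term_counts(X_binary: np.ndarray, labels: np.ndarray) -> list[int]:
    return [
        int((X_binary[labels == c].any(axis=0)).sum()) for c in np.unique(labels)
    ]


def min_sqrt_kmax(
    m: TermDocumentMatrix,
    k_range: tuple[int, int],
    Z: np.ndarray | None = None,
) -> int:
    """Largest k in range whose every cluster keeps at least floor(sqrt(U))
    unique terms; returns the range minimum (with a warning) if none does."""
    n = len(m.row_ids)
    lo, hi = k_range
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"k_range {k_range} must lie within [1, {n}]")
    Z = ward_linkage(m) if Z is None else Z
    X_binary = m.dense() > 0
    U = int(X_binary.any(axis=0).sum())
    T = sqrt_threshold(max(U, 1))
    for k in range(hi, lo - 1, -1):
        labels = _cut_labels(Z, n, k) if k > 1 else np.ones(n, dtype=int)
        if min(_cluster_term_counts(X_binary, labels)) >= T:
            return k
    warnings.warn(
        f"no k in {k_range} keeps >= {T} unique terms per cluster; using k={lo}",
        stacklevel=2,
    )
    return lo


def ward_plateau(
    m: TermDocumentMatrix,
    k_range: tuple[int, int],
    eps: float = 0.05,
    Z: np.ndarray | None = None,
) -> tuple[int, int]:
    """Widest contiguous interval of k where successive dendrogram merge
    heights differ by less than ``eps`` times the maximum merge height.

    The merge creating the k-cluster cut has height h[n-1-k] (heights in
    merge order); k and k+1 belong to the same flat stretch when their
    creating merges are close in height — the short vertical steps of the
    dendrogram.  Fewer than 3 rows yields the degenerate interval (1, 1).
    """
    n = len(m.row_ids)
    if n < 3:
        return (1, 1)
    Z = ward_linkage(m) if Z is None else Z
    heights = Z[:, 2]
    hmax = float(heights.max())
    if hmax == 0.0:
        return (max(k_range[0], 1), min(k_range[1], n))
    lo, hi = max(k_range[0], 2), min(k_range[1], n - 2)
    flat = [
        k
        for k in range(lo, hi + 1)
        if abs(heights[n - 1 - k] - heights[n - 2 - k]) < eps * hmax
    ]
    if not flat:
        return (lo, lo)
    best_start = best_end = cur_start = flat[0]
    prev = flat[0]
    for k in flat[1:]:
        if k == prev + 1:
            prev = k
        else:
            if prev - cur_start > best_end - best_start:
                best_start, best_end = cur_start, prev
            cur_start = prev = k
    if prev - cur_start > best_end - best_start:
        best_start, best_end = cur_start, prev
    return (best_start, best_end)


def two_stage_cluster(
    m: TermDocumentMatrix, n_initial: int, k: int, key: str = ""
) -> ClusterSet:
    """Optional coarse-then-fine mode: cut documents into ``n_initial``
    clusters, then Ward-cluster the cluster centroids down to k and relabel
    each document by its centroid's final cluster."""
    n = len(m.row_ids)
    n_initial = min(n_initial, n)
    if not 1 <= k <= n_initial:
        raise ValueError(f"k={k} out of range [1, {n_initial}]")
    Z = ward_linkage(m)
    coarse = _cut_labels(Z, n, n_initial) if n_initial > 1 else np.ones(n, dtype=int)
    X = m.dense()
    centroids = np.vstack([X[coarse == c].mean(axis=0) for c in range(1, n_initial + 1)])
    Zc = linkage(centroids, method="ward", metric="euclidean")
    fine = _cut_labels(Zc, n_initial, k) if k > 1 else np.ones(n_initial, dtype=int)
    labels = fine[coarse - 1]
    return ClusterSet(key=key, k=k, assignments=dict(zip(m.row_ids, labels.tolist())))


def resolve_k(k_cart: int, k_sqrt: int, plateau: tuple[int, int]) -> tuple[int, bool]:
    """The agreement rule: if the square-root k lies inside the Ward plateau
    the diagnostics agree and it is final; otherwise take the maximum of the
    candidates (CART k, square-root k, plateau upper end)."""
    agreed = plateau[0] <= k_sqrt <= plateau[1]
    return (k_sqrt if agreed else max(k_cart, k_sqrt, plateau[1])), agreed


def select_k(
    m: TermDocumentMatrix,
    config: ClusterSelectConfig | None = None,
    key: str = "",
) -> KSelectionReport:
    """Run the three diagnostics and decide k.

    Agreement means the square-root k lies inside the Ward plateau, in which
    case it is final; otherwise the maximum of (CART k, square-root k,
    plateau upper end) is taken.  Degenerate inputs (fewer than 3 rows)
    yield k=1.
    """
    config = config or ClusterSelectConfig()
    n = len(m.row_ids)
    if n < 3:
        return KSelectionReport(
            key=key, scree={}, k_cart=1, k_sqrt=1, plateau=(1, 1), k_final=1, agreed=False
        )
    k_range = config.k_range or (2, min(15, n - 1))
    lo, hi = max(2, k_range[0]), min(k_range[1], n - 1)
    Z = ward_linkage(m)
    scree = cart_scree(m, (lo, hi), config, Z=Z)
    k_cart = select_k_cart(scree, config.cart_threshold, config.cart_drop)
    k_sqrt = min_sqrt_kmax(m, (lo, hi), Z=Z)
    plateau = ward_plateau(m, (lo, hi), config.plateau_eps, Z=Z)
    k_final, agreed = resolve_k(k_cart, k_sqrt, plateau)
    return KSelectionReport(
        key=key, scree=scree, k_cart=k_cart, k_sqrt=k_sqrt,
        plateau=plateau, k_final=k_final, agreed=agreed,
    )
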