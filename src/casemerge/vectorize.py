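"""TF-IDF term-document matrices.

Weights are raw term frequency times ``idf = ln(N/df) + 1`` with no row
normalization, so document vectors retain their natural length.  Cluster-set
distances computed downstream therefore live on the same absolute scale for
corpora of comparable document length, which is what makes fixed distance
buckets (0-10, 11-20, ...) meaningful.

Cross-sub-category comparisons are made in a *pooled* space: the documents of
both sub-categories are stacked and vectorized together, so both sides share
one vocabulary and one idf.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer

from .text import TokenizedDoc


@dataclass
class TermDocumentMatrix:
    """TF-IDF weights: one row per document, one column per vocabulary term."""

    vocab: list[str]
    row_ids: list[str]
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.weights.shape != (len(self.row_ids), len(self.vocab)):
            raise ValueError("weights shape does not match row_ids x vocab")
        self._row_index = {rid: i for i, rid in enumerate(self.row_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.weights.todense())

    def rows(self, row_ids: Sequence[str]) -> np.ndarray:
        """Dense sub-matrix for the given documents, in the given order."""
        idx = [self._row_index[r] for r in row_ids]
        return np.asarray(self.weights[idx].todense())

    def export(self, prefix: str | Path) -> None:
        """Write weights as Matrix Market plus vocab/row-id text files."""
        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.weights)
        prefix.with_suffix(".vocab.txt").write_text("\n".join(self.vocab) + "\n")
        prefix.with_suffix(".rows.txt").write_text("\n".join(self.row_ids) + "\n")


def build_tfidf(
    docs: Sequence[TokenizedDoc],
    vocab: Sequence[str] | None = None,
    min_df: int = 1,
) -> TermDocumentMatrix:
    """Build a TF-IDF matrix over tokenized documents.

    ``tf`` is the raw in-document count, ``idf = ln(N/df) + 1``, and rows are
    not normalized.  If ``vocab`` is given, columns are restricted and ordered
    to it and out-of-vocabulary tokens are dropped (restricting never changes
    the weight of a surviving term); otherwise the vocabulary is the sorted
    set of observed terms and carries no all-zero column.
    """
    if not docs or all(not d.tokens for d in docs):
        raise ValueError("cannot build TF-IDF: no non-empty documents")
    counter = CountVectorizer(
        analyzer=lambda doc: doc.tokens,
        vocabulary=list(vocab) if vocab is not None else None,
        min_df=min_df,
        lowercase=False,
    )
    counts = counter.fit_transform(docs)
    weights = TfidfTransformer(norm=None, smooth_idf=False, sublinear_tf=False).fit_transform(
        counts
    )
    if vocab is not None:
        out_vocab = list(vocab)
    else:
        out_vocab = counter.get_feature_names_out().tolist()
    return TermDocumentMatrix(
        vocab=out_vocab,
        row_ids=[d.case_id for d in docs],
        weights=sp.csr_matrix(weights),
    )


def joint_vocabulary(
    docs_a: Sequence[TokenizedDoc], docs_b: Sequence[TokenizedDoc]
) -> list[str]:
    """Sorted union of the two document sets' vocabularies."""
    terms: set[str] = set()
    for d in docs_a:
        terms.update(d.tokens)
    for d in docs_b:
        terms.update(d.tokens)
    return sorted(terms)


def pooled_tfidf(
    docs_a: Sequence[TokenizedDoc],
    docs_b: Sequence[TokenizedDoc],
    prefix_a: str = "a",
    prefix_b: str = "b",
) -> TermDocumentMatrix:
    """Vectorize two document sets in one shared space.

    Documents are stacked (A first) and TF-IDF is computed over the pooled
    set, so idf reflects both sides.  Row ids are prefixed (``a::``/``b::``)
    to stay unique when the same case appears in both sub-categories.
    """
    pooled = [
        TokenizedDoc(case_id=f"{prefix_a}::{d.case_id}", tokens=d.tokens) for d in docs_a
    ] + [TokenizedDoc(case_id=f"{prefix_b}::{d.case_id}", tokens=d.tokens) for d in docs_b]
    return build_tfidf(pooled)


def unique_term_count(docs: Sequence[TokenizedDoc]) -> int:
    """Number of distinct tokens across all documents."""
    terms: set[str] = set()
    for d in docs:
        terms.update(d.tokens)
    return len(terms)
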