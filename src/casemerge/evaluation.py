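"""Validation statistics for merge decisions.

Three audits complement the Hausdorff merge rule:

* **Top-term overlap** — two merged sub-categories should share a majority of
  their top-25 frequent terms (pass at >= 50%).
* **Case term coverage** — a sub-category's top terms should actually appear
  in its cases: the mean fraction of a case's distinct tokens found among the
  top-25 terms, judged relevant at >= 15%.
* **Merge rate** — the headline percentage of sub-categories absorbed into
  merge groups.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import ClinicalCase
from .naming import TermRanking, top_frequent_terms
from .text import TokenizedDoc

OVERLAP_PASS_THRESHOLD = 0.5
COVERAGE_PASS_THRESHOLD = 0.15


@dataclass
class OverlapReport:
    pair: tuple[str, str]
    overlap: float
    passes: bool


def overlap_validation(
    docs_a: Sequence[TokenizedDoc],
    docs_b: Sequence[TokenizedDoc],
    n: int = 25,
    keys: tuple[str, str] = ("a", "b"),
) -> OverlapReport:
    """Fraction of shared top-n frequent terms between two sub-categories.

    Symmetric; the denominator is capped by the smaller ranking so identical
    small corpora score 1.0.  Passes at >= 50%.
    """
    ra = top_frequent_terms(docs_a, n)
    rb = top_frequent_terms(docs_b, n)
    denom = min(n, len(ra.terms), len(rb.terms))
    overlap = len(ra.term_set & rb.term_set) / denom
    return OverlapReport(pair=keys, overlap=overlap, passes=overlap >= OVERLAP_PASS_THRESHOLD)


def case_term_coverage(case: TokenizedDoc, ranking: TermRanking) -> float:
    """Fraction of the case's *distinct* tokens that are top-ranked terms."""
    distinct = set(case.tokens)
    if not distinct:
        raise ValueError(f"case {case.case_id!r} has no tokens")
    return len(distinct & ranking.term_set) / len(distinct)


def mean_case_coverage(
    docs: Iterable[TokenizedDoc],
    ranking: TermRanking,
    threshold: float = COVERAGE_PASS_THRESHOLD,
) -> tuple[float, bool]:
    """Mean case term coverage and whether it clears the relevance threshold.

    Empty cases are excluded from the mean (with a warning)."""
    values = []
    for d in docs:
        if not d.tokens:
            warnings.warn(f"case {d.case_id!r} is empty; excluded from coverage mean",
                          stacklevel=2)
            continue
        values.append(case_term_coverage(d, ranking))
    if not values:
        raise ValueError("no non-empty cases to average")
    mean = sum(values) / len(values)
    return mean, mean >= threshold


def merge_rate(merged_count: int, total_count: int) -> int:
    """Percentage of sub-categories merged, rounded to the nearest integer
    (e.g. 72 of 82 -> 88)."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= merged_count <= total_count:
        raise ValueError("merged_count must lie in [0, total_count]")
    return round(100 * merged_count / total_count)


def sample_cases_for_review(
    cases: Sequence[ClinicalCase], n: int = 20, seed: int = 0,
    path: str | Path | None = None,
) -> list[ClinicalCase]:
    """Seeded uniform sample of cases exported for human relevance review
    (the YES/NO judgment itself is a human step, not computed here)."""
    rng = random.Random(seed)
    sample = rng.sample(list(cases), min(n, len(cases)))
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            for c in sample:
                fh.write(json.dumps(
                    {"case_id": c.case_id, "source_id": c.source_id, "fields": c.fields},
                    ensure_ascii=False) + "\n")
    return sample
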