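"""Attribute naming for merge groups and emission of the integrated schema.

The name of a merged attribute is decided by a cascade:

1. If two or more member sub-categories share the same (normalized) caption,
   that caption wins — sources that independently chose "diagnosis" settle
   the question.
2. Otherwise each member's top frequent terms are compared against the top
   frequent terms of the pooled (merged) documents; the member with maximum
   coverage of the merged ranking lends its caption.  Coverage ties are
   broken by matching member captions against the ontology entity labels of
   the group's top-5 terms; a remaining tie is resolved by a seeded uniform
   choice.

The emitted schema is one attribute per merge group plus one source-qualified
attribute per unmerged sub-category.
"""

from __future__ import annotations

import random
import re
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import CodingStandard
from .merge import MergeGroup
from .text import TokenizedDoc

_NORM_RE = re.compile(r"[^a-z0-9]+")


def normalize_caption(caption: str) -> str:
    return _NORM_RE.sub("", caption.lower())


@dataclass
class TermRanking:
    """Terms of a corpus ranked by frequency (descending; ties lexicographic)."""

    owner: str
    terms: tuple[tuple[str, int], ...]

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.terms)


@dataclass
class SchemaAttribute:
    name: str
    members: tuple[str, ...]
    provenance: str  # same_name | coverage | ontology | random | singleton


def top_frequent_terms(docs: Sequence[TokenizedDoc], n: int = 25, owner: str = "") -> TermRanking:
    """The n most frequent terms; ties broken lexicographically.  Returns the
    full ranking when the vocabulary is smaller than n."""
    counts: Counter[str] = Counter()
    for d in docs:
        counts.update(d.tokens)
    if not counts:
        raise ValueError("cannot rank terms of an empty corpus")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return TermRanking(owner=owner, terms=tuple(ranked[:n]))


def term_coverage(member: TermRanking, merged: TermRanking) -> float:
    """Fraction of the merged ranking's terms present in the member's ranking."""
    if not member.terms or not merged.terms:
        raise ValueError("rankings must be non-empty")
    return len(member.term_set & merged.term_set) / len(merged.terms)


def _caption_of(key: str) -> str:
    return key.split("/", 1)[1] if "/" in key else key


def assign_attribute_name(
    group: MergeGroup,
    rankings: Mapping[str, TermRanking],
    merged_ranking: TermRanking,
    ontology: CodingStandard | None = None,
    seed: int = 0,
) -> SchemaAttribute:
    """Name a merge group by the caption cascade (deterministic given seed).

    ``rankings`` maps each member key (``source/caption``) to its own top-term
    ranking; ``merged_ranking`` is the ranking of the pooled group documents.
    """
    members = sorted(group.members)
    if not members:
        raise ValueError("cannot name an empty merge group")

    # rule 1: shared caption
    norm_counts = Counter(normalize_caption(_caption_of(k)) for k in members)
    best_norm, count = max(norm_counts.items(), key=lambda kv: (kv[1], kv[0]))
    if count >= 2:
        # preserve the original capitalization of the first sharer
        for k in members:
            if normalize_caption(_caption_of(k)) == best_norm:
                return SchemaAttribute(
                    name=_caption_of(k), members=tuple(members), provenance="same_name"
                )

    # rule 2: maximum coverage of the merged ranking
    coverages = {k: term_coverage(rankings[k], merged_ranking) for k in members}
    best_cov = max(coverages.values())
    tied = [k for k in members if coverages[k] == best_cov]
    if len(tied) == 1:
        return SchemaAttribute(
            name=_caption_of(tied[0]), members=tuple(members), provenance="coverage"
        )

    # rule 2e: ontology entities of the group's top-5 terms
    if ontology is not None and len(ontology) > 0:
        entities = set()
        for term, _ in merged_ranking.terms[:5]:
            entry = ontology.lookup(term)
            if entry is not None:
                entities.add(normalize_caption(entry.entity))
        onto_matches = [k for k in tied if normalize_caption(_caption_of(k)) in entities]
        if len(onto_matches) == 1:
            return SchemaAttribute(
                name=_caption_of(onto_matches[0]), members=tuple(members), provenance="ontology"
            )
        if onto_matches:
            tied = onto_matches

    choice = random.Random(seed).choice(sorted(tied))
    return SchemaAttribute(
        name=_caption_of(choice), members=tuple(members), provenance="random"
    )


def emit_schema(
    attributes: Sequence[SchemaAttribute],
    unmerged: Sequence[str] = (),
) -> dict:
    """Build the integrated-schema document: one attribute per merge group
    plus one source-qualified attribute per unmerged sub-category.

    Name collisions after normalization are disambiguated with numeric
    suffixes.  Every input sub-category appears exactly once.
    """
    attrs = list(attributes) + [
        SchemaAttribute(name=k.replace("/", "_"), members=(k,), provenance="singleton")
        for k in unmerged
    ]
    used: dict[str, int] = {}
    out = []
    for a in attrs:
        norm = normalize_caption(a.name) or "attribute"
        used[norm] = used.get(norm, 0) + 1
        name = a.name if used[norm] == 1 else f"{a.name}_{used[norm]}"
        out.append(
            {
                "name": name,
                "members": list(a.members),
                "provenance": a.provenance,
            }
        )
    return {"attributes": out}


def render_sql(schema: dict, table: str = "integrated_cases") -> str:
    """Render the schema as a single-table DDL with text columns."""
    cols = ",\n".join(
        f'    "{_sql_ident(a["name"])}" TEXT' for a in schema["attributes"]
    )
    return (
        f"CREATE TABLE {table} (\n"
        "    case_id TEXT PRIMARY KEY,\n"
        "    source_id TEXT,\n"
        f"{cols}\n"
        ");\n"
    )


def _sql_ident(name: str) -> str:
    ident = re.sub(r"[^A-Za-z0-9_]+", "_", name).strip("_").lower()
    return ident or "attribute"
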