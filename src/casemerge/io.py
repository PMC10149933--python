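"""Corpus, coding-standard and word-list input/output.

A corpus is a flat list of :class:`ClinicalCase` records, each belonging to one
source and carrying a mapping from sub-category caption (e.g. ``"history"``,
``"findings"``) to free text.  Two plain-text dialects are supported:

* **JSONL** — one JSON object per line with keys ``case_id``, ``source_id`` and
  ``fields`` (caption → text).  A caption absent from ``fields`` (or mapped to
  ``null``) is *missing*; an empty string is present-but-empty.
* **CSV** — columns ``case_id``, ``source_id`` followed by one column per
  caption; an empty cell means the field is missing.

Coding standards (term dictionaries derived from medical ontologies such as
RadLex or SNOMED CT) are read from 4-column TSV: term, pipe-separated
synonyms, definition, entity label.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class CorpusFormatError(ValueError):
    """Raised for malformed corpus or dictionary files."""


@dataclass
class ClinicalCase:
    """One clinical case: captioned free-text fields from a single source.

    ``fields`` holds only *present* captions; a missing field is simply absent
    from the mapping, which keeps "missing" distinguishable from an empty
    string.  Captions whose text was filled in by imputation are listed in
    ``imputed``.
    """

    case_id: str
    source_id: str
    fields: dict[str, str] = field(default_factory=dict)
    imputed: set[str] = field(default_factory=set)

    def has_field(self, caption: str) -> bool:
        return caption in self.fields


@dataclass(frozen=True)
class SubCategory:
    """One source's captioned collection of case texts.

    This is the unit that gets clustered and merged: all non-empty texts filed
    under one caption within one source, in corpus order.
    """

    source_id: str
    caption: str
    documents: tuple[tuple[str, str], ...]  # (case_id, raw text)

    @property
    def key(self) -> str:
        return f"{self.source_id}/{self.caption}"


@dataclass(frozen=True)
class CodingEntry:
    term: str
    synonyms: tuple[str, ...]
    definition: str
    entity: str


@dataclass
class CodingStandard:
    """Term dictionary mapping clinical terms to synonyms and entity labels."""

    entries: list[CodingEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_term: dict[str, CodingEntry] = {}
        for e in self.entries:
            self._by_term[e.term] = e
            for s in e.synonyms:
                self._by_term.setdefault(s.lower(), e)

    def lookup(self, term: str) -> CodingEntry | None:
        """Find the entry for a term or any of its synonyms (case-insensitive)."""
        return self._by_term.get(term.lower())

    def __len__(self) -> int:
        return len(self.entries)


def load_corpus(path: str | Path, format: str = "jsonl") -> list[ClinicalCase]:
    """Read a corpus file in the JSONL or CSV dialect.

    Input order is preserved and ``case_id`` uniqueness is enforced.
    """
    path = Path(path)
    if format == "jsonl":
        cases = _load_jsonl(path)
    elif format == "csv":
        cases = _load_csv(path)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    seen: set[str] = set()
    for c in cases:
        if c.case_id in seen:
            raise CorpusFormatError(f"duplicate case_id: {c.case_id!r}")
        seen.add(c.case_id)
    return cases


def _load_jsonl(path: Path) -> list[ClinicalCase]:
    cases = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                fields = {
                    str(k): str(v)
                    for k, v in obj["fields"].items()
                    if v is not None
                }
                case = ClinicalCase(
                    case_id=str(obj["case_id"]),
                    source_id=str(obj["source_id"]),
                    fields=fields,
                    imputed=set(obj.get("imputed", ())),
                )
            except (json.JSONDecodeError, KeyError, TypeError, AttributeError) as exc:
                raise CorpusFormatError(f"{path}: malformed line {lineno}: {exc}") from exc
            cases.append(case)
    return cases


def _load_csv(path: Path) -> list[ClinicalCase]:
    cases = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if header[:2] != ["case_id", "source_id"]:
            raise CorpusFormatError(
                f"{path}: CSV header must start with case_id,source_id; got {header[:2]}"
            )
        captions = header[2:]
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(row)}"
                )
            fields = {cap: cell for cap, cell in zip(captions, row[2:]) if cell != ""}
            cases.append(ClinicalCase(case_id=row[0], source_id=row[1], fields=fields))
    return cases


def write_corpus(cases: Sequence[ClinicalCase], path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus in the JSONL or CSV dialect (inverse of :func:`load_corpus`)."""
    path = Path(path)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for c in cases:
                obj = {"case_id": c.case_id, "source_id": c.source_id, "fields": c.fields}
                if c.imputed:
                    obj["imputed"] = sorted(c.imputed)
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif format == "csv":
        captions: list[str] = []
        for c in cases:
            for cap in c.fields:
                if cap not in captions:
                    captions.append(cap)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "source_id", *captions])
            for c in cases:
                writer.writerow(
                    [c.case_id, c.source_id, *(c.fields.get(cap, "") for cap in captions)]
                )
    else:
        raise ValueError(f"unknown corpus format: {format!r}")


def assemble_subcategories(cases: Iterable[ClinicalCase]) -> list[SubCategory]:
    """Group case texts into one :class:`SubCategory` per (source, caption).

    A case contributes to a caption's document list iff the field is present
    and non-empty after whitespace stripping.  Captions appear in first-seen
    order; documents keep corpus order.
    """
    docs: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for case in cases:
        for caption, text in case.fields.items():
            key = (case.source_id, caption)
            docs.setdefault(key, [])
            if text.strip():
                docs[key].append((case.case_id, text))
    return [
        SubCategory(source_id=src, caption=cap, documents=tuple(d))
        for (src, cap), d in docs.items()
        if d
    ]


def load_coding_standard(path: str | Path) -> CodingStandard:
    """Read a 4-column TSV term dictionary: term, synonyms (pipe-separated),
    definition, entity label.  Terms are lowercased; duplicates are an error."""
    path = Path(path)
    entries: list[CodingEntry] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 4 tab-separated columns, got {len(cols)}"
                )
            term = cols[0].strip().lower()
            if term in seen:
                raise CorpusFormatError(f"{path}: line {lineno}: duplicate term {term!r}")
            seen.add(term)
            synonyms = tuple(s.strip() for s in cols[1].split("|") if s.strip())
            entries.append(
                CodingEntry(term=term, synonyms=synonyms, definition=cols[2].strip(),
                            entity=cols[3].strip())
            )
    return CodingStandard(entries=entries)


def load_wordlist(path: str | Path) -> set[str]:
    """Read a plain-text word list: one lowercase token per line, ``#`` comments."""
    words: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                words.add(line.lower())
    return words
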