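"""Text cleaning, tokenization and Gestalt-similarity imputation.

Cleaning lowercases, splits on non-alphanumeric runs, removes English
stop-words except for a configurable *keep-list* of clinically meaningful
function words (negations and spatial modifiers such as "no", "with",
"below" carry diagnostic meaning and must survive), and normalizes
inflection either with a light rule-based English lemmatizer or a Porter
stemmer.

Gestalt (Ratcliff/Obershelp) similarity is used to impute a missing
sub-category from a present one whose caption is nearly the same string
(e.g. "finding" vs "findings"), a common artefact of heterogeneous sources.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from difflib import SequenceMatcher
from functools import lru_cache

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .io import ClinicalCase

#: Clinically meaningful stop-words kept during cleaning.  The keep-list is a
#: configuration input; this default holds the canonical five examples.
DEFAULT_KEEP_LIST = frozenset({"most", "between", "no", "below", "with"})

DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass(frozen=True)
class CleanConfig:
    """Configuration for :func:`clean_text` and imputation.

    Parameters
    ----------
    stopword_list : frozenset of str
        Base stop-word list (lowercase).
    keep_list : frozenset of str
        Tokens exempt from stop-word removal.
    stemmer : {"lemmatize", "porter", "none"}
        Inflection normalizer.  ``lemmatize`` maps e.g. "studies" and
        "studying" to "study"; ``porter`` applies classic Porter stemming.
    min_token_len : int
        Tokens shorter than this are dropped (garbage-character removal).
    impute_threshold : float
        Minimum caption Gestalt similarity for missing-field imputation.
    """

    stopword_list: frozenset[str] = DEFAULT_STOPWORDS
    keep_list: frozenset[str] = DEFAULT_KEEP_LIST
    stemmer: str = "lemmatize"
    min_token_len: int = 2
    impute_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.stemmer not in ("lemmatize", "porter", "none"):
            raise ValueError(f"unknown stemmer: {self.stemmer!r}")
        if self.min_token_len < 1:
            raise ValueError("min_token_len must be >= 1")
        if not 0.0 <= self.impute_threshold <= 1.0:
            raise ValueError("impute_threshold must be in [0, 1]")

    @property
    def effective_stopwords(self) -> frozenset[str]:
        return self.stopword_list - self.keep_list


@dataclass(frozen=True)
class TokenizedDoc:
    case_id: str
    tokens: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Inflection normalizers
# ---------------------------------------------------------------------------

_VOWELS = set("aeiou")

_IRREGULAR = {
    "feet": "foot", "teeth": "tooth", "men": "man", "women": "woman",
    "children": "child", "diagnoses": "diagnosis", "metastases": "metastasis",
    "stenoses": "stenosis", "prognoses": "prognosis", "foci": "focus",
    "nuclei": "nucleus", "vertebrae": "vertebra",
}


def lemmatize(token: str) -> str:
    """Light rule-based English lemmatizer: strips plural and participle
    inflection ("studies", "studying" -> "study"; "scanned" -> "scan")."""
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    n = len(token)
    if token.endswith("ies") and n > 4:
        return token[:-3] + "y"
    if token.endswith("ying") and n > 5:
        return token[:-4] + "y"
    if token.endswith("ing") and n > 5:
        stem = token[:-3]
        if not any(ch in _VOWELS for ch in stem):
            return token
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS | {"l", "s"}:
            stem = stem[:-1]  # running -> run
        elif _needs_e(stem):
            stem += "e"  # imaging -> image
        return stem
    if token.endswith("ied") and n > 4:
        return token[:-3] + "y"
    if token.endswith("ed") and n > 4:
        stem = token[:-2]
        if not any(ch in _VOWELS for ch in stem):
            return token
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS | {"l", "s"}:
            stem = stem[:-1]
        elif _needs_e(stem):
            stem += "e"
        return stem
    if token.endswith("sses") and n > 5:
        return token[:-2]
    if token.endswith(("xes", "zes", "ches", "shes")) and n > 4:
        return token[:-2]
    if token.endswith("s") and n > 3 and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def _needs_e(stem: str) -> bool:
    # consonant + 'v'/'s'-like endings where dropping 'e' happened: imag-, clos-
    return len(stem) > 3 and stem[-1] in "vcgzs" and stem[-2] in _VOWELS


def porter_stem(token: str) -> str:
    """Classic Porter stemmer (suffix-stripping; 'studies' -> 'studi')."""
    return _porter(token)


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in "aeiou":
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    # number of VC sequences
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if prev_vowel and cons:
            m += 1
        prev_vowel = not cons
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_cvc(stem: str) -> bool:
    if len(stem) < 3:
        return False
    c1, v, c2 = len(stem) - 3, len(stem) - 2, len(stem) - 1
    return (
        _is_cons(stem, c1)
        and not _is_cons(stem, v)
        and _is_cons(stem, c2)
        and stem[c2] not in "wxy"
    )


def _porter(w: str) -> str:
    if len(w) <= 2:
        return w
    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]
    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _contains_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and _contains_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif len(w) >= 2 and w[-1] == w[-2] and _is_cons(w, len(w) - 1) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"
    # step 1c
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"
    # step 2
    for suf, rep in (
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ):
        if w.endswith(suf):
            if _measure(w[: -len(suf)]) > 0:
                w = w[: -len(suf)] + rep
            break
    # step 3
    for suf, rep in (
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ):
        if w.endswith(suf):
            if _measure(w[: -len(suf)]) > 0:
                w = w[: -len(suf)] + rep
            break
    # step 4
    for suf in (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ):
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 1:
                w = stem
            break
    else:
        if w.endswith("ion") and len(w) > 3 and w[-4] in "st" and _measure(w[:-3]) > 1:
            w = w[:-3]
    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        if _measure(stem) > 1 or (_measure(stem) == 1 and not _ends_cvc(stem)):
            w = stem
    # step 5b
    if len(w) >= 2 and w[-1] == "l" and w[-2] == "l" and _measure(w) > 1:
        w = w[:-1]
    return w


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def clean_text(raw: str, config: CleanConfig | None = None, case_id: str = "") -> TokenizedDoc:
    """Lowercase, tokenize on non-alphanumeric runs, drop stop-words (except
    keep-list members) and short tokens, and normalize inflection.

    Deterministic; empty input yields an empty token list.
    """
    config = config or CleanConfig()
    removed = config.effective_stopwords
    if config.stemmer == "lemmatize":
        norm = lemmatize
    elif config.stemmer == "porter":
        norm = porter_stem
    else:
        norm = lambda t: t  # noqa: E731
    tokens = []
    for tok in _TOKEN_RE.findall(raw.lower()):
        if tok in removed:
            continue
        tok = norm(tok) if tok not in config.keep_list else tok
        if len(tok) < config.min_token_len:
            continue
        tokens.append(tok)
    return TokenizedDoc(case_id=case_id, tokens=tuple(tokens))


# ---------------------------------------------------------------------------
# Gestalt (Ratcliff/Obershelp) pattern-matching similarity
# ---------------------------------------------------------------------------

# Beyond this combined length the exact recursion falls back to the classic
# greedy algorithm (a lower bound); captions compared in practice are short.
_EXACT_LIMIT = 64


@lru_cache(maxsize=65536)
def _matched_length(s1: str, s2: str) -> int:
    """Total length of recursively matched common blocks, maximizing over all
    positions of the longest common substring.

    The classic Ratcliff/Obershelp recursion anchors on *a* longest common
    substring and recurses left and right of it.  When several longest blocks
    exist, different anchors can yield different totals; taking the maximum
    makes the score well-defined and symmetric.
    """
    if not s1 or not s2:
        return 0
    best_len = 0
    positions: list[tuple[int, int]] = []
    n2 = len(s2)
    for i in range(len(s1)):
        for j in range(n2):
            length = 0
            while i + length < len(s1) and j + length < n2 and s1[i + length] == s2[j + length]:
                length += 1
            if length > best_len:
                best_len = length
                positions = [(i, j)]
            elif length == best_len and length > 0:
                positions.append((i, j))
    if best_len == 0:
        return 0
    return best_len + max(
        _matched_length(s1[:i], s2[:j])
        + _matched_length(s1[i + best_len :], s2[j + best_len :])
        for i, j in positions
    )


def gestalt_similarity(s1: str, s2: str) -> float:
    """Ratcliff/Obershelp ratio 2K / (|s1| + |s2|), where K is the total
    length of recursively matched common blocks.

    Symmetric, bounded in [0, 1], and exactly 1 iff the strings are
    identical.  Two empty strings are defined as identical (1.0).
    """
    if not s1 and not s2:
        return 1.0
    total = len(s1) + len(s2)
    if len(s1) + len(s2) <= _EXACT_LIMIT:
        k = _matched_length(s1, s2)
    else:
        k = max(
            sum(b.size for b in SequenceMatcher(None, s1, s2, autojunk=False).get_matching_blocks()),
            sum(b.size for b in SequenceMatcher(None, s2, s1, autojunk=False).get_matching_blocks()),
        )
    return 2.0 * k / total


def impute_missing_category(
    case: ClinicalCase, caption: str, config: CleanConfig | None = None
) -> ClinicalCase:
    """Fill a missing caption from the present caption whose *name* is most
    Gestalt-similar, if that similarity reaches ``config.impute_threshold``.

    Returns a new case; present fields are never modified.  The imputed
    caption is recorded in ``case.imputed``.
    """
    config = config or CleanConfig()
    if case.has_field(caption):
        raise ValueError(f"caption {caption!r} is present in case {case.case_id!r}")
    best_caption, best_sim = None, -1.0
    for present in case.fields:
        sim = gestalt_similarity(caption.lower(), present.lower())
        if sim > best_sim:
            best_caption, best_sim = present, sim
    if best_caption is None or best_sim < config.impute_threshold:
        return case
    new_fields = dict(case.fields)
    new_fields[caption] = case.fields[best_caption]
    return replace(case, fields=new_fields, imputed=set(case.imputed) | {caption})
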