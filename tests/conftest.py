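import numpy as np
import pytest

from casemerge.io import ClinicalCase
from casemerge.text import TokenizedDoc


@pytest.fixture
def tiny_cases() -> list[ClinicalCase]:
    """Three cases from two sources with history/findings captions."""
    return [
        ClinicalCase("c1", "mirc", {"history": "chest pain two weeks",
                                    "findings": "no mass with effusion"}),
        ClinicalCase("c2", "mirc", {"history": "fever and cough",
                                    "findings": "right lower lobe opacity"}),
        ClinicalCase("c3", "eurorad", {"history": "headache onset sudden",
                                       "findings": "small subdural collection"}),
    ]


def make_block_docs(
    rng: np.random.Generator,
    t: int = 6,
    docs_per_group: int = 10,
    vocab_per_group: int = 9,
    n_base: int = 3,
    n_rand: int = 1,
) -> tuple[list[TokenizedDoc], list[int]]:
    """Documents with t well-separated vocabulary groups.

    Each group has a small private vocabulary; every document repeats the
    group's base terms and adds random extra terms from the group pool, so
    groups are internally coherent but any small fragment of one carries few
    distinct terms.  Returns the documents and their group labels.
    """
    docs, labels = [], []
    for g in range(t):
        pool = [f"g{g}w{i}" for i in range(vocab_per_group)]
        base = pool[:n_base]
        for d in range(docs_per_group):
            extra = [
                pool[n_base + int(i)]
                for i in rng.choice(vocab_per_group - n_base, size=n_rand, replace=False)
            ]
            docs.append(TokenizedDoc(case_id=f"g{g}d{d}", tokens=tuple(base + extra)))
            labels.append(g)
    return docs, labels


@pytest.fixture
def block_docs():
    rng = np.random.default_rng(7)
    docs, labels = make_block_docs(rng)
    return docs, labels
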