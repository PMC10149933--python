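"""Audit merge decisions with the validation statistics.

Merged sub-categories should share most of their top-25 frequent terms
(pass at >= 50%), and a sub-category's top terms should cover a meaningful
share of each case's tokens (relevant at >= 15%).
"""

import warnings

from casemerge import (
    assemble_subcategories,
    clean_text,
    default_scenarios,
    generate_corpus,
    mean_case_coverage,
    merge_rate,
    overlap_validation,
    top_frequent_terms,
)

warnings.filterwarnings("ignore")

cases, truth = generate_corpus(default_scenarios()["easy"])
subs = {s.key: s for s in assemble_subcategories(cases)}
tok = {
    key: [clean_text(text, case_id=cid) for cid, text in sub.documents]
    for key, sub in subs.items()
}

pairs = [
    ("src0/findings", "src1/observation"),   # same topic
    ("src0/findings", "src1/indication"),    # different topics
]
for a, b in pairs:
    rep = overlap_validation(tok[a], tok[b], n=25, keys=(a, b))
    same = "same topic" if truth[a] == truth[b] else "different topics"
    print(f"top-25 overlap {a} vs {b} ({same}): "
          f"{rep.overlap:.2f} -> {'passes' if rep.passes else 'fails'} (>= 0.50)")

ranking = top_frequent_terms(tok["src0/findings"], n=25, owner="src0/findings")
mean, passes = mean_case_coverage(tok["src0/findings"], ranking)
print(f"mean case term coverage in src0/findings: {mean:.2f} "
      f"-> {'relevant' if passes else 'not relevant'} (>= 0.15)")

print(f"reference merge-rate arithmetic: 72 of 82 -> {merge_rate(72, 82)}%; "
      f"29 of 82 retained -> {merge_rate(29, 82)}%")
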