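"""Clean clinical text and impute a missing section from a near-identical
caption via Gestalt (Ratcliff/Obershelp) string similarity."""

from casemerge import (
    CleanConfig,
    ClinicalCase,
    clean_text,
    gestalt_similarity,
    impute_missing_category,
)

config = CleanConfig()  # lemmatize, English stop-words minus the keep-list

raw = "Studies show NO acute masses, with small effusions."
doc = clean_text(raw, config)
print(f"raw:    {raw}")
print(f"tokens: {doc.tokens}")
# "no" and "with" survive (clinical keep-list); inflections are normalized.

for a, b in [("finding", "findings"), ("history", "findings")]:
    print(f"gestalt({a!r}, {b!r}) = {gestalt_similarity(a, b):.3f}")

case = ClinicalCase("c1", "mirc", {"findings": "no acute disease"})
imputed = impute_missing_category(case, "finding", config)
print(f"missing caption 'finding' imputed from 'findings': "
      f"{imputed.fields.get('finding')!r} (flagged: {sorted(imputed.imputed)})")
# Similarity 0.933 >= threshold 0.8, so the near-identical caption fills in;
# a dissimilar caption like 'history' (0.267) would be left missing.
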