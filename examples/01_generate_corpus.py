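"""Generate a synthetic multi-source clinical corpus with ground truth.

Three sources publish cases whose sections describe the same four latent
topics under different captions.  The truth map records which caption of
which source belongs to which topic — the target the pipeline must recover.
"""

from collections import Counter

from casemerge import assemble_subcategories, default_scenarios, generate_corpus

config = default_scenarios()["easy"]
cases, truth = generate_corpus(config)

print(f"{len(cases)} cases from {config.n_sources} sources")
subs = assemble_subcategories(cases)
for sub in subs:
    print(f"  {sub.key:24s} -> topic {truth[sub.key]:10s} ({len(sub.documents)} documents)")

lengths = [len(text.split()) for c in cases for text in c.fields.values()]
print(f"document lengths: {min(lengths)}-{max(lengths)} tokens")
missing = Counter(len(c.fields) for c in cases)
print(f"fields per case: {dict(sorted(missing.items()))} (4 topics, some fields missing)")
print("sample text:", next(iter(cases[0].fields.values()))[:70], "...")
# Each source/caption pair is one sub-category; captions differ across
# sources even when the underlying topic is the same.
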