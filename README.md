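# casemerge

Clinical case repositories — teaching files, report archives, image-metadata
collections — expose free text under inconsistent section captions: one
source calls a section `findings`, another `observation`, a third
`clinicalfindings`. Integrating such sources into one database means
deciding which captioned sub-categories are semantically the same, without
annotations or a human expert per pair.

`casemerge` implements an unsupervised pipeline for that decision and emits
the resulting integrated schema:

1. **Preprocess** — lowercase, tokenize, lemmatize, drop English stop-words
   except a clinical keep-list (`no`, `with`, `below`, ... carry diagnostic
   meaning); optionally impute a missing section from a present one whose
   caption is Gestalt-similar (Ratcliff/Obershelp ratio `2K/(|s1|+|s2|)`).
2. **Vectorize** — TF-IDF with raw term frequency and `idf = ln(N/df) + 1`,
   no row normalization, so distances live on a stable absolute scale.
3. **Cluster** — Ward-linkage hierarchical agglomerative clustering
   (Euclidean metric) per sub-category. The number of clusters *k* combines
   three diagnostics: a CART scree (decision-tree accuracy of predicting
   cluster labels), the **minimum square-root criterion** (every cluster
   keeps at least ⌊√U⌋ unique terms, U = the sub-category's unique-term
   count), and the Ward dendrogram plateau.
4. **Merge** — for each sub-category pair, every cluster of one side is
   compared with every cluster of the other (many-to-many) by the Hausdorff
   distance

   d_H(A, B) = max( max_{a∈A} min_{b∈B} ‖a−b‖, max_{b∈B} min_{a∈A} ‖a−b‖ )

   in a pooled TF-IDF space. Distances are bucketed into 0–10, 11–20,
   21–30, 31–40, 41+; a pair **merges when ≥ 80% of its cluster-pair
   distances fall within 0–10**. Merged pairs close transitively into merge
   groups.
5. **Name & emit** — each group becomes one schema attribute, named by a
   cascade: shared caption → caption of the member whose top-25 frequent
   terms best cover the pooled ranking → ontology-entity tie-break →
   seeded random choice. Output is JSON plus optional SQL DDL.

A synthetic-corpus generator (`casemerge.synth`) produces multi-source
corpora with aliased captions, formulaic template text, boilerplate junk
and a ground-truth merge map, so the full pipeline is testable end to end
without clinical data.

## Worked example

```sh
python examples/05_build_schema.py
```

prints (seed 0 of the `easy` scenario — 3 sources × 4 topics, 70% shared
vocabulary):

```
12 sub-categories -> 4 merge groups + 1 unmerged
merged: 92% of sub-categories; schema retains 42% of the original count
  attribute 'clinicalfindings'   [random] <- ['src0/findings', 'src1/observation', 'src2/clinicalfindings']
  attribute 'discussion'         [random] <- ['src0/history', 'src1/indication', 'src2/discussion']
  attribute 'protocol'           [random] <- ['src0/technique', 'src1/procedure', 'src2/protocol']
  attribute 'conclusion'         [random] <- ['src1/impression', 'src2/conclusion']
```

Each line is one attribute of the integrated schema: the sub-categories it
absorbed (their captions differ per source but describe one topic) and the
naming rule that fired. One sub-category missed the 80% threshold on this
seed and stays a singleton column — exactly how borderline pairs are meant
to be handled.

The distance mechanics of a single pair:

```sh
python examples/04_merge_subcategories.py
```

```
6 x 6 clusters -> 36 cluster-pair distances
distance buckets: {'0-10': 0.83, '11-20': 0.0, '21-30': 0.17, '31-40': 0.0, '41+': 0.0}
fraction within 0-10: 0.83 -> merged = True (threshold 0.80)
direct full-set Hausdorff baseline: 26.0 (would NOT merge at cutoff 10)
```

83% of the cluster pairs sit within 0–10, so the pair merges; the 17% in
21–30 trace back to one source's boilerplate cluster. That same boilerplate
dominates the *unclustered* full-set distance (26.0), which is why direct
thresholding misses pairs the cluster-level comparison recovers.

Other examples: corpus generation (`01`), text cleaning and Gestalt
imputation (`02`), cluster-number selection (`03`), merge validation
statistics (`06`).

## Command line

```sh
casemerge synth --scenario easy --seed 7 --out data/      # corpus + truth map
casemerge run --corpus data/corpus.jsonl --out out/       # schema + reports
```

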