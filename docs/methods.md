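# Methods

## Problem and model

Heterogeneous clinical sources store case narratives under captioned
sections ("sub-categories"). The package treats schema matching as a
set-distance problem over document clusters: two sub-categories are the
same attribute when the clusters of one are close — as point sets in a
shared TF-IDF space — to the clusters of the other.

The pipeline is: assemble sub-categories → clean and tokenize → TF-IDF →
Ward HAC per sub-category → Hausdorff distances between all cluster pairs
of each sub-category pair → bucket distribution and merge rule → transitive
closure into merge groups → attribute naming → schema emission.

## Text cleaning

Tokens are lowercased alphanumeric runs. Stop-words come from a standard
English list minus a *keep-list* of clinically meaningful function words
(default `{most, between, no, below, with}`): negation and spatial
modifiers change the meaning of findings and must survive. The keep-list is
a plain-text config input. Inflection is normalized by a rule-based English
lemmatizer (plural/participle stripping: "studies"/"studying" → "study");
a classic Porter stemmer is available behind `stemmer="porter"`. Both are
implemented in-package; they are light normalizers, not full morphological
analyzers, and unknown irregular forms pass through unchanged. Tokens
shorter than `min_token_len` (default 2) are dropped as garbage.

### Gestalt similarity and imputation

Missing-section imputation compares *caption strings* with the
Ratcliff/Obershelp ratio `2K/(|s1|+|s2|)`, where `K` is the total length of
recursively matched common blocks. The recursion anchors on a longest
common substring; when several longest blocks exist, different anchors can
yield different totals, so the implementation maximizes over all anchor
positions. That makes the score well-defined and symmetric — the classic
greedy variant (e.g. earliest-anchor implementations) is order-dependent
and can undercount (for "aaa" vs "abaa" greedy finds K=2 where K=3 is
achievable). Above 64 combined characters the exact recursion falls back
to the greedy algorithm; captions are far shorter in practice. Two empty
strings are defined as identical (ratio 1). A missing caption is filled
from the most-similar present caption when the ratio reaches
`impute_threshold` (default 0.8); caption-level matching was chosen over
content-level because it is deterministic, cheap, and matches the
"finding"/"findings" style of heterogeneity the mechanism targets.
Imputed fields are flagged and present fields are never modified.

## TF-IDF convention

Raw term frequency times `idf = ln(N/df) + 1`, no row normalization
(scikit-learn's `TfidfTransformer(norm=None, smooth_idf=False)`). The
unnormalized convention is deliberate: the merge rule uses *absolute*
distance buckets (0–10, 11–20, …), which are only meaningful when document
vectors keep their natural length. Unit-normalized rows would compress all
distances below ~1.4 and make fixed bucket edges useless. Cross-sub-category
comparisons re-vectorize both document sets *pooled*, so both sides share
one vocabulary and one idf; idf is therefore corpus-wide per analysis pool,
not per category. Restricting a matrix to a given vocabulary never changes
the weights of surviving terms. Minimum document frequency defaults to 1.

## Clustering and the choice of k

Ward linkage over Euclidean distances (scipy), cut with `cut_tree`, which
guarantees exactly k clusters and nested cuts even under tied merge
heights; ties are resolved by scipy's deterministic merge order, and labels
are renumbered in order of first appearance. Three diagnostics feed the
choice of k over a candidate range:

* **CART scree** (`cart_scree`): for each k, a decision tree (entropy
  splitting, `min_samples_leaf` 2) is trained to predict cluster labels
  from the TF-IDF features; stratified 5-fold cross-validated accuracy is
  recorded. Cross-validation rather than resubstitution, because a tree
  can trivially memorize its training labels. Folds shrink when the
  smallest cluster is smaller than the fold count; a singleton cluster
  forces resubstitution with a warning. `select_k_cart` picks the smallest
  well-classified k (accuracy ≥ 0.90) followed by a significant drop
  (≥ 0.02 absolute, configurable) at k+1, falling back to the argmax.
* **Minimum square-root criterion** (`min_sqrt_kmax`): the largest k whose
  every cluster keeps at least ⌊√U⌋ unique terms, U being the
  sub-category's unique-term count (U = 1404 gives 37). The rule is the
  printed worked value's reading of the criterion; the comparison is
  inclusive (≥). If no k qualifies, the range minimum is returned with a
  warning.
* **Ward plateau** (`ward_plateau`): the widest contiguous k-interval where
  successive dendrogram merge heights differ by less than `eps` (default
  0.05) times the maximum merge height — the short vertical steps of the
  dendrogram. Fewer than 3 rows yields the degenerate interval (1, 1);
  an all-zero-height dendrogram (duplicate rows) is flat everywhere.

**Agreement rule** (`resolve_k`): if the square-root k lies inside the
plateau, the diagnostics agree and it is final; otherwise the maximum of
(CART k, square-root k, plateau upper end) is taken. Degenerate inputs
(< 3 documents) get k = 1.

An optional two-stage mode (`two_stage=True`) first cuts the documents into
`n_initial` (default 45) clusters, then Ward-clusters the centroids down to
k — the coarse-then-fine variant; single-stage document clustering is the
default because it matches the worked k = 12 selection.

The pipeline's default k-range upper end is ⌈n/10⌉ (capped at 15):
clusters of roughly ten documents, so each cluster's point set supports a
stable Hausdorff estimate. `select_k` called directly defaults to
(2, min(15, n−1)).

## Merge rule

For sub-categories A (k_A clusters) and B (k_B clusters), all k_A·k_B
cluster pairs get a Hausdorff distance (Euclidean point metric, full member
sets — the distance is a set distance, not a centroid distance). Distances
are bucketed into (−∞,10], (10,20], (20,30], (30,40], (40,∞): the printed
integer ranges are real intervals, half-open so no real value falls in a
gap, and a distance of exactly 10 belongs to the first bucket. The pair
merges when the first-bucket fraction is ≥ 0.80 (inclusive, "minimum
80%"). Merged pairs close into groups by connected components — the
closure rule implied by multi-way merged attributes. All pairs are
evaluated by default. Bucket edges and the threshold are config-exposed
because other TF-IDF conventions compress the distance scale.

The **direct baseline** (`direct_distance_baseline`) is the Hausdorff
distance between the *unclustered* full document sets. It is dominated by
each side's most atypical documents (boilerplate, junk), which is exactly
why the cluster-level route recovers pairs the direct threshold misses:
clustering quarantines atypical documents into a few clusters that spoil
only ~1/k of the cluster pairs.

Image-only records with structured metadata are folded in by
`metadata_as_subcategory`: field values are space-joined per case (in field
order) into pseudo-documents and processed identically thereafter.

## Attribute naming

Cascade per merge group: (1) if ≥ 2 members share a caption after
normalization (lowercase, punctuation stripped — so "Clinicalfindings" and
"findings" stay distinct), the most-shared caption wins; (2) otherwise each
member's top-25 term ranking is compared against the pooled group ranking
and the member with maximum coverage lends its caption. Coverage is
merged-relative: |member ∩ merged| / |merged| (a member-relative variant is
a one-line switch in `term_coverage` callers). Ties consult the coding
standard: the entity labels of the group's top-5 pooled terms are collected
and a tied caption matching an entity label wins; a remaining tie is a
uniform seeded choice. Every rule records its provenance
(`same_name`/`coverage`/`ontology`/`random`). The emitted schema lists one
attribute per group plus one source-qualified attribute per unmerged
sub-category; name collisions get numeric suffixes. Naming is deterministic
given (group, rankings, ontology, seed).

## Validation statistics

* `overlap_validation`: fraction of shared top-25 frequent terms between
  two sub-categories (pass ≥ 0.50). The denominator is capped by the
  smaller ranking so identical small corpora score 1.0.
* `case_term_coverage`: fraction of a case's *distinct* tokens found in the
  top-25 ranking (distinct, not total — the statistic asks whether the top
  terms describe the case, not how often); the sample mean over cases is
  judged relevant at ≥ 0.15, empty cases excluded with a warning.
* `merge_rate`: integer-rounded percentage (72 of 82 → 88).
* `sample_cases_for_review`: a seeded uniform case sample exported as JSONL
  for human relevance review; the YES/NO judgment itself is a human step.

Coding standards are read from 4-column TSV (term, pipe-separated synonyms,
definition, entity label). Ontology-coverage statistics computed against a
loaded coding standard apply to whatever dictionary is supplied; no
reference dictionary ships with the package.

## Synthetic data: what it emulates, and what it does not

`generate_corpus` emits several sources × several topics; each
(source, topic) sub-category's caption comes from an alias table mirroring
captions seen in real repositories (findings/observation/clinicalfindings,
history/indication/discussion, …), which exercises the naming cascade's
rule 2. Documents are built from:

* a topic **template phrase** shared across sources — token counts follow a
  decreasing Zipf-like rank-frequency pattern, and each topic has 6
  template variants differing in two variant-slot terms;
* a **source-private phrase** for the topic, sized so the shared share of
  topical tokens equals `shared_vocab_fraction` (default 0.7);
* 2–3 common filler tokens and per-document jitter (a token dropped or
  duplicated at rate 0.3).

Template-and-phrase construction, rather than i.i.d. token sampling, is the
package's model of formulaic clinical text. It is also what reproduces the
distance regime the method's fixed bucket edges assume: near-duplicate
same-topic documents land within 0–10 of their cross-source counterparts,
different topics land well above, boilerplate sits at 15–35, and nothing
exceeds ~50. I.i.d. sampling over realistic vocabularies cannot reach that
regime — rare-term draws carry idf ≈ 3–5 and push *every* pairwise distance
past the merge edge regardless of document length or pool sizes.

One source (`boilerplate_sources=(0,)`) emits boilerplate documents at
`outlier_rate` 0.08: a fixed per-source junk phrase standing in for
submission headers. These form a tight within-source cluster that is far
from everything else, so the merge rule survives them (~1/k of cluster
pairs affected) while the direct full-set baseline does not — the designed
contrast between the two routes.

Fields are dropped at `missing_rate` 0.05; document lengths land in the
upper teens of tokens (the `tokens_per_doc` midpoint sets the template
scale; per-document variation comes from jitter and filler counts, so the
realized spread is narrower than the nominal range). The `TruthMap` records
each sub-category's latent topic. Presets: `easy` (the defaults above),
`hard` (40% sharing, heavy filler noise), `no-merge` (no sharing — every
topical token is source-private).

What passing on synthetic data does **not** show: robustness to real
clinical language (abbreviations, negation scope, misspellings, section
cross-contamination), to vocabulary sizes in the thousands, or to sources
with non-aligned topic inventories. The generator's geometry is idealized;
on real corpora the bucket edges and the merge threshold are the knobs to
re-examine first.

## Numerical choices and degenerate inputs

* Hausdorff via a single `cdist` matrix: exact, O(|A||B|d); empty sets and
  dimension mismatches are errors.
* Bucket fractions use right-closed bins; they sum to 1 within 1e-9.
* Whitespace-only text counts as a missing field; documents that tokenize
  to nothing are dropped before vectorization; sub-categories that lose all
  documents are excluded from the pipeline.
* Duplicate case ids, malformed lines, wrong column counts: errors naming
  the offending id or line.
* Seeds: every stochastic step (tree cross-validation shuffling, naming
  tie-breaks, the generator) takes an explicit seed; pipeline runs are
  reproducible byte-for-byte given (corpus, config, seed).

## Known limitations

* The square-root criterion interacts with document sparsity: corpora whose
  every document carries most of the vocabulary never trigger it, and the
  selected k then drifts to the top of the candidate range (harmless for
  merging, which is insensitive to over-segmentation of homogeneous
  sub-categories, but the reported k is then a range artifact).
* Caption-level imputation cannot recover a missing section whose caption
  has no near-duplicate among the present ones.
* The naming cascade assumes captions are meaningful words; sources with
  opaque codes as captions will fall through to the seeded random rule.
* Distance buckets are tied to the TF-IDF convention; changing weighting or
  normalization requires re-calibrating the edges.
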