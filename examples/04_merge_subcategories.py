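"""Compare two sub-categories cluster-against-cluster with the Hausdorff
distance and apply the 80%-within-[0,10] merge rule.

Also shows the direct (unclustered) baseline: the full-set Hausdorff
distance is dominated by each side's most atypical documents, which is why
the cluster-level route merges pairs the direct threshold misses.
"""

import warnings

from casemerge import (
    ClusterAssignments,
    assemble_subcategories,
    bucket_distribution,
    build_tfidf,
    clean_text,
    default_scenarios,
    direct_distance_baseline,
    generate_corpus,
    hac_cluster,
    merge_decision,
    pairwise_cluster_distances,
    pooled_tfidf,
)

warnings.filterwarnings("ignore")

cases, truth = generate_corpus(default_scenarios()["easy"])
subs = {s.key: s for s in assemble_subcategories(cases)}
a, b = "src0/findings", "src1/observation"   # same topic, different captions
print(f"comparing {a} vs {b} (true topics: {truth[a]}, {truth[b]})")

tok = {
    key: [clean_text(text, case_id=cid) for cid, text in subs[key].documents]
    for key in (a, b)
}
space = pooled_tfidf(tok[a], tok[b], prefix_a=a, prefix_b=b)

k = 6
ca = ClusterAssignments.from_cluster_set(hac_cluster(build_tfidf(tok[a]), k, key=a), a)
cb = ClusterAssignments.from_cluster_set(hac_cluster(build_tfidf(tok[b]), k, key=b), b)
pdm = pairwise_cluster_distances(ca, cb, space)
print(f"{k} x {k} clusters -> {pdm.entries.size} cluster-pair distances")

buckets = bucket_distribution(pdm)
labels = ["0-10", "11-20", "21-30", "31-40", "41+"]
print("distance buckets:", {lab: round(f, 2) for lab, f in zip(labels, buckets)})

decision = merge_decision(pdm)
print(f"fraction within 0-10: {decision.in_range_fraction:.2f} "
      f"-> merged = {decision.merged} (threshold 0.80)")

direct = direct_distance_baseline(
    [f"{a}::{d.case_id}" for d in tok[a]],
    [f"{b}::{d.case_id}" for d in tok[b]],
    space,
)
print(f"direct full-set Hausdorff baseline: {direct:.1f} "
      f"({'would merge' if direct <= 10 else 'would NOT merge'} at cutoff 10)")
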