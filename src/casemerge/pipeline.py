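"""End-to-end categorize-and-merge pipeline.

From raw cases to an integrated schema:

1. assemble sub-categories (one per source/caption pair) and clean their
   texts;
2. per sub-category, build a TF-IDF matrix, choose the number of clusters and
   cut the Ward dendrogram;
3. per sub-category pair, re-vectorize both sides in a pooled TF-IDF space,
   compute all cluster-pair Hausdorff distances and apply the 80%-in-[0,10]
   merge rule (plus the unclustered direct-distance baseline);
4. close merged pairs into groups, name each group by the caption cascade
   and emit the schema.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from dataclasses import replace as dc_replace

from .cluster import ClusterSelectConfig, ClusterSet, KSelectionReport, hac_cluster, select_k, two_stage_cluster
from .io import ClinicalCase, CodingStandard, SubCategory, assemble_subcategories
from .merge import (
    DEFAULT_BUCKET_EDGES,
    DEFAULT_MERGE_THRESHOLD,
    ClusterAssignments,
    MergeDecision,
    MergeGroup,
    build_merge_groups,
    direct_distance_baseline,
    merge_decision,
    pairwise_cluster_distances,
)
from .naming import SchemaAttribute, assign_attribute_name, emit_schema, top_frequent_terms
from .evaluation import merge_rate
from .text import CleanConfig, TokenizedDoc, clean_text
from .vectorize import build_tfidf, pooled_tfidf


@dataclass(frozen=True)
class PipelineConfig:
    clean: CleanConfig = field(default_factory=CleanConfig)
    select: ClusterSelectConfig = field(default_factory=ClusterSelectConfig)
    fixed_k: int | None = None  # bypass selection with a fixed cluster count
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD
    bucket_edges: tuple[float, ...] = DEFAULT_BUCKET_EDGES
    top_n: int = 25
    seed: int = 0


@dataclass
class PipelineResult:
    subcategories: list[SubCategory]
    tokenized: dict[str, list[TokenizedDoc]]
    reports: dict[str, KSelectionReport]
    cluster_sets: dict[str, ClusterSet]
    decisions: list[MergeDecision]
    baselines: dict[tuple[str, str], float]
    groups: list[MergeGroup]
    unmerged: list[str]
    attributes: list[SchemaAttribute]
    schema: dict

    @property
    def keys(self) -> list[str]:
        return [s.key for s in self.subcategories]

    @property
    def merged_percentage(self) -> int:
        """Percentage of sub-categories absorbed into merge groups."""
        merged = sum(len(g.members) for g in self.groups)
        return merge_rate(merged, len(self.subcategories))

    @property
    def retained_percentage(self) -> int:
        """Final attribute count as a percentage of input sub-categories."""
        return merge_rate(len(self.groups) + len(self.unmerged), len(self.subcategories))

    def partition(self) -> dict[str, int]:
        """Sub-category key -> group id (singletons get their own ids)."""
        out: dict[str, int] = {}
        for gid, g in enumerate(self.groups):
            for k in g.members:
                out[k] = gid
        next_id = len(self.groups)
        for k in self.unmerged:
            out[k] = next_id
            next_id += 1
        return out


def run_pipeline(
    cases: list[ClinicalCase],
    config: PipelineConfig | None = None,
    coding_standard: CodingStandard | None = None,
) -> PipelineResult:
    """Run the full categorize-and-merge pipeline over a corpus."""
    config = config or PipelineConfig()
    subs = assemble_subcategories(cases)

    tokenized: dict[str, list[TokenizedDoc]] = {}
    kept: list[SubCategory] = []
    for sub in subs:
        docs = [
            clean_text(text, config.clean, case_id=case_id)
            for case_id, text in sub.documents
        ]
        docs = [d for d in docs if d.tokens]
        if docs:
            tokenized[sub.key] = docs
            kept.append(sub)
    subs = kept

    reports: dict[str, KSelectionReport] = {}
    cluster_sets: dict[str, ClusterSet] = {}
    for sub in subs:
        docs = tokenized[sub.key]
        matrix = build_tfidf(docs)
        if config.fixed_k is not None:
            k = max(1, min(config.fixed_k, len(docs)))
            reports[sub.key] = KSelectionReport(
                key=sub.key, scree={}, k_cart=k, k_sqrt=k,
                plateau=(k, k), k_final=k, agreed=True,
            )
        else:
            select = config.select
            if select.k_range is None:
                # size clusters to roughly ten documents each, so every
                # cluster's point set supports a stable Hausdorff estimate
                hi = min(15, max(2, -(-len(docs) // 10)))
                select = dc_replace(select, k_range=(2, min(hi, max(2, len(docs) - 1))))
            reports[sub.key] = select_k(matrix, select, key=sub.key)
            k = reports[sub.key].k_final
        if config.select.two_stage and k < len(docs):
            cluster_sets[sub.key] = two_stage_cluster(
                matrix, config.select.n_initial, k, key=sub.key
            )
        else:
            cluster_sets[sub.key] = hac_cluster(matrix, k, key=sub.key)

    decisions: list[MergeDecision] = []
    baselines: dict[tuple[str, str], float] = {}
    for sub_a, sub_b in itertools.combinations(subs, 2):
        ka, kb = sub_a.key, sub_b.key
        space = pooled_tfidf(tokenized[ka], tokenized[kb], prefix_a=ka, prefix_b=kb)
        ca = ClusterAssignments.from_cluster_set(cluster_sets[ka], prefix=ka)
        cb = ClusterAssignments.from_cluster_set(cluster_sets[kb], prefix=kb)
        pdm = pairwise_cluster_distances(ca, cb, space)
        decisions.append(merge_decision(pdm, config.merge_threshold, config.bucket_edges))
        baselines[(ka, kb)] = direct_distance_baseline(
            [f"{ka}::{d.case_id}" for d in tokenized[ka]],
            [f"{kb}::{d.case_id}" for d in tokenized[kb]],
            space,
        )

    groups, unmerged = build_merge_groups(decisions, all_keys=[s.key for s in subs])

    rankings = {
        key: top_frequent_terms(docs, config.top_n, owner=key)
        for key, docs in tokenized.items()
    }
    attributes: list[SchemaAttribute] = []
    for g in groups:
        pooled_docs = [d for key in sorted(g.members) for d in tokenized[key]]
        merged_ranking = top_frequent_terms(pooled_docs, config.top_n, owner="+".join(sorted(g.members)))
        attr = assign_attribute_name(
            g, rankings, merged_ranking, ontology=coding_standard, seed=config.seed
        )
        g.attribute_name = attr.name
        attributes.append(attr)
    schema = emit_schema(attributes, unmerged)

    return PipelineResult(
        subcategories=subs,
        tokenized=tokenized,
        reports=reports,
        cluster_sets=cluster_sets,
        decisions=decisions,
        baselines=baselines,
        groups=groups,
        unmerged=unmerged,
        attributes=attributes,
        schema=schema,
    )
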