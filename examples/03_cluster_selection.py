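"""Choose the number of clusters for one sub-category.

Three diagnostics run side by side: a decision-tree scree (how separable are
the clusters), the minimum square-root criterion (every cluster must keep
floor(sqrt(U)) unique terms), and the Ward dendrogram plateau.  Agreement is
declared when the square-root k lies inside the plateau.
"""

import warnings

from casemerge import (
    ClusterSelectConfig,
    assemble_subcategories,
    build_tfidf,
    clean_text,
    default_scenarios,
    generate_corpus,
    select_k,
    sqrt_threshold,
    unique_term_count,
)

warnings.filterwarnings("ignore")

cases, truth = generate_corpus(default_scenarios()["easy"])
sub = assemble_subcategories(cases)[0]
docs = [clean_text(text, case_id=cid) for cid, text in sub.documents]
matrix = build_tfidf(docs)

U = unique_term_count(docs)
print(f"sub-category {sub.key}: {len(docs)} documents, U = {U} unique terms")
print(f"minimum unique terms per cluster: floor(sqrt({U})) = {sqrt_threshold(U)}")
print(f"(for the reference corpus size of 1,404 terms the threshold is {sqrt_threshold(1404)})")

report = select_k(matrix, ClusterSelectConfig(k_range=(2, 8), seed=0), key=sub.key)
print("CART scree (k -> cross-validated accuracy):",
      {k: round(v, 2) for k, v in report.scree.items()})
print(f"k_cart = {report.k_cart}, k_sqrt = {report.k_sqrt}, plateau = {report.plateau}")
print(f"agreed = {report.agreed} -> k_final = {report.k_final}")
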