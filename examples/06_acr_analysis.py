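"""Classify accessible chromatin regions (ACRs) and their retention fates.

Distance classes follow the genic / proximal (<=2 kb) / distal (>2 kb)
convention; retention categories track whether the duplicated ACR copy
survived in the other subgenome.
"""

import pandas as pd

from subfrac.acr import assign_retention_category, category_counts, classify_acrs

genes = pd.DataFrame(
    {
        "gene_id": ["wgd_a", "single_b"],
        "chrom": ["c1", "c1"],
        "start": [10_000, 60_000],
        "end": [14_000, 64_000],
    }
)
acrs = pd.DataFrame(
    {
        "chrom": ["c1", "c1", "c1"],
        "start": [11_000, 8_200, 4_000],
        "end": [11_300, 8_500, 4_300],
        "acr_id": ["acr_g", "acr_p", "acr_d"],
        "score": [2.1, 1.4, 0.9],
    }
)
annotated = classify_acrs(acrs, genes)
for _, r in annotated.iterrows():
    print(
        f"{r['acr_id']}: {r['distance_class']:8s} "
        f"({r['distance']:.0f} bp from {r['nearest_gene']})"
    )

homology = pd.DataFrame(
    {
        "maize_acr": ["acr_g", "acr_p", "acr_d"],
        "subgenome": ["maize1", "maize1", "maize2"],
        "partner_acr": ["acr_x", None, None],
        "sorghum_acr": ["sb1", "sb2", "sb3"],
    }
)
status = pd.Series({"wgd_a": "pair", "single_b": "singleton_m1"})
annotated["retention_category"] = assign_retention_category(annotated, homology, status)
print("retention categories:", category_counts(annotated["retention_category"]))

# Category 1 = both ACR copies retained near a WGD pair; 2/3 = only the
# maize1/maize2 copy retained near WGD genes; 4/5 = the same near singletons.
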