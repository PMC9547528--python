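"""Accessible chromatin region (ACR) classification and retention analysis.

ACRs are classified by edge distance to their nearest annotated gene:
genic (overlap), proximal (within 2 kb, inclusive), distal (beyond 2 kb).
Retention is quantified two ways: the ratio of ACRs near singleton genes to
ACRs near WGD (retained-pair) genes per subgenome, and — for ACRs with
outgroup-syntenic support — five categories from the fate of the duplicated
ACR copy: (1) both copies retained near WGD genes, (2)/(3) only the
subgenome-1 / subgenome-2 copy retained near WGD genes, (4)/(5) the same
near singleton genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .partition import GenomePartition
from .stats import TestResult, unpaired_t

GENIC = "genic"
PROXIMAL = "proximal"
DISTAL = "distal"
PROXIMAL_MAX = 2000  # "within 2 kb" read as inclusive


def _distance_class(distance: float) -> str:
    if distance == 0:
        return GENIC
    if distance <= PROXIMAL_MAX:
        return PROXIMAL
    return DISTAL


def classify_acrs(acrs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate each ACR with its nearest gene, edge distance and class.

    ``genes`` carries gene_id/chrom/start/end.  ACRs on chromosomes without
    any gene are classed distal with a missing nearest gene (with a warning).
    """
    by_chrom = {
        c: g.sort_values("start").reset_index(drop=True) for c, g in genes.groupby("chrom")
    }
    nearest, dist, cls = [], [], []
    orphan_chroms = set()
    for chrom, a_start, a_end in zip(acrs["chrom"], acrs["start"], acrs["end"]):
        g = by_chrom.get(chrom)
        if g is None or len(g) == 0:
            orphan_chroms.add(chrom)
            nearest.append(None)
            dist.append(np.nan)
            cls.append(DISTAL)
            continue
        starts = g["start"].to_numpy(dtype=float)
        ends = g["end"].to_numpy(dtype=float)
        d = np.maximum(np.maximum(starts - a_end, a_start - ends), 0.0)
        i = int(np.argmin(d))
        nearest.append(g["gene_id"].iloc[i])
        dist.append(float(d[i]))
        cls.append(_distance_class(float(d[i])))
    if orphan_chroms:
        warnings.warn(f"no genes on chromosomes {sorted(orphan_chroms)}; ACRs classed distal")
    out = acrs.copy()
    out["nearest_gene"] = nearest
    out["distance"] = dist
    out["distance_class"] = cls
    return out


def acr_retention_ratio(
    acrs: pd.DataFrame, gene_status: pd.Series, subgenome_of_gene: pd.Series, subgenome: str
) -> tuple[int, int, float]:
    """(n near singletons, n near WGD genes, 1-decimal ratio) for a subgenome.

    ``gene_status`` maps gene id -> pair/singleton_m1/singleton_m2 (genes
    absent from the map — no outgroup syntelog — exclude their ACRs).
    """
    singleton_status = {"maize1": "singleton_m1", "maize2": "singleton_m2"}[subgenome]
    n_singleton = n_wgd = 0
    for gene in acrs["nearest_gene"]:
        if gene is None or gene not in gene_status.index:
            continue
        if subgenome_of_gene.get(gene) != subgenome:
            continue
        status = gene_status[gene]
        if status == "pair":
            n_wgd += 1
        elif status == singleton_status:
            n_singleton += 1
    ratio = round(n_singleton / n_wgd, 1) if n_wgd else float("nan")
    return n_singleton, n_wgd, ratio


def assign_retention_category(
    acrs: pd.DataFrame, homology: pd.DataFrame, gene_status: pd.Series
) -> pd.Series:
    """Five-way retention category for syntenic ACRs.

    ``homology`` columns: maize_acr, subgenome (of the ACR), partner_acr
    (the homoeologous ACR in the other subgenome, nullable), sorghum_acr
    (outgroup syntenic ACR, nullable).  Only ACRs with a sorghum syntenic ACR
    are categorised.  Near-WGD ACRs: category 1 when both copies are
    retained, 2 when only the subgenome-1 copy survives, 3 when only the
    subgenome-2 copy survives; near-singleton ACRs: categories 4 and 5
    analogously.  Everything else is <NA>.
    """
    hom = homology.set_index("maize_acr")
    cats = pd.Series(pd.NA, index=acrs.index, dtype="object")
    unknown = 0
    for idx, (acr_id, gene) in enumerate(zip(acrs["acr_id"], acrs["nearest_gene"])):
        if acr_id not in hom.index:
            unknown += 1
            continue
        rec = hom.loc[acr_id]
        if pd.isna(rec["sorghum_acr"]):
            continue  # not syntenic with the outgroup
        if gene is None or gene not in gene_status.index:
            continue
        status = gene_status[gene]
        has_partner = pd.notna(rec["partner_acr"])
        sub = rec["subgenome"]
        if status == "pair":
            if has_partner:
                cat = 1
            else:
                cat = 2 if sub == "maize1" else 3
        elif status in ("singleton_m1", "singleton_m2"):
            if has_partner:
                continue  # partner ACR near a lost gene is inconsistent input
            cat = 4 if sub == "maize1" else 5
        else:
            continue
        cats.iloc[idx] = cat
    if unknown:
        warnings.warn(f"{unknown} ACRs absent from the homology table; category NA")
    return cats.rename("retention_category")


def category_counts(categories: pd.Series) -> dict[int, int]:
    counts = categories.value_counts()
    return {k: int(counts.get(k, 0)) for k in (1, 2, 3, 4, 5)}


def accessibility_compare(
    acrs: pd.DataFrame, group_col: str = "group", score_col: str = "score"
) -> pd.DataFrame:
    """Mean/median accessibility per group plus pairwise two-sample t-tests.

    Groups with fewer than two members yield NA summary rows and are left out
    of the tests.
    """
    rows = []
    groups = {}
    for name, g in acrs.groupby(group_col):
        scores = g[score_col].to_numpy(dtype=float)
        if scores.size < 2:
            rows.append(
                {group_col: name, "n": scores.size, "mean": np.nan, "median": np.nan}
            )
            continue
        groups[name] = scores
        rows.append(
            {
                group_col: name,
                "n": scores.size,
                "mean": float(scores.mean()),
                "median": float(np.median(scores)),
            }
        )
    summary = pd.DataFrame(rows)
    tests = []
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res: TestResult = unpaired_t(groups[a], groups[b])
            tests.append(
                {
                    "group1": a,
                    "group2": b,
                    "difference": float(groups[a].mean() - groups[b].mean()),
                    "t": res.statistic,
                    "pvalue": res.pvalue,
                }
            )
    summary.attrs["tests"] = pd.DataFrame(tests)
    return summary


def loop_region_counts(
    loops: pd.DataFrame,
    partitions: dict[str, GenomePartition],
    subgenome_of_chrom: dict[str, str],
) -> pd.DataFrame:
    """Count chromatin loops per subgenome x region by anchor midpoints.

    Loops whose anchors fall in different (subgenome, region) combinations
    are tallied under "mixed"; anchors on unknown chromosomes skip the loop
    with a warning.
    """
    counts: dict[tuple[str, str], int] = {
        (sub, reg): 0
        for sub in sorted(set(subgenome_of_chrom.values()))
        for reg in ("arm", "peri")
    }
    mixed = 0
    skipped = 0
    for _, row in loops.iterrows():
        labels = []
        ok = True
        for c_col, s_col, e_col in (("chrom1", "start1", "end1"), ("chrom2", "start2", "end2")):
            chrom = row[c_col]
            if chrom not in partitions or chrom not in subgenome_of_chrom:
                ok = False
                break
            part = partitions[chrom]
            mid = (row[s_col] + row[e_col]) / 2.0
            if not (0 <= mid < part.length):
                ok = False
                break
            labels.append((subgenome_of_chrom[chrom], part.classify(row[s_col], row[e_col])))
        if not ok:
            skipped += 1
            continue
        if labels[0] == labels[1]:
            counts[labels[0]] += 1
        else:
            mixed += 1
    if skipped:
        warnings.warn(f"skipped {skipped} loops with anchors off known chromosomes")
    rows = [
        {"subgenome": sub, "region": reg, "n_loops": n}
        for (sub, reg), n in sorted(counts.items())
    ]
    rows.append({"subgenome": "mixed", "region": "mixed", "n_loops": mixed})
    return pd.DataFrame(rows)
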