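"""Syntelog filtering, retention bookkeeping and duplicated-block statistics.

The homoeolog table has one row per ancestral (outgroup-anchored) gene with
nullable subgenome-1 / subgenome-2 gene ids.  Rows are classified as retained
pairs (both copies present, "WGD genes") or singletons (one copy lost).
Retained pairs fall into four chromatin-environment categories from the
arm/peri location of each copy.  Blocks are maximal runs of syntelogs, in
ancestral gene order, that share the same chromosome pairing between the two
subgenomes; per-block retention follows

    retention_1 = (singletons_1 + WGD) / (singletons_1 + singletons_2 + WGD)

and symmetrically for side 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .partition import GenomePartition, classify_frame

PAIR = "pair"
SINGLETON_M1 = "singleton_m1"
SINGLETON_M2 = "singleton_m2"

CATEGORIES = ("M1arm_M2arm", "M1peri_M2peri", "M1arm_M2peri", "M1peri_M2arm")


def derive_status(table: pd.DataFrame) -> pd.Series:
    """pair / singleton_m1 / singleton_m2 from gene-id nullity."""
    has1 = table["maize1_gene"].notna()
    has2 = table["maize2_gene"].notna()
    if (~has1 & ~has2).any():
        raise ValueError("row with neither subgenome copy present")
    status = np.where(has1 & has2, PAIR, np.where(has1, SINGLETON_M1, SINGLETON_M2))
    return pd.Series(status, index=table.index, name="status")


def filter_syntelogs(
    raw: pd.DataFrame, ks_min: float = 0.05, omega_max: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop tandem duplicates and outgroup comparisons outside the Ks/omega gates.

    A row is removed when its tandem flag is set, when any retained copy's Ks
    against the outgroup is below ``ks_min`` (too recent to be a WGD-derived
    syntelog), or when any retained copy's omega exceeds ``omega_max``
    (implausible Ka/Ks, likely mis-annotation).  Retained copies with missing
    Ks or omega reject the row as "incomplete".

    Expected columns: maize1_gene, maize2_gene (nullable), tandem, and
    per-copy outgroup statistics ks_m1/omega_m1/ks_m2/omega_m2.

    Returns (filtered table with a ``status`` column, removal log with
    ``reason`` per dropped row).
    """
    reasons = pd.Series("", index=raw.index, dtype=object)
    has1 = raw["maize1_gene"].notna()
    has2 = raw["maize2_gene"].notna()

    incomplete = (
        (has1 & (raw["ks_m1"].isna() | raw["omega_m1"].isna()))
        | (has2 & (raw["ks_m2"].isna() | raw["omega_m2"].isna()))
    )
    ks_bad = (has1 & (raw["ks_m1"] < ks_min)) | (has2 & (raw["ks_m2"] < ks_min))
    om_bad = (has1 & (raw["omega_m1"] > omega_max)) | (has2 & (raw["omega_m2"] > omega_max))

    # reason precedence: tandem removal happens before the Ks/omega gates
    reasons[om_bad] = "omega_max"
    reasons[ks_bad] = "ks_min"
    reasons[incomplete] = "incomplete"
    reasons[raw["tandem"].astype(bool)] = "tandem"

    removed = reasons != ""
    log = raw.loc[removed].copy()
    log["reason"] = reasons[removed]
    kept = raw.loc[~removed].copy()
    kept["status"] = derive_status(kept)
    return kept, log


def assign_category(region_m1: str, region_m2: str) -> str:
    """Chromatin-environment category of a retained pair."""
    key = (region_m1, region_m2)
    mapping = {
        ("arm", "arm"): "M1arm_M2arm",
        ("peri", "peri"): "M1peri_M2peri",
        ("arm", "peri"): "M1arm_M2peri",
        ("peri", "arm"): "M1peri_M2arm",
    }
    if key not in mapping:
        raise ValueError(f"unknown region pair {key}")
    return mapping[key]


def annotate_regions(
    table: pd.DataFrame,
    genes: pd.DataFrame,
    partitions: dict[str, GenomePartition],
) -> pd.DataFrame:
    """Attach per-copy coordinates, arm/peri class, and the pair category.

    ``genes`` is a frame indexed by gene id with chrom/start/end/strand.
    """
    out = table.copy()
    for side in ("m1", "m2"):
        col = f"maize{side[1]}_gene"
        present = out[col].notna()
        ids = out.loc[present, col]
        sub = genes.loc[ids]
        for field in ("chrom", "start", "end", "strand"):
            out.loc[present, f"{side}_{field}"] = sub[field].to_numpy()
        coords = out.loc[present, [f"{side}_chrom", f"{side}_start", f"{side}_end"]]
        coords.columns = ["chrom", "start", "end"]
        out.loc[present, f"region_{side}"] = classify_frame(coords, partitions).to_numpy()
    pairs = out["status"] == PAIR
    out.loc[pairs, "category"] = [
        assign_category(r1, r2)
        for r1, r2 in zip(out.loc[pairs, "region_m1"], out.loc[pairs, "region_m2"])
    ]
    return out


def singleton_wgd_ratio(
    table: pd.DataFrame, subgenome: str, region: str | None = None
) -> tuple[int, int, float]:
    """Singleton:WGD counts and 1-decimal ratio for one subgenome.

    Singletons of subgenome k are rows where only the subgenome-k copy
    survives; WGD genes are that subgenome's members of retained pairs.
    ``region`` (arm/peri) restricts both counts by the location of the
    subgenome-k copy.  Ratio is NaN when there are no WGD genes.
    """
    if subgenome not in ("maize1", "maize2"):
        raise ValueError(f"unknown subgenome {subgenome!r}")
    side = "m1" if subgenome == "maize1" else "m2"
    singleton_status = SINGLETON_M1 if side == "m1" else SINGLETON_M2
    rows = table
    if region is not None:
        rows = rows[rows[f"region_{side}"] == region]
    n_singleton = int((rows["status"] == singleton_status).sum())
    n_wgd = int((rows["status"] == PAIR).sum())
    ratio = round(n_singleton / n_wgd, 1) if n_wgd else float("nan")
    return n_singleton, n_wgd, ratio


def retention_rate(n_singleton_own: int, n_singleton_other: int, n_wgd: int) -> float:
    """Fraction of a block's ancestral genes still present on one side."""
    denom = n_singleton_own + n_singleton_other + n_wgd
    if denom == 0:
        return float("nan")
    return (n_singleton_own + n_wgd) / denom


def build_blocks(
    table: pd.DataFrame, min_genes: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the (ancestral-ordered) homoeolog table into duplicated blocks.

    A block is a maximal run of consecutive rows whose non-null subgenome
    chromosomes agree on a single (m1_chrom, m2_chrom) pairing; singleton rows
    extend the run of the pairing they are compatible with.  Blocks with fewer
    than ``min_genes`` genes on either side are dropped.

    Requires region/coordinate annotation (:func:`annotate_regions`).  Returns
    (table with a ``block_id`` column (NaN outside kept blocks), block summary
    frame).
    """
    m1c = table["m1_chrom"].to_numpy(dtype=object)
    m2c = table["m2_chrom"].to_numpy(dtype=object)
    n = len(table)
    run_ids = np.full(n, -1)
    run = -1
    cur1 = cur2 = None
    for i in range(n):
        r1 = m1c[i] if isinstance(m1c[i], str) else None
        r2 = m2c[i] if isinstance(m2c[i], str) else None
        conflict = (r1 is not None and cur1 is not None and r1 != cur1) or (
            r2 is not None and cur2 is not None and r2 != cur2
        )
        if run < 0 or conflict:
            run += 1
            cur1, cur2 = r1, r2
        else:
            cur1 = cur1 or r1
            cur2 = cur2 or r2
        run_ids[i] = run

    out = table.copy()
    out["_run"] = run_ids
    blocks = []
    block_id = 0
    out["block_id"] = np.nan
    for run, grp in out.groupby("_run", sort=True):
        n_pairs = int((grp["status"] == PAIR).sum())
        n_s1 = int((grp["status"] == SINGLETON_M1).sum())
        n_s2 = int((grp["status"] == SINGLETON_M2).sum())
        side1 = n_pairs + n_s1
        side2 = n_pairs + n_s2
        if min(side1, side2) < min_genes:
            continue
        rec = {
            "block_id": block_id,
            "n_pairs": n_pairs,
            "n_singleton_m1": n_s1,
            "n_singleton_m2": n_s2,
            "m1_genes": side1,
            "m2_genes": side2,
            "retention_m1": retention_rate(n_s1, n_s2, n_pairs),
            "retention_m2": retention_rate(n_s2, n_s1, n_pairs),
        }
        for side in ("m1", "m2"):
            present = grp[f"{side}_chrom"].notna()
            sub = grp.loc[present]
            rec[f"{side}_chrom"] = sub[f"{side}_chrom"].iloc[0] if len(sub) else None
            rec[f"{side}_start"] = float(sub[f"{side}_start"].min()) if len(sub) else np.nan
            rec[f"{side}_end"] = float(sub[f"{side}_end"].max()) if len(sub) else np.nan
            regions = sub[f"region_{side}"]
            rec[f"{side}_region"] = (
                regions.mode().iloc[0] if len(regions) else None
            )  # majority environment of member genes
        rec["env_pair"] = f"M1{rec['m1_region']}_M2{rec['m2_region']}"
        out.loc[grp.index, "block_id"] = block_id
        blocks.append(rec)
        block_id += 1
    out = out.drop(columns="_run")
    return out, pd.DataFrame(blocks)


def block_stats(
    blocks: pd.DataFrame,
    table: pd.DataFrame,
    tes: pd.DataFrame,
    recomb_maps: dict | None = None,
) -> pd.DataFrame:
    """Fill per-block size, gene density, TE content and recombination columns.

    TE megabases are summed overlap of TE intervals (``tes``: chrom, start,
    end, te_class) with each block side's span, total and per TE class.
    Recombination is the mean map rate at the positions of the block's WGD
    (paired) member genes, per side — singletons are excluded from that
    comparison.
    """
    out = blocks.copy()
    te_classes = sorted(tes["te_class"].unique()) if len(tes) else []
    te_by_chrom = {c: g for c, g in tes.groupby("chrom")} if len(tes) else {}
    for side in ("m1", "m2"):
        sizes, densities, te_mb, recomb = [], [], [], []
        te_mb_class: dict[str, list] = {cls: [] for cls in te_classes}
        for _, b in out.iterrows():
            span = (b[f"{side}_start"], b[f"{side}_end"])
            size_mb = (span[1] - span[0]) / 1e6
            sizes.append(size_mb)
            densities.append(b[f"{side}_genes"] / size_mb if size_mb > 0 else np.nan)
            g = te_by_chrom.get(b[f"{side}_chrom"])
            if g is None:
                te_mb.append(0.0)
                for cls in te_classes:
                    te_mb_class[cls].append(0.0)
            else:
                ov = np.minimum(g["end"].to_numpy(), span[1]) - np.maximum(
                    g["start"].to_numpy(), span[0]
                )
                ov = np.clip(ov, 0, None)
                te_mb.append(float(ov.sum()) / 1e6)
                for cls in te_classes:
                    mask = (g["te_class"] == cls).to_numpy()
                    te_mb_class[cls].append(float(ov[mask].sum()) / 1e6)
            if recomb_maps is None:
                recomb.append(np.nan)
            else:
                members = table[
                    (table["block_id"] == b["block_id"]) & (table["status"] == PAIR)
                ]
                rmap = recomb_maps.get(b[f"{side}_chrom"])
                if rmap is None or not len(members):
                    recomb.append(np.nan)
                else:
                    mids = (
                        members[f"{side}_start"].to_numpy()
                        + members[f"{side}_end"].to_numpy()
                    ) / 2.0
                    recomb.append(float(np.mean(rmap.rate_at(mids))))
        out[f"{side}_size_mb"] = sizes
        out[f"{side}_gene_density"] = densities
        out[f"{side}_te_mb"] = te_mb
        for cls in te_classes:
            out[f"{side}_te_mb_{cls}"] = te_mb_class[cls]
        out[f"{side}_recomb"] = recomb
    return out
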