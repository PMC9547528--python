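"""End-to-end pipeline orchestration and table-style reporting.

``run_pipeline`` consumes a dataset directory (synthetic or real data laid
out the same way), runs partition -> syntelog filtering -> block building ->
molecular evolution -> dominance -> profiles -> ACR analysis, writes
machine-readable TSV/JSON outputs, and returns a nested summary dict.

``build_report`` assembles the duplicated-block comparison table: for every
block environment class (both sides in arms, both in pericentromeres, and
the two mixed classes) it reports block counts, singleton-vs-WGD contingency
tests, and paired per-block comparisons (gene counts, block sizes, gene
densities, retention rates, TE content by class, recombination) between the
two subgenomes.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import acr as acr_mod
from . import dominance as dom_mod
from . import fractionation as frac_mod
from . import io
from . import molevol
from . import partition as part_mod
from . import profiles as prof_mod
from .stats import chi_square, paired_t

BLOCK_STATS = [
    ("n_genes", "m1_genes", "m2_genes"),
    ("block_size_mb", "m1_size_mb", "m2_size_mb"),
    ("gene_density", "m1_gene_density", "m2_gene_density"),
    ("retention_rate", "retention_m1", "retention_m2"),
    ("te_mb", "m1_te_mb", "m2_te_mb"),
    ("te_mb_LTR", "m1_te_mb_LTR", "m2_te_mb_LTR"),
    ("te_mb_DNA", "m1_te_mb_DNA", "m2_te_mb_DNA"),
    ("recombination", "m1_recomb", "m2_recomb"),
]


def build_report(table: pd.DataFrame, blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-environment-class block comparison rows (means +- SD, test, P)."""
    rows = []
    for env, grp in blocks.groupby("env_pair"):
        rows.append(
            {
                "env_pair": env,
                "statistic": "n_blocks",
                "maize1": len(grp),
                "maize2": len(grp),
                "test": "",
                "pvalue": np.nan,
            }
        )
        s1 = int(grp["n_singleton_m1"].sum())
        s2 = int(grp["n_singleton_m2"].sum())
        w = int(grp["n_pairs"].sum())
        rec = {
            "env_pair": env,
            "statistic": "singletons_vs_wgd",
            "maize1": f"{s1} vs {w}",
            "maize2": f"{s2} vs {w}",
            "test": "chi2",
            "pvalue": np.nan,
        }
        try:
            rec["pvalue"] = chi_square([[s1, w], [s2, w]]).pvalue
        except ValueError:
            pass
        rows.append(rec)
        for name, c1, c2 in BLOCK_STATS:
            if c1 not in grp.columns or c2 not in grp.columns:
                continue
            x = grp[c1].to_numpy(dtype=float)
            y = grp[c2].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            rec = {
                "env_pair": env,
                "statistic": name,
                "maize1": f"{np.nanmean(x):.3f} ± {np.nanstd(x, ddof=1) if ok.sum() > 1 else 0:.3f}",
                "maize2": f"{np.nanmean(y):.3f} ± {np.nanstd(y, ddof=1) if ok.sum() > 1 else 0:.3f}",
                "test": "paired_t",
                "pvalue": np.nan,
            }
            if ok.sum() >= 2:
                rec["pvalue"] = paired_t(x[ok], y[ok]).pvalue
            rows.append(rec)
    return pd.DataFrame(rows)


def _load_dataset(data_dir: Path) -> dict:
    d = {}
    d["genes"] = io.read_gff3(data_dir / "genes.gff3")
    d["tes"] = io.read_bed(data_dir / "tes.bed").rename(columns={"name": "te_class"})
    d["markers"] = io.read_tsv(data_dir / "markers.tsv")
    d["centromeres"] = io.read_tsv(data_dir / "centromeres.tsv")
    d["syntelogs"] = io.read_tsv(data_dir / "syntelogs.tsv", index_col=0)
    d["cds_sorghum"] = io.read_fasta(data_dir / "cds_sorghum.fasta")
    d["cds_maize"] = io.read_fasta(data_dir / "cds_maize.fasta")
    d["fpkm"] = io.read_matrix(data_dir / "expression_fpkm.tsv")
    d["protein"] = io.read_matrix(data_dir / "protein_abundance.tsv")
    d["sirna"] = io.read_sirna_track(data_dir / "tracks" / "sirna.tsv")
    d["methylation"] = io.read_methylation_track(data_dir / "tracks" / "methylation.tsv")
    d["histone"] = io.read_histone_track(data_dir / "tracks" / "histone.tsv")
    d["acrs"] = io.read_bed(
        data_dir / "acrs.bed",
        names=("chrom", "start", "end", "acr_id", "score", "subgenome"),
    )
    d["acr_homology"] = io.read_tsv(data_dir / "acr_homology.tsv")
    d["acr_seq_maize"] = io.read_fasta(data_dir / "acr_seqs_maize.fasta")
    d["acr_seq_sorghum"] = io.read_fasta(data_dir / "acr_seqs_sorghum.fasta")
    d["loops"] = io.read_bedpe(data_dir / "loops.bedpe")
    d["snps"] = io.read_tsv(data_dir / "snps.tsv")
    return d


def _build_partitions(data) -> dict[str, part_mod.GenomePartition]:
    partitions = {}
    cen = data["centromeres"].set_index("chrom")
    maps = {
        chrom: part_mod.RecombinationMap(g["bp"].to_numpy(), g["cM"].to_numpy())
        for chrom, g in data["markers"].groupby("chrom")
    }
    data["recomb_maps"] = maps
    for chrom, genes_c in data["genes"].groupby("chrom"):
        length = int(data["markers"][data["markers"]["chrom"] == chrom]["bp"].max())
        tes_c = data["tes"][data["tes"]["chrom"] == chrom]
        track = part_mod.window_stats(
            genes_c["start"].to_numpy(),
            tes_c[["start", "end"]].to_numpy(),
            length,
            recomb_map=maps.get(chrom),
            chrom=chrom,
        )
        partitions[chrom] = part_mod.segment(
            track, tuple(cen.loc[chrom, ["start", "end"]]), chrom_length=length
        )
    return partitions


def _profile_summary(profile: prof_mod.MetaProfile, step: int) -> dict:
    up_i = int(np.argmax(profile.upstream))
    down_i = int(np.argmax(profile.downstream))
    return {
        # offset of the window centre relative to TSS (upstream, negative
        # towards the flank) / TTS (downstream)
        "upstream_peak_offset": -(prof_mod.FLANK - up_i * step - profile.window / 2),
        "downstream_peak_offset": down_i * step + profile.window / 2,
        "upstream_peak": float(np.max(profile.upstream)),
        "downstream_peak": float(np.max(profile.downstream)),
        "upstream_mean": float(np.mean(profile.upstream)),
        "downstream_mean": float(np.mean(profile.downstream)),
    }


def run_pipeline(
    data_dir,
    out_dir,
    ks_min: float = 0.05,
    omega_max: float = 2.0,
    min_block_genes: int = 5,
    with_profiles: bool = True,
) -> dict:
    """Run every stage on a dataset directory and write reports to out_dir."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {}

    t0 = time.perf_counter()
    data = _load_dataset(data_dir)
    timings["load"] = time.perf_counter() - t0

    # ---- partition ------------------------------------------------------
    t0 = time.perf_counter()
    partitions = _build_partitions(data)
    io.write_tsv(part_mod.partitions_to_bed(partitions), out_dir / "partition.bed")
    summary["partition"] = {
        chrom: {"peri": list(p.peri), "length": p.length} for chrom, p in partitions.items()
    }
    timings["partition"] = time.perf_counter() - t0

    # ---- outgroup distances + syntelog filtering ------------------------
    t0 = time.perf_counter()
    raw = data["syntelogs"].copy()
    seqs = {**data["cds_maize"], **data["cds_sorghum"]}
    for side, col in (("m1", "maize1_gene"), ("m2", "maize2_gene")):
        present = raw[col].notna()
        pairs = pd.DataFrame(
            {"gene1": raw.loc[present, col], "gene2": raw.loc[present, "sorghum_gene"]}
        )
        dist = molevol.batch_ng86(pairs, seqs)
        raw.loc[present, f"ks_{side}"] = dist["ks"].to_numpy()
        raw.loc[present, f"omega_{side}"] = dist["omega"].to_numpy()
    table, removal_log = frac_mod.filter_syntelogs(raw, ks_min=ks_min, omega_max=omega_max)
    genes_ix = data["genes"].set_index("gene_id")
    table = frac_mod.annotate_regions(table, genes_ix, partitions)
    io.write_tsv(removal_log, out_dir / "syntelog_removals.tsv")
    summary["filter"] = {
        "n_input": int(len(raw)),
        "n_kept": int(len(table)),
        "removal_reasons": removal_log["reason"].value_counts().to_dict(),
    }
    ratios = {}
    for sub in ("maize1", "maize2"):
        for reg in ("arm", "peri"):
            ns, nw, ratio = frac_mod.singleton_wgd_ratio(table, sub, reg)
            ratios[f"{sub}_{reg}"] = {"singletons": ns, "wgd": nw, "ratio": ratio}
    summary["singleton_wgd_ratios"] = ratios
    timings["fractionation"] = time.perf_counter() - t0

    # ---- blocks ----------------------------------------------------------
    t0 = time.perf_counter()
    table, blocks = frac_mod.build_blocks(table, min_genes=min_block_genes)
    blocks = frac_mod.block_stats(blocks, table, data["tes"], data["recomb_maps"])
    io.write_tsv(table, out_dir / "syntelogs_annotated.tsv")
    io.write_tsv(blocks, out_dir / "blocks.tsv")
    report = build_report(table, blocks)
    io.write_tsv(report, out_dir / "block_report.tsv")
    summary["blocks"] = {
        "n_blocks": int(len(blocks)),
        "by_env": blocks["env_pair"].value_counts().to_dict() if len(blocks) else {},
    }
    timings["blocks"] = time.perf_counter() - t0

    # ---- homoeolog molecular evolution ----------------------------------
    t0 = time.perf_counter()
    pairs = table[table["status"] == frac_mod.PAIR].copy()
    evo = {}
    for sub, col in (("maize1", "maize1_gene"), ("maize2", "maize2_gene")):
        p = pd.DataFrame({"gene1": pairs[col], "gene2": pairs["sorghum_gene"]})
        d = molevol.batch_ng86(p, seqs)
        pairs[f"ka_{sub}"] = d["ka"].to_numpy()
        pairs[f"ks_{sub}"] = d["ks"].to_numpy()
        pairs[f"omega_{sub}"] = d["omega"].to_numpy()
    for cat, grp in pairs.groupby("category"):
        ok = grp[["ka_maize1", "ka_maize2"]].notna().all(axis=1)
        g = grp[ok]
        if len(g) < 2:
            continue
        evo[cat] = {
            "n_pairs": int(len(g)),
            "mean_ka_maize1": float(g["ka_maize1"].mean()),
            "mean_ka_maize2": float(g["ka_maize2"].mean()),
            "mean_ks_maize1": float(g["ks_maize1"].mean()),
            "mean_ks_maize2": float(g["ks_maize2"].mean()),
            "ka_pvalue": paired_t(g["ka_maize1"], g["ka_maize2"]).pvalue,
            "ks_pvalue": paired_t(g["ks_maize1"], g["ks_maize2"]).pvalue,
        }
    io.write_tsv(pairs, out_dir / "pair_distances.tsv")
    summary["evolution"] = evo
    timings["molevol"] = time.perf_counter() - t0

    # ---- genetic load ----------------------------------------------------
    t0 = time.perf_counter()
    snps = data["snps"]
    ind_cols = [c for c in snps.columns if c.startswith("ind_")]
    loads = {}
    if ind_cols and len(snps):
        deleterious = (snps["snp_class"] == "nonsyn") & (snps["gerp"] > 0)
        per_gene = (
            snps.loc[deleterious]
            .groupby("gene_id")[ind_cols]
            .sum()
            .mean(axis=1)
        )
        gene_lengths = genes_ix["end"] - genes_ix["start"]
        gene_meta = genes_ix.loc[
            genes_ix.index.intersection(per_gene.index), ["subgenome"]
        ].copy()
        gene_meta["load"] = per_gene / gene_lengths
        gene_meta["region"] = part_mod.classify_frame(
            genes_ix.loc[gene_meta.index], partitions
        )
        for (sub, reg), grp in gene_meta.groupby(["subgenome", "region"]):
            loads[f"{sub}_{reg}"] = float(grp["load"].mean())
    summary["genetic_load"] = loads
    timings["load_stats"] = time.perf_counter() - t0

    # ---- dominance -------------------------------------------------------
    t0 = time.perf_counter()
    dom = dom_mod.dominance_summary(data["fpkm"], pairs)
    io.write_tsv(dom, out_dir / "dominance_summary.tsv")
    dom_means = dom[dom["tissue"] == "__mean__"].set_index("category")
    summary["dominance"] = {
        cat: {
            "pct_maize1": float(r["pct_maize1"]),
            "pct_maize2": float(r["pct_maize2"]),
            "n_pairs": int(r["n_pairs"]),
        }
        for cat, r in dom_means.iterrows()
    }
    expr_cmp = {}
    for cat, grp in pairs.groupby("category"):
        if len(grp) >= 2:
            expr_cmp[cat] = dom_mod.mean_expression_compare(data["fpkm"], grp)
    summary["mean_expression"] = expr_cmp
    timings["dominance"] = time.perf_counter() - t0

    # ---- profiles --------------------------------------------------------
    t0 = time.perf_counter()
    if with_profiles:
        prof = {}
        arm_pairs = pairs[pairs["category"] == "M1arm_M2arm"]
        for sub, col in (("maize1", "maize1_gene"), ("maize2", "maize2_gene")):
            gset = genes_ix.loc[arm_pairs[col]].reset_index().rename(
                columns={"index": "gene_id"}
            )
            if len(gset) == 0:
                continue
            sp = prof_mod.sirna_profile(data["sirna"], gset)
            mp = prof_mod.methylation_profile(data["methylation"], gset, context="CHH")
            hp = prof_mod.histone_profile(data["histone"], data["histone"], gset)
            prof[sub] = {
                "sirna": _profile_summary(sp, step=10),
                "chh": _profile_summary(mp, step=50),
                "histone_body_mean": float(np.mean(hp.body)),
            }
            sp.to_frame().to_csv(out_dir / f"profile_sirna_{sub}.tsv", sep="\t", index=False)
            mp.to_frame().to_csv(out_dir / f"profile_chh_{sub}.tsv", sep="\t", index=False)
        summary["profiles_arm_pairs"] = prof
    timings["profiles"] = time.perf_counter() - t0

    # ---- ACRs ------------------------------------------------------------
    t0 = time.perf_counter()
    acrs = acr_mod.classify_acrs(data["acrs"], data["genes"])
    gene_status = pd.concat(
        [
            pd.Series(table["status"].to_numpy(), index=table[col].to_numpy())
            for col in ("maize1_gene", "maize2_gene")
        ]
    )
    gene_status = gene_status[gene_status.index.notna()]
    subgenome_of_gene = genes_ix["subgenome"]
    acr_ratios = {}
    for sub in ("maize1", "maize2"):
        ns, nw, ratio = acr_mod.acr_retention_ratio(
            acrs, gene_status, subgenome_of_gene, sub
        )
        acr_ratios[sub] = {"near_singleton": ns, "near_wgd": nw, "ratio": ratio}
    acrs["retention_category"] = acr_mod.assign_retention_category(
        acrs, data["acr_homology"], gene_status
    )
    acrs["region"] = part_mod.classify_frame(acrs, partitions)
    acrs["group"] = acrs["subgenome"] + "_" + acrs["region"]
    access = acr_mod.accessibility_compare(acrs)
    io.write_tsv(acrs, out_dir / "acrs_annotated.tsv")
    io.write_tsv(access, out_dir / "acr_accessibility.tsv")
    dist_class = acrs["distance_class"].value_counts().to_dict()
    summary["acr"] = {
        "ratios": acr_ratios,
        "distance_classes": {k: int(v) for k, v in dist_class.items()},
        "retention_categories": acr_mod.category_counts(acrs["retention_category"]),
        "accessibility_mean": {
            r["group"]: r["mean"] for _, r in access.iterrows()
        },
    }
    # ACR divergence vs the outgroup
    hom = data["acr_homology"]
    k_vals: dict[str, list[float]] = {}
    acr_region = acrs.set_index("acr_id")["region"]
    for _, row in hom.iterrows():
        if pd.isna(row["sorghum_acr"]):
            continue
        mseq = data["acr_seq_maize"].get(row["maize_acr"])
        sseq = data["acr_seq_sorghum"].get(row["sorghum_acr"])
        if mseq is None or sseq is None:
            continue
        try:
            k = molevol.jc_distance(mseq, sseq)
        except molevol.SaturationError:
            continue
        reg = acr_region.get(row["maize_acr"], "arm")
        k_vals.setdefault(f"{row['subgenome']}_{reg}", []).append(k)
    summary["acr"]["mean_k"] = {g: float(np.mean(v)) for g, v in sorted(k_vals.items())}
    # loops
    sub_of_chrom = {
        c: ("maize1" if c.startswith("m1_") else "maize2") for c in partitions
    }
    loop_counts = acr_mod.loop_region_counts(data["loops"], partitions, sub_of_chrom)
    io.write_tsv(loop_counts, out_dir / "loop_counts.tsv")
    summary["loops"] = {
        f"{r['subgenome']}_{r['region']}": int(r["n_loops"]) for _, r in loop_counts.iterrows()
    }
    timings["acr"] = time.perf_counter() - t0

    summary["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary
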