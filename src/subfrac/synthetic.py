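"""Synthetic two-subgenome dataset generator.

Emulates a paleotetraploid genome descended from a sorghum-like ancestor:
every ancestral gene once had one copy in each subgenome, copies are lost
with subgenome- and region-dependent probabilities (biased fractionation),
surviving coding sequences diverge at configured synonymous/nonsynonymous
rates, the dominant subgenome's arm genes carry a multiplicative expression
advantage, gene flanks carry 24-nt siRNA / CHH-methylation "islands", and
accessible chromatin regions (ACRs) are retained with subgenome- and
region-dependent probabilities.  Chromosomes have gene-rich, TE-poor,
high-recombination arms around a gene-poor, TE-rich, recombination-
suppressed pericentromeric band, so the partition stage can recover the
planted geography.

Everything is driven by one :class:`~subfrac.config.SimConfig` and one seeded
generator; the same config and seed reproduce byte-identical output files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _codon, io
from .config import SimConfig

PAIR = "pair"
SINGLETON_M1 = "singleton_m1"
SINGLETON_M2 = "singleton_m2"


# ------------------------------------------------------------- sequences

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence of sense codons starting with ATG."""
    codons = rng.choice(_codon.SENSE_CODONS, size=n_codons)
    return "ATG" + "".join(codons[1:])


def evolve_cds(seq: str, ka: float, ks: float, rng: np.random.Generator) -> str:
    """Apply Poisson-distributed substitutions at per-site rates ka and ks.

    Event counts are Poisson(ka x nonsynonymous sites) and
    Poisson(ks x synonymous sites) of the ancestral sequence; each event is
    placed by rejection sampling (random codon, position and base, accepted
    when the change has the required effect and creates no stop codon), so
    multiple hits and within-codon interactions occur naturally.
    """
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    s_sites = sum(_codon.SYN_SITES[c] for c in codons)
    n_sites = 3 * len(codons) - s_sites
    n_syn = rng.poisson(ks * s_sites)
    n_non = rng.poisson(ka * n_sites)
    events = np.array([True] * n_syn + [False] * n_non)
    rng.shuffle(events)
    n = len(codons)
    for synonymous in events:
        for _ in range(1000):  # rejection loop
            ci = rng.integers(n)
            options = (
                _codon.synonymous_options(codons[ci])
                if synonymous
                else _codon.nonsynonymous_options(codons[ci])
            )
            if not options:
                continue
            pos, base = options[rng.integers(len(options))]
            c = codons[ci]
            codons[ci] = c[:pos] + base + c[pos + 1 :]
            break
        else:  # pragma: no cover - would need a pathological sequence
            raise RuntimeError("could not place substitution")
    return "".join(codons)


def evolve_nucleotide(seq: str, k: float, rng: np.random.Generator) -> str:
    """Jukes–Cantor-style evolution of non-coding sequence at rate k subs/site."""
    bases = list(seq)
    n_events = rng.poisson(k * len(bases))
    for _ in range(n_events):
        i = int(rng.integers(len(bases)))
        alts = [b for b in "ACGT" if b != bases[i]]
        bases[i] = alts[int(rng.integers(3))]
    return "".join(bases)


# ------------------------------------------------------------- geography

def peri_band(config: SimConfig) -> tuple[float, float]:
    L, f = config.chrom_length, config.peri_fraction
    return (L * (1 - f) / 2.0, L * (1 + f) / 2.0)


def _gene_positions(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Positions along one chromosome following the arm/peri density profile."""
    b0, b1 = peri_band(config)
    L = config.chrom_length
    xs = np.array([0.0, b0, b1, L])
    masses = np.array(
        [
            0.0,
            b0 * config.gene_density_arm,
            (b1 - b0) * config.gene_density_peri,
            (L - b1) * config.gene_density_arm,
        ]
    )
    cum = np.cumsum(masses)
    q = (np.arange(n) + 0.5) / n * cum[-1]
    pos = np.interp(q, cum, xs)
    pos = pos + rng.normal(0.0, L / max(n, 1) / 10.0, size=n)
    pos = np.sort(np.clip(pos, 10_000, L - 10_000))
    return pos


def _region_of(pos_mid: np.ndarray, config: SimConfig) -> np.ndarray:
    b0, b1 = peri_band(config)
    return np.where((pos_mid >= b0) & (pos_mid < b1), "peri", "arm")


def _te_intervals(config: SimConfig, chrom: str, rng: np.random.Generator) -> pd.DataFrame:
    """TE intervals filling the configured bp fraction per region."""
    b0, b1 = peri_band(config)
    L = config.chrom_length
    rows = []
    x = 0.0
    while x < L:
        density = config.te_density_peri if b0 <= x < b1 else config.te_density_arm
        te_len = float(np.clip(rng.gamma(2.0, 2000.0), 500, 20000))
        gap = te_len * (1 - density) / density * float(rng.lognormal(0.0, 0.3))
        start = x + gap
        end = min(start + te_len, L)
        if start >= L:
            break
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "te_class": "LTR" if rng.random() < 0.8 else "DNA",
            }
        )
        x = end
    return pd.DataFrame(rows)


def _marker_map(config: SimConfig, chrom: str, rng: np.random.Generator) -> pd.DataFrame:
    b0, b1 = peri_band(config)
    bp = np.arange(0, config.chrom_length + 1, config.marker_spacing, dtype=float)
    mids = (bp[:-1] + bp[1:]) / 2.0
    base = np.where((mids >= b0) & (mids < b1), config.recomb_peri, config.recomb_arm)
    rates = base * rng.lognormal(0.0, 0.25, size=len(base))
    cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(bp) / 1e6)])
    return pd.DataFrame({"chrom": chrom, "bp": bp.astype(int), "cM": np.round(cm, 6)})


# ----------------------------------------------------------- signal tracks

def _gene_region(gene: pd.Series) -> tuple[int, int]:
    return max(0, int(gene["start"]) - 2000), int(gene["end"]) + 2000


def _island_lambda(positions: np.ndarray, gene: pd.Series, height: float, config: SimConfig):
    """Gaussian flanking bumps centred island_offset bp beyond TSS and TTS."""
    sigma = config.island_width / 2.0
    c1 = gene["start"] - config.island_offset
    c2 = gene["end"] + config.island_offset
    bump = np.exp(-0.5 * ((positions - c1) / sigma) ** 2) + np.exp(
        -0.5 * ((positions - c2) / sigma) ** 2
    )
    return height * bump


def generate_track(
    kind: str,
    genes: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, int | None]:
    """Simulate one signal track over the flanks+body of the given genes.

    Returns (track frame, library_total) — the total is meaningful for the
    siRNA kind only.  Methylation rows are per-cytosine (5 bp lattice) CHH
    records; siRNA rows are 10 bp bins; histone rows are 100 bp bins with
    treat and input counts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(genes) == 0:
        raise ValueError("gene set is empty")
    frames = []
    for _, gene in genes.iterrows():
        lo, hi = _gene_region(gene)
        factor = (
            config.sirna_island_factor_m1 if gene.get("subgenome") == "maize1" else 1.0
        )
        if kind == "sirna":
            pos = np.arange(lo - lo % 10, hi, 10, dtype=float)
            lam = config.sirna_background * 10 + 10 * _island_lambda(
                pos + 5, gene, config.sirna_island * factor, config
            )
            counts = rng.poisson(lam)
            keep = counts > 0
            frames.append(
                pd.DataFrame(
                    {"chrom": gene["chrom"], "pos": pos[keep].astype(int), "count": counts[keep]}
                )
            )
        elif kind == "methylation":
            pos = np.arange(lo - lo % 5, hi, 5, dtype=float)
            total = rng.poisson(config.meth_coverage, size=len(pos))
            keep = total > 0
            pos, total = pos[keep], total[keep]
            level = np.clip(
                config.meth_background
                + _island_lambda(pos, gene, config.chh_island_height, config),
                0.0,
                1.0,
            )
            meth = rng.binomial(total, level)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": gene["chrom"],
                        "pos": pos.astype(int),
                        "context": "CHH",
                        "meth": meth,
                        "total": total,
                    }
                )
            )
        elif kind == "histone":
            pos = np.arange(lo - lo % 100, hi, 100, dtype=float)
            boost = config.histone_body_boost.get(
                (gene.get("subgenome"), gene.get("region")), 0.0
            )
            in_body = (pos + 50 >= gene["start"]) & (pos + 50 < gene["end"])
            lam_t = config.histone_input_rate * (1.0 + boost * in_body)
            treat = rng.poisson(lam_t)
            inp = rng.poisson(config.histone_input_rate, size=len(pos))
            frames.append(
                pd.DataFrame(
                    {"chrom": gene["chrom"], "pos": pos.astype(int), "treat": treat, "input": inp}
                )
            )
        else:
            raise ValueError(f"unknown track kind {kind!r}")
    track = pd.concat(frames, ignore_index=True)
    track = track.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    # collapse duplicate positions where gene regions overlap
    if kind == "sirna":
        track = track.groupby(["chrom", "pos"], as_index=False)["count"].max()
        library_total = int(track["count"].sum())
        return track, library_total
    if kind == "methylation":
        track = track.groupby(["chrom", "pos", "context"], as_index=False)[
            ["meth", "total"]
        ].max()
        return track, None
    track = track.groupby(["chrom", "pos"], as_index=False)[["treat", "input"]].max()
    return track, None


# --------------------------------------------------------------- main build

def _segment_layout(config: SimConfig, rng: np.random.Generator):
    """Cut ancestral chromosomes into segments and place them in both subgenomes.

    Returns a per-copy frame (one row per ancestral gene per subgenome) with
    chromosome assignment and within-chromosome order, plus ancestral ids.
    Segment placement keeps the relative chromosomal position of most
    segments (chromatin environments correlate between homoeologs, as in
    real paleopolyploids) while reassigning some to other chromosomes or
    shifted positions, which creates block-pairing breaks and
    cross-environment pairs.
    """
    anc_rows = []
    segments = []  # (anc_chrom_idx, seg_idx, gene_index_array, rel_mid)
    for ci in range(config.n_chromosomes):
        b0, b1 = peri_band(config)
        arm_mb = (config.chrom_length - (b1 - b0)) / 1e6
        peri_mb = (b1 - b0) / 1e6
        n_genes = int(round(arm_mb * config.gene_density_arm + peri_mb * config.gene_density_peri))
        start = 0
        cuts = np.sort(
            rng.choice(np.arange(1, n_genes), size=config.n_blocks_per_chromosome - 1, replace=False)
        )
        bounds = np.concatenate([[0], cuts, [n_genes]])
        for si in range(len(bounds) - 1):
            idx = np.arange(bounds[si], bounds[si + 1])
            rel_mid = (bounds[si] + bounds[si + 1]) / 2.0 / n_genes
            segments.append((ci, si, idx, rel_mid))
        for gi in range(n_genes):
            anc_rows.append(
                {
                    "anc_id": f"anc_{ci:02d}_{gi:05d}",
                    "sorghum_gene": f"Sb{ci + 1:02d}g{(gi + 1) * 10:06d}",
                    "sorghum_chrom": f"sb_chr{ci + 1:02d}",
                    "sorghum_order": gi,
                    "anc_chrom_idx": ci,
                }
            )
    anc = pd.DataFrame(anc_rows)

    copy_rows = []
    for sub in ("maize1", "maize2"):
        placements = []  # (target_chrom_idx, sort_key, segment)
        for ci, si, idx, rel_mid in segments:
            if sub == "maize1":
                placements.append((ci, rel_mid, (ci, idx)))
            else:
                target = ci
                if rng.random() < 0.15 and config.n_chromosomes > 1:
                    others = [c for c in range(config.n_chromosomes) if c != ci]
                    target = others[int(rng.integers(len(others)))]
                key = float(np.clip(rel_mid + rng.normal(0.0, 0.05), 0.0, 1.0))
                placements.append((target, key, (ci, idx)))
        for target in range(config.n_chromosomes):
            ordered = sorted(
                [p for p in placements if p[0] == target], key=lambda p: (p[1], p[2][0])
            )
            order = 0
            for _, _, (ci, idx) in ordered:
                for gi in idx:
                    copy_rows.append(
                        {
                            "anc_id": f"anc_{ci:02d}_{gi:05d}",
                            "subgenome": sub,
                            "chrom_idx": target,
                            "order": order,
                        }
                    )
                    order += 1
    copies = pd.DataFrame(copy_rows)
    return anc, copies


def _place_copies(copies: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    out = []
    for (sub, ci), grp in copies.groupby(["subgenome", "chrom_idx"], sort=True):
        grp = grp.sort_values("order")
        pos = _gene_positions(len(grp), config, rng)
        lengths = rng.integers(2000, 5001, size=len(grp))
        strands = np.where(rng.random(len(grp)) < 0.5, "+", "-")
        chrom = f"{'m1' if sub == 'maize1' else 'm2'}_chr{ci + 1:02d}"
        g = grp.copy()
        g["chrom"] = chrom
        g["start"] = pos.astype(int)
        g["end"] = (pos + lengths).astype(int)
        g["strand"] = strands
        g["region"] = _region_of(pos + lengths / 2.0, config)
        g["gene_id"] = [
            f"{'m1' if sub == 'maize1' else 'm2'}_{a.split('anc_')[1]}" for a in g["anc_id"]
        ]
        out.append(g)
    return pd.concat(out, ignore_index=True)


def generate_dataset(config: SimConfig, out_dir) -> dict:
    """Write the complete synthetic dataset to ``out_dir``; return the manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)

    anc, copies = _segment_layout(config, rng)
    copies = _place_copies(copies, config, rng)
    m1 = copies[copies["subgenome"] == "maize1"].set_index("anc_id")
    m2 = copies[copies["subgenome"] == "maize2"].set_index("anc_id")
    anc = anc.set_index("anc_id")

    # --- retention fates -------------------------------------------------
    # Fates are allocated by stratified assignment within each environment
    # stratum (region of copy 1 x region of copy 2): realised loss fractions
    # match the configured probabilities at simulation scale, and the seed
    # only decides which gene draws which fate.  Loss of both copies is
    # excluded (fate probabilities are renormalised), so the retained-gene
    # bookkeeping identity holds exactly.
    anc_ids = anc.index.to_numpy()
    tandem = rng.random(len(anc_ids)) < config.tandem_frac
    statuses = np.empty(len(anc_ids), dtype=object)
    region1 = m1.loc[anc_ids, "region"].to_numpy()
    region2 = m2.loc[anc_ids, "region"].to_numpy()
    statuses[tandem] = PAIR  # tandem rows keep both copies; filtered downstream
    free = ~tandem
    for r1 in ("arm", "peri"):
        for r2 in ("arm", "peri"):
            idx = np.where(free & (region1 == r1) & (region2 == r2))[0]
            if idx.size == 0:
                continue
            p1 = config.loss_prob[("maize1", r1)]
            p2 = config.loss_prob[("maize2", r2)]
            z = 1.0 - p1 * p2  # condition on at least one copy surviving
            n_s1 = int(round(idx.size * (1 - p1) * p2 / z))
            n_s2 = int(round(idx.size * (1 - p2) * p1 / z))
            n_s2 = min(n_s2, idx.size - n_s1)
            shuffled = rng.permutation(idx)
            statuses[shuffled[:n_s1]] = SINGLETON_M1
            statuses[shuffled[n_s1 : n_s1 + n_s2]] = SINGLETON_M2
            statuses[shuffled[n_s1 + n_s2 :]] = PAIR
    status = pd.Series(statuses, index=anc_ids)
    retained_m1 = status.isin([PAIR, SINGLETON_M1])
    retained_m2 = status.isin([PAIR, SINGLETON_M2])

    genes = pd.concat(
        [
            m1.loc[retained_m1[m1.index].to_numpy()].reset_index(),
            m2.loc[retained_m2[m2.index].to_numpy()].reset_index(),
        ],
        ignore_index=True,
    )[["gene_id", "chrom", "start", "end", "strand", "subgenome", "region", "anc_id"]]
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    # --- syntelog table (ancestral order) --------------------------------
    table = pd.DataFrame(
        {
            "maize1_gene": [
                m1.loc[a, "gene_id"] if retained_m1[a] else None for a in anc_ids
            ],
            "maize2_gene": [
                m2.loc[a, "gene_id"] if retained_m2[a] else None for a in anc_ids
            ],
            "sorghum_gene": anc["sorghum_gene"].to_numpy(),
            "sorghum_chrom": anc["sorghum_chrom"].to_numpy(),
            "sorghum_order": anc["sorghum_order"].to_numpy(),
            "tandem": tandem,
        },
        index=anc_ids,
    )
    table = table.sort_values(["sorghum_chrom", "sorghum_order"], kind="stable")
    table.index.name = "anc_id"

    # --- sequences -------------------------------------------------------
    anc_seq = {a: random_cds(rng, config.n_codons) for a in anc_ids}
    sorghum_fasta = {anc.loc[a, "sorghum_gene"]: anc_seq[a] for a in anc_ids}
    maize_fasta: dict[str, str] = {}
    for a in anc_ids:
        for sub, side, retained in (
            ("maize1", m1, retained_m1),
            ("maize2", m2, retained_m2),
        ):
            if not retained[a]:
                continue
            region = side.loc[a, "region"]
            seq = evolve_cds(
                anc_seq[a],
                ka=config.nonsyn_rate[(sub, region)],
                ks=config.syn_rate[(sub, region)],
                rng=rng,
            )
            maize_fasta[side.loc[a, "gene_id"]] = seq

    n_alignments = 0
    for a in anc_ids:
        if status[a] != PAIR:
            continue
        g1, g2 = m1.loc[a, "gene_id"], m2.loc[a, "gene_id"]
        io.write_fasta(
            {g1: maize_fasta[g1], g2: maize_fasta[g2]}, out / "alignments" / f"{a}.fasta"
        )
        n_alignments += 1

    # --- expression ------------------------------------------------------
    base = np.exp(rng.normal(config.expr_log_mean, config.expr_log_sd, size=len(anc_ids)))
    baseline = pd.Series(base, index=anc_ids)
    pair_ids = [a for a in anc_ids if status[a] == PAIR]
    arm_pairs = [a for a in pair_ids if m1.loc[a, "region"] == "arm"]
    n_dom = int(round(config.dominance_fraction * len(arm_pairs)))
    dominant = set(
        rng.choice(np.array(arm_pairs, dtype=object), size=n_dom, replace=False)
        if n_dom
        else []
    )

    def expr_matrix(n_cols: int, prefix: str) -> pd.DataFrame:
        cols = [f"{prefix}{i + 1:02d}" for i in range(n_cols)]
        rows = {}
        for _, g in genes.iterrows():
            mult = (
                config.dominance_effect
                if g["subgenome"] == "maize1" and g["anc_id"] in dominant
                else 1.0
            )
            noise = np.exp(rng.normal(0.0, config.expr_noise_sd, size=n_cols))
            rows[g["gene_id"]] = baseline[g["anc_id"]] * mult * noise
        mat = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        mat.index.name = "gene_id"
        return mat.round(4)

    fpkm = expr_matrix(config.n_tissues, "tissue_")
    protein = expr_matrix(config.n_protein_samples, "sample_")

    # --- SNPs and genotype panel ----------------------------------------
    snp_rows = []
    ind_cols = [f"ind_{i:02d}" for i in range(config.n_panel_individuals)]
    for _, g in genes.iterrows():
        n_snps = rng.poisson((g["end"] - g["start"]) / 1000.0 * config.snps_per_kb)
        if n_snps == 0:
            continue
        pos = np.sort(rng.integers(g["start"], g["end"], size=n_snps))
        classes = np.where(rng.random(n_snps) < 0.5, "nonsyn", "syn")
        gerp = rng.normal(0.5, 1.5, size=n_snps)
        q = rng.beta(0.5, 3.0, size=n_snps)
        biased = (
            (classes == "nonsyn")
            & (gerp > 0)
            & (g["subgenome"] == "maize2")
            & (g["region"] == "arm")
        )
        q = np.where(biased, np.clip(q * config.load_bias_m2_arm, 0, 1), q)
        counts = rng.binomial(2, q[:, None], size=(n_snps, len(ind_cols)))
        for j in range(n_snps):
            row = {
                "chrom": g["chrom"],
                "pos": int(pos[j]),
                "gene_id": g["gene_id"],
                "ref": "A",
                "alt": "G",
                "ancestral": "A",
                "snp_class": classes[j],
                "gerp": round(float(gerp[j]), 4),
            }
            row.update({c: int(v) for c, v in zip(ind_cols, counts[j])})
            snp_rows.append(row)
    snps = pd.DataFrame(snp_rows)

    # --- tracks ----------------------------------------------------------
    sirna, library_total = generate_track("sirna", genes, config, rng)
    meth, _ = generate_track("methylation", genes, config, rng)
    histone, _ = generate_track("histone", genes, config, rng)

    # --- ACRs, homology, sequences, loops --------------------------------
    acr_rows, hom_rows = [], []
    acr_seq_maize: dict[str, str] = {}
    acr_seq_sorghum: dict[str, str] = {}
    lo_len, hi_len = config.acr_length
    for a in anc_ids:
        if rng.random() >= config.acr_prob:
            continue
        length = int(rng.integers(lo_len, hi_len + 1))
        kind = rng.choice(["genic", "proximal", "distal"], p=[0.4, 0.3, 0.3])
        side_up = rng.random() < 0.5
        if kind == "genic":
            rel = float(rng.random())
            offset = None
        elif kind == "proximal":
            offset = int(rng.integers(1, 2001))
        else:
            offset = int(rng.integers(2001, 8001))
        syntenic = rng.random() < config.acr_syntenic_prob
        anc_acr_seq = "".join(rng.choice(list("ACGT"), size=length))
        sorghum_acr = f"sb_acr_{a.split('anc_')[1]}" if syntenic else None
        if syntenic:
            acr_seq_sorghum[sorghum_acr] = anc_acr_seq
        copy_ids = {}
        for sub, side, retained in (
            ("maize1", m1, retained_m1),
            ("maize2", m2, retained_m2),
        ):
            if not retained[a]:
                continue
            g = side.loc[a]
            if rng.random() >= config.acr_retention_prob[(sub, g["region"])]:
                continue
            if kind == "genic":
                start = int(g["start"] + rel * max(1, (g["end"] - g["start"] - length)))
            elif side_up:
                start = int(g["start"] - offset - length)
            else:
                start = int(g["end"] + offset)
            start = max(0, start)
            score = float(np.round(np.exp(rng.normal(0.0, 0.4)), 4))
            if sub == "maize1" and g["region"] == "arm":
                score = round(score * config.accessibility_bias_m1_arm, 4)
            acr_id = f"{'m1' if sub == 'maize1' else 'm2'}_acr_{a.split('anc_')[1]}"
            copy_ids[sub] = acr_id
            acr_rows.append(
                {
                    "chrom": g["chrom"],
                    "start": start,
                    "end": start + length,
                    "acr_id": acr_id,
                    "score": score,
                    "subgenome": sub,
                    "anc_id": a,
                }
            )
            if syntenic:
                acr_seq_maize[acr_id] = evolve_nucleotide(
                    anc_acr_seq, config.acr_k_rate[(sub, g["region"])], rng
                )
        for sub, acr_id in copy_ids.items():
            other = "maize2" if sub == "maize1" else "maize1"
            hom_rows.append(
                {
                    "maize_acr": acr_id,
                    "subgenome": sub,
                    "partner_acr": copy_ids.get(other),
                    "sorghum_acr": sorghum_acr,
                }
            )
    acrs = pd.DataFrame(acr_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    homology = pd.DataFrame(hom_rows)

    # loops: distal/proximal ACR <-> target gene TSS, biased towards m1 arms
    gene_ix = genes.set_index("gene_id")
    anc_gene = genes.set_index(["anc_id", "subgenome"])["gene_id"]
    loop_pool = acrs.merge(
        genes[["anc_id", "subgenome", "gene_id", "region"]],
        on=["anc_id", "subgenome"],
        how="left",
    )
    weights = np.where(
        (loop_pool["subgenome"] == "maize1") & (loop_pool["region"] == "arm"),
        config.loop_bias_m1_arm,
        1.0,
    )
    weights = weights / weights.sum()
    chosen = rng.choice(len(loop_pool), size=min(config.n_loops, len(loop_pool)), p=weights)
    loop_rows = []
    for i in chosen:
        rec = loop_pool.iloc[int(i)]
        g = gene_ix.loc[rec["gene_id"]]
        tss = int(g["start"]) if g["strand"] == "+" else int(g["end"])
        loop_rows.append(
            {
                "chrom1": rec["chrom"],
                "start1": int(rec["start"]),
                "end1": int(rec["end"]),
                "chrom2": g["chrom"],
                "start2": max(0, tss - 500),
                "end2": tss + 500,
            }
        )
    loops = pd.DataFrame(loop_rows)

    # --- flat files ------------------------------------------------------
    chrom_names = [
        f"{p}_chr{ci + 1:02d}" for p in ("m1", "m2") for ci in range(config.n_chromosomes)
    ]
    b0, b1 = peri_band(config)
    centromeres = pd.DataFrame(
        {
            "chrom": chrom_names,
            "start": int(config.chrom_length / 2 - 1e6),
            "end": int(config.chrom_length / 2 + 1e6),
        }
    )
    tes = pd.concat(
        [_te_intervals(config, c, rng) for c in chrom_names], ignore_index=True
    )
    markers = pd.concat(
        [_marker_map(config, c, rng) for c in chrom_names], ignore_index=True
    )

    records = {}
    records["genes.gff3"] = io.write_gff3(genes, out / "genes.gff3")
    records["tes.bed"] = io.write_bed(
        tes.assign(name=tes["te_class"]), out / "tes.bed"
    )
    records["markers.tsv"] = io.write_tsv(markers, out / "markers.tsv")
    records["centromeres.tsv"] = io.write_tsv(centromeres, out / "centromeres.tsv")
    records["syntelogs.tsv"] = io.write_tsv(table, out / "syntelogs.tsv", index=True)
    records["cds_sorghum.fasta"] = io.write_fasta(sorghum_fasta, out / "cds_sorghum.fasta")
    records["cds_maize.fasta"] = io.write_fasta(maize_fasta, out / "cds_maize.fasta")
    records["alignments/"] = n_alignments
    records["snps.tsv"] = io.write_tsv(snps, out / "snps.tsv")
    records["expression_fpkm.tsv"] = io.write_tsv(fpkm, out / "expression_fpkm.tsv", index=True)
    records["protein_abundance.tsv"] = io.write_tsv(
        protein, out / "protein_abundance.tsv", index=True
    )
    records["tracks/sirna.tsv"] = io.write_sirna_track(
        sirna, library_total, out / "tracks" / "sirna.tsv"
    )
    records["tracks/methylation.tsv"] = io.write_methylation_track(
        meth, out / "tracks" / "methylation.tsv"
    )
    records["tracks/histone.tsv"] = io.write_histone_track(
        histone, out / "tracks" / "histone.tsv"
    )
    records["acrs.bed"] = io.write_bed(
        acrs, out / "acrs.bed", columns=("chrom", "start", "end", "acr_id", "score", "subgenome")
    )
    records["acr_homology.tsv"] = io.write_tsv(homology, out / "acr_homology.tsv")
    records["acr_seqs_maize.fasta"] = io.write_fasta(acr_seq_maize, out / "acr_seqs_maize.fasta")
    records["acr_seqs_sorghum.fasta"] = io.write_fasta(
        acr_seq_sorghum, out / "acr_seqs_sorghum.fasta"
    )
    records["loops.bedpe"] = io.write_bedpe(loops, out / "loops.bedpe")

    status_by_region: dict[str, int] = {}
    for sub, side, singleton in (
        ("maize1", m1, SINGLETON_M1),
        ("maize2", m2, SINGLETON_M2),
    ):
        regions = side["region"]
        for reg in ("arm", "peri"):
            in_reg = regions[regions == reg].index
            status_by_region[f"{sub}_{reg}_pairs"] = int((status[in_reg] == PAIR).sum())
            status_by_region[f"{sub}_{reg}_singletons"] = int(
                (status[in_reg] == singleton).sum()
            )
    truth = {
        "status_counts": status.value_counts().to_dict(),
        "n_ancestral_genes": int(len(anc_ids)),
        "n_tandem": int(tandem.sum()),
        "n_dominant_pairs": len(dominant),
        "peri_band": [b0, b1],
        "island_offset": config.island_offset,
        "status_by_region": status_by_region,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    records["truth.json"] = 1

    manifest = io.write_manifest(
        records,
        out,
        extra={
            "seed": config.seed,
            "n_ancestral_genes": int(len(anc_ids)),
            "n_pairs": int((status == PAIR).sum()),
            "n_singleton_m1": int((status == SINGLETON_M1).sum()),
            "n_singleton_m2": int((status == SINGLETON_M2).sum()),
        },
    )
    with open(manifest) as fh:
        return json.load(fh)
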