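"""Metagene profiles of TEs, 24-nt siRNAs, DNA methylation and histone marks.

All profiles are strand-aware and anchored at the transcription start site
(TSS, upstream flank) and termination site (TTS, downstream flank):

* TE proportion and siRNA abundance: 100 bp windows sliding in 10 bp steps
  across 2 kb flanks -> 191 windows per side; siRNA values are TP10M
  (reads x 1e7 / library size).
* Weighted methylation: non-overlapping 50 bp flank windows (40 per side)
  and 40 equal-size gene-body bins; window level = sum(methylated reads) /
  sum(total reads) over the window's cytosines, and zero-coverage windows
  are excluded from cross-gene means (the ratio is undefined there).
* Histone signal: non-overlapping 100 bp flank windows (20 per side) plus
  40 body bins of log2((treat reads + 1) / (input reads + 1)).

Flanks running off the chromosome start are truncated, and per-window gene
counts are tracked so means always use the correct denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import CoverageIndex, SignalTrack

FLANK = 2000
N_BODY_BINS = 40

GEOMETRIES = {  # (window bp, step bp, n windows per flank)
    "sliding": (100, 10, (FLANK - 100) // 10 + 1),  # 191
    "meth": (50, 50, FLANK // 50),  # 40
    "histone": (100, 100, FLANK // 100),  # 20
}


@dataclass
class MetaProfile:
    """Mean signal per window, with per-window gene counts."""

    kind: str
    upstream: np.ndarray
    downstream: np.ndarray
    body: np.ndarray | None = None
    n_upstream: np.ndarray = field(default=None)
    n_downstream: np.ndarray = field(default=None)
    n_body: np.ndarray | None = None
    window: int = 100
    step: int = 10

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg, vals, ns in (
            ("upstream", self.upstream, self.n_upstream),
            ("body", self.body, self.n_body),
            ("downstream", self.downstream, self.n_downstream),
        ):
            if vals is None:
                continue
            for i, v in enumerate(vals):
                rows.append(
                    {"segment": seg, "window": i, "mean": v, "n_genes": int(ns[i])}
                )
        return pd.DataFrame(rows)


def flank_windows(gene: dict, geometry: str) -> tuple[np.ndarray, np.ndarray]:
    """Absolute (start, end) arrays for upstream and downstream flank windows.

    Window index 0 is farthest upstream of the TSS (resp. closest to the TTS
    for the downstream flank); coordinates are truncated at 0.  Each array has
    shape (n_windows, 2).
    """
    window, step, n = GEOMETRIES[geometry]
    rel = np.arange(n) * step  # 0 .. flank-window
    if gene["strand"] == "+":
        tss, tts = gene["start"], gene["end"]
        up = np.stack([tss - FLANK + rel, tss - FLANK + rel + window], axis=1)
        down = np.stack([tts + rel, tts + rel + window], axis=1)
    else:
        tss, tts = gene["end"], gene["start"]
        up = np.stack([tss + FLANK - rel - window, tss + FLANK - rel], axis=1)
        down = np.stack([tts - rel - window, tts - rel], axis=1)
    return np.clip(up, 0, None), np.clip(down, 0, None)


def body_bins(gene: dict) -> np.ndarray | None:
    """40 equal bins over the gene body, bin 0 at the TSS end; None if too short."""
    length = gene["end"] - gene["start"]
    if length < N_BODY_BINS:
        return None
    edges = gene["start"] + np.floor(np.arange(N_BODY_BINS + 1) * length / N_BODY_BINS)
    bins = np.stack([edges[:-1], edges[1:]], axis=1)
    if gene["strand"] == "-":
        bins = bins[::-1]
    return bins


def _iter_genes(genes: pd.DataFrame):
    if len(genes) == 0:
        raise ValueError("empty gene set")
    for _, g in genes.iterrows():
        yield {
            "chrom": g["chrom"],
            "start": int(g["start"]),
            "end": int(g["end"]),
            "strand": g["strand"],
        }


def _accumulate(mean_sums, counts, values, valid):
    mean_sums[valid] += values[valid]
    counts[valid] += 1


def nearest_te_distance(
    gene_start: int, gene_end: int, te_starts: np.ndarray, te_ends: np.ndarray
) -> float:
    """Edge-to-edge distance from a gene to its nearest TE (0 if overlapping).

    TE arrays must be sorted by start and belong to the gene's chromosome;
    returns NaN when the chromosome has no TE.
    """
    te_starts = np.asarray(te_starts, dtype=float)
    te_ends = np.asarray(te_ends, dtype=float)
    if te_starts.size == 0:
        return float("nan")
    gaps_left = gene_start - te_ends  # TE fully upstream of the gene
    gaps_right = te_starts - gene_end
    dist = np.maximum(np.maximum(gaps_left, gaps_right), 0.0)
    return float(dist.min())


def te_proportion_profile(genes: pd.DataFrame, tes: pd.DataFrame) -> MetaProfile:
    """Mean TE bp fraction per 100 bp sliding flank window."""
    cov = CoverageIndex.from_frame(tes) if len(tes) else CoverageIndex({})
    _, _, n = GEOMETRIES["sliding"]
    sums = {"up": np.zeros(n), "down": np.zeros(n)}
    counts = {"up": np.zeros(n, dtype=int), "down": np.zeros(n, dtype=int)}
    for gene in _iter_genes(genes):
        up, down = flank_windows(gene, "sliding")
        for key, win in (("up", up), ("down", down)):
            widths = win[:, 1] - win[:, 0]
            valid = widths > 0
            frac = np.zeros(n)
            if gene["chrom"] in cov.chroms():
                ov = cov.coverage(gene["chrom"], win[:, 0], win[:, 1])
                frac[valid] = ov[valid] / widths[valid]
            _accumulate(sums[key], counts[key], frac, valid)
    return MetaProfile(
        kind="te",
        upstream=np.divide(sums["up"], counts["up"], out=np.zeros_like(sums["up"]), where=counts["up"] > 0),
        downstream=np.divide(sums["down"], counts["down"], out=np.zeros_like(sums["down"]), where=counts["down"] > 0),
        n_upstream=counts["up"],
        n_downstream=counts["down"],
        window=100,
        step=10,
    )


def sirna_profile(track: SignalTrack, genes: pd.DataFrame) -> MetaProfile:
    """Mean 24-nt siRNA TP10M per 100 bp sliding flank window."""
    if track.library_total is None or track.library_total <= 0:
        raise ValueError("siRNA track requires a positive library_total")
    scale = 1e7 / track.library_total
    _, _, n = GEOMETRIES["sliding"]
    sums = {"up": np.zeros(n), "down": np.zeros(n)}
    counts = {"up": np.zeros(n, dtype=int), "down": np.zeros(n, dtype=int)}
    for gene in _iter_genes(genes):
        up, down = flank_windows(gene, "sliding")
        for key, win in (("up", up), ("down", down)):
            valid = (win[:, 1] - win[:, 0]) > 0
            reads = track.window_sums(gene["chrom"], win[:, 0], win[:, 1], "count")
            _accumulate(sums[key], counts[key], reads * scale, valid)
    return MetaProfile(
        kind="sirna",
        upstream=np.divide(sums["up"], counts["up"], out=np.zeros_like(sums["up"]), where=counts["up"] > 0),
        downstream=np.divide(sums["down"], counts["down"], out=np.zeros_like(sums["down"]), where=counts["down"] > 0),
        n_upstream=counts["up"],
        n_downstream=counts["down"],
        window=100,
        step=10,
    )


def methylation_profile(
    track: SignalTrack, genes: pd.DataFrame, context: str = "CHH"
) -> MetaProfile:
    """Weighted methylation: 50 bp flank windows + 40 gene-body bins."""
    if context not in ("CG", "CHG", "CHH"):
        raise ValueError(f"unknown methylation context {context!r}")
    _, _, n = GEOMETRIES["meth"]
    segs = {
        "up": (np.zeros(n), np.zeros(n, dtype=int)),
        "down": (np.zeros(n), np.zeros(n, dtype=int)),
        "body": (np.zeros(N_BODY_BINS), np.zeros(N_BODY_BINS, dtype=int)),
    }

    def add(seg, win, gene):
        sums, counts = segs[seg]
        meth = track.window_sums(gene["chrom"], win[:, 0], win[:, 1], "meth", context)
        total = track.window_sums(gene["chrom"], win[:, 0], win[:, 1], "total", context)
        covered = (total > 0) & ((win[:, 1] - win[:, 0]) > 0)
        level = np.zeros(len(win))
        level[covered] = meth[covered] / total[covered]
        _accumulate(sums, counts, level, covered)

    short = 0
    for gene in _iter_genes(genes):
        up, down = flank_windows(gene, "meth")
        add("up", up, gene)
        add("down", down, gene)
        bins = body_bins(gene)
        if bins is None:
            short += 1
            continue
        add("body", bins, gene)
    if short:
        warnings.warn(f"skipped {short} genes shorter than {N_BODY_BINS} bp for body bins")
    out = {}
    for seg, (sums, counts) in segs.items():
        out[seg] = (np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0), counts)
    return MetaProfile(
        kind=f"meth_{context}",
        upstream=out["up"][0],
        downstream=out["down"][0],
        body=out["body"][0],
        n_upstream=out["up"][1],
        n_downstream=out["down"][1],
        n_body=out["body"][1],
        window=50,
        step=50,
    )


def histone_profile(
    treat: SignalTrack, input_track: SignalTrack, genes: pd.DataFrame
) -> MetaProfile:
    """log2((treat+1)/(input+1)) in 100 bp flank windows and 40 body bins."""
    treat_chroms = set(treat.df["chrom"].unique())
    input_chroms = set(input_track.df["chrom"].unique())
    gene_chroms = set(genes["chrom"].unique())
    if (gene_chroms & treat_chroms) != (gene_chroms & input_chroms):
        raise ValueError("treat and input tracks cover different chromosomes")
    _, _, n = GEOMETRIES["histone"]
    segs = {
        "up": (np.zeros(n), np.zeros(n, dtype=int)),
        "down": (np.zeros(n), np.zeros(n, dtype=int)),
        "body": (np.zeros(N_BODY_BINS), np.zeros(N_BODY_BINS, dtype=int)),
    }

    def add(seg, win, gene):
        sums, counts = segs[seg]
        t = treat.window_sums(gene["chrom"], win[:, 0], win[:, 1], "treat")
        i = input_track.window_sums(gene["chrom"], win[:, 0], win[:, 1], "input")
        valid = (win[:, 1] - win[:, 0]) > 0
        _accumulate(sums, counts, np.log2((t + 1.0) / (i + 1.0)), valid)

    short = 0
    for gene in _iter_genes(genes):
        up, down = flank_windows(gene, "histone")
        add("up", up, gene)
        add("down", down, gene)
        bins = body_bins(gene)
        if bins is None:
            short += 1
            continue
        add("body", bins, gene)
    if short:
        warnings.warn(f"skipped {short} genes shorter than {N_BODY_BINS} bp for body bins")
    out = {seg: (np.divide(s, c, out=np.zeros_like(s), where=c > 0), c) for seg, (s, c) in segs.items()}
    return MetaProfile(
        kind="histone",
        upstream=out["up"][0],
        downstream=out["down"][0],
        body=out["body"][0],
        n_upstream=out["up"][1],
        n_downstream=out["down"][1],
        n_body=out["body"][1],
        window=100,
        step=100,
    )
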