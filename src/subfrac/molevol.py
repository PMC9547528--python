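"""Pairwise evolutionary distances and mutation-burden summaries.

Implements Nei–Gojobori (1986)-style Ka/Ks counting on codon alignments,
Jukes–Cantor (1969) nucleotide distance for non-coding sequence such as
accessible chromatin regions, and a GERP-based genetic-load statistic
(average number of derived, putatively deleterious alleles per individual,
normalised by gene-body length).

Both distance estimators use the same multiple-hit correction,

    d = -(3/4) * ln(1 - (4/3) * p),

which saturates at p = 0.75; proportions at or beyond that bound raise
:class:`SaturationError` rather than returning a complex number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _codon

VALID_BASES = frozenset("ACGT")


class SaturationError(ValueError):
    """Observed difference proportion is at or beyond the correctable bound."""


class AlignmentError(ValueError):
    """Malformed alignment (unequal lengths, frame problems, in-frame stops)."""


@dataclass(frozen=True)
class EvoDistances:
    """Substitution-rate estimates for one aligned pair."""

    ka: float
    ks: float
    omega: float  # NaN when Ks == 0
    n_codons_used: int

    @property
    def k(self) -> float:  # convenience for non-coding callers
        return self.ka


@dataclass(frozen=True)
class SiteCounts:
    """Raw Nei–Gojobori counts before the distance correction."""

    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    n_codons_used: int

    @property
    def ps(self) -> float:
        return self.s_diffs / self.s_sites

    @property
    def pn(self) -> float:
        return self.n_diffs / self.n_sites


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a difference proportion."""
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 0.75 is saturated")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _iter_codon_pairs(seq1: str, seq2: str):
    """Yield aligned codon pairs, skipping columns unusable for counting.

    Codons containing a gap or non-ACGT character in either sequence are
    skipped entirely.  An in-frame stop codon in otherwise clean sequence is
    an alignment error: stops must be pre-masked to gaps upstream.
    """
    if len(seq1) != len(seq2):
        raise AlignmentError(
            f"aligned sequences differ in length ({len(seq1)} vs {len(seq2)})"
        )
    if len(seq1) % 3:
        raise AlignmentError(f"alignment length {len(seq1)} not divisible by 3")
    for i in range(0, len(seq1), 3):
        c1 = seq1[i : i + 3].upper()
        c2 = seq2[i : i + 3].upper()
        if not (set(c1) <= VALID_BASES and set(c2) <= VALID_BASES):
            continue
        for c in (c1, c2):
            if c in _codon.STOP_CODONS:
                raise AlignmentError(
                    f"in-frame stop codon {c} at position {i}; mask stops to '-'"
                )
        yield c1, c2


def ng86_counts(seq1: str, seq2: str) -> SiteCounts:
    """Nei–Gojobori site and difference counts for a codon alignment.

    Synonymous/nonsynonymous site totals are averaged over the two sequences;
    multi-difference codons are averaged with equal weight over substitution
    pathways (stop-codon intermediates excluded).
    """
    s1 = s2 = 0.0
    sd = nd = 0.0
    used = 0
    for c1, c2 in _iter_codon_pairs(seq1, seq2):
        s1 += _codon.SYN_SITES[c1]
        s2 += _codon.SYN_SITES[c2]
        d_s, d_n = _codon.pathway_differences(c1, c2)
        sd += d_s
        nd += d_n
        used += 1
    if used == 0:
        raise AlignmentError("no countable codons in alignment")
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * used - s_sites
    return SiteCounts(s_sites, n_sites, sd, nd, used)


def ng86(seq1: str, seq2: str) -> EvoDistances:
    """Ka, Ks and omega for an aligned coding pair (NG86 counting + JC correction)."""
    counts = ng86_counts(seq1, seq2)
    ks = jc_correct(counts.ps)
    ka = jc_correct(counts.pn)
    omega = ka / ks if ks > 0 else float("nan")
    return EvoDistances(ka=ka, ks=ks, omega=omega, n_codons_used=counts.n_codons_used)


def jc_distance(seq1: str, seq2: str) -> float:
    """Jukes–Cantor distance K for two aligned nucleotide sequences.

    Columns with a gap or non-ACGT character in either sequence are excluded.
    """
    if len(seq1) != len(seq2):
        raise AlignmentError(
            f"aligned sequences differ in length ({len(seq1)} vs {len(seq2)})"
        )
    compared = 0
    mismatches = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in VALID_BASES or b not in VALID_BASES:
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise AlignmentError("no comparable sites in alignment")
    return jc_correct(mismatches / compared)


def batch_ng86(
    pairs: pd.DataFrame,
    sequences: dict[str, str],
    id1: str = "gene1",
    id2: str = "gene2",
) -> pd.DataFrame:
    """Run :func:`ng86` over a table of gene-id pairs.

    Returns a frame with columns gene1, gene2, ka, ks, omega, n_codons_used;
    pairs whose sequences are missing or saturated get NaN distances.
    """
    rows = []
    for g1, g2 in zip(pairs[id1], pairs[id2]):
        rec = {"gene1": g1, "gene2": g2}
        try:
            d = ng86(sequences[g1], sequences[g2])
            rec.update(
                ka=d.ka, ks=d.ks, omega=d.omega, n_codons_used=d.n_codons_used
            )
        except (KeyError, SaturationError, AlignmentError):
            rec.update(ka=np.nan, ks=np.nan, omega=np.nan, n_codons_used=0)
        rows.append(rec)
    return pd.DataFrame(rows)


def genetic_load(
    snps: pd.DataFrame,
    gene_start: int,
    gene_end: int,
    panel: pd.DataFrame,
    gerp_col: str = "gerp",
    class_col: str = "snp_class",
) -> float:
    """Average derived deleterious alleles per individual per gene-body bp.

    Deleterious sites are nonsynonymous SNPs with GERP strictly > 0.  ``panel``
    holds per-individual derived-allele counts (rows aligned with ``snps``).
    """
    length = gene_end - gene_start
    if length <= 0:
        raise ValueError("gene length must be positive")
    if panel.shape[1] == 0:
        raise ValueError("genotype panel is empty")
    if len(snps) != len(panel):
        raise ValueError("snps and panel must have the same number of rows")
    deleterious = (snps[class_col] == "nonsyn") & (snps[gerp_col] > 0)
    if not deleterious.any():
        return 0.0
    per_individual = panel.loc[deleterious.to_numpy()].sum(axis=0)
    return float(per_individual.mean()) / length
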