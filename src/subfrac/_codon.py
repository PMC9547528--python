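"""Codon bookkeeping shared by the Ka/Ks estimator and the sequence simulator.

Precomputes, for the standard genetic code:

* per-codon synonymous site fractions (Nei–Gojobori style, mutations to stop
  codons excluded from the denominators), and
* per-codon-pair synonymous/nonsynonymous difference counts, averaged with
  equal weight over all substitution pathways that avoid stop-codon
  intermediates.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))


def is_sense(codon: str) -> bool:
    return codon in CODON_TABLE


def _site_fractions(codon: str) -> tuple[float, ...]:
    """Fraction of synonymous changes at each position of ``codon``.

    Changes that would create a stop codon are dropped from both numerator and
    denominator; each position still contributes exactly one site.
    """
    fracs = []
    aa = CODON_TABLE[codon]
    for pos in range(3):
        syn = 0
        total = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            total += 1
            if CODON_TABLE[alt] == aa:
                syn += 1
        fracs.append(syn / total if total else 0.0)
    return tuple(fracs)


SYN_SITE_FRACTIONS: dict[str, tuple[float, ...]] = {
    c: _site_fractions(c) for c in SENSE_CODONS
}
# total synonymous sites per codon (each codon contributes 3 sites overall)
SYN_SITES: dict[str, float] = {c: sum(f) for c, f in SYN_SITE_FRACTIONS.items()}


@lru_cache(maxsize=None)
def pathway_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous difference counts between two sense codons.

    Single-step differences are classified directly; codons differing at two
    or three positions are averaged with equal weight over the substitution
    orders whose intermediate codons are not stops.  If every order passes
    through a stop, all orders are used (the degenerate fallback keeps the
    counts defined).
    """
    if codon1 == codon2:
        return (0.0, 0.0)
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = codon1
        steps = []
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            if nxt in STOP_CODONS:
                through_stop = True
            current = nxt
        pathways.append((through_stop, steps))
    usable = [steps for stop, steps in pathways if not stop]
    if not usable:
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if CODON_TABLE.get(a) == CODON_TABLE.get(b):
                sd += 1.0
            else:
                nd += 1.0
    sd /= len(usable)
    nd /= len(usable)
    return (sd, nd)


def synonymous_options(codon: str) -> list[tuple[int, str]]:
    """(position, base) single-nucleotide changes that are synonymous."""
    return _options(codon, synonymous=True)


def nonsynonymous_options(codon: str) -> list[tuple[int, str]]:
    """(position, base) single-nucleotide changes that are nonsynonymous
    and do not create a stop codon."""
    return _options(codon, synonymous=False)


@lru_cache(maxsize=None)
def _options_cached(codon: str, synonymous: bool) -> tuple[tuple[int, str], ...]:
    aa = CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            if (CODON_TABLE[alt] == aa) == synonymous:
                out.append((pos, base))
    return tuple(out)


def _options(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    return list(_options_cached(codon, synonymous))
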