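"""Independent brute-force oracles used only by the test suite.

These re-derive the quantities the package computes, from first principles
and with no shared code paths: codon site fractions and pathway enumeration
are recomputed directly from the genetic code; chi-square and t statistics
are evaluated from their textbook formulas.
"""

from __future__ import annotations

import itertools
import math

from Bio.Data.CodonTable import standard_dna_table

_CODE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of non-stop single changes at ``pos`` that are synonymous."""
    syn = total = 0
    for base in "ACGT":
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt in _STOPS:
            continue
        total += 1
        if _CODE[alt] == _CODE[codon]:
            syn += 1
    return syn / total if total else 0.0


def brute_force_ng86(seq1: str, seq2: str):
    """(S, N, Sd, Nd, Ka, Ks) by direct enumeration of every codon pair."""
    s_sites_1 = s_sites_2 = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if not (set(c1) <= set("ACGT") and set(c2) <= set("ACGT")):
            continue
        n_codons += 1
        s_sites_1 += sum(_syn_fraction(c1, p) for p in range(3))
        s_sites_2 += sum(_syn_fraction(c2, p) for p in range(3))
        diff = [p for p in range(3) if c1[p] != c2[p]]
        if not diff:
            continue
        path_counts = []
        for order in itertools.permutations(diff):
            cur = c1
            steps_syn = steps_non = 0
            hit_stop = False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if nxt in _STOPS:
                    hit_stop = True
                if _CODE.get(cur) == _CODE.get(nxt):
                    steps_syn += 1
                else:
                    steps_non += 1
                cur = nxt
            path_counts.append((hit_stop, steps_syn, steps_non))
        usable = [(s, n) for stop, s, n in path_counts if not stop]
        if not usable:
            usable = [(s, n) for _, s, n in path_counts]
        sd += sum(s for s, _ in usable) / len(usable)
        nd += sum(n for _, n in usable) / len(usable)
    s_sites = (s_sites_1 + s_sites_2) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps, pn = sd / s_sites, nd / n_sites
    ks = -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
    ka = -0.75 * math.log(1.0 - 4.0 * pn / 3.0)
    return s_sites, n_sites, sd, nd, ka, ks


def brute_force_chi2(table) -> float:
    """Pearson chi-square statistic from sum((O-E)^2 / E)."""
    (a, b), (c, d) = table
    total = a + b + c + d
    stat = 0.0
    for obs, r, col in ((a, a + b, a + c), (b, a + b, b + d), (c, c + d, a + c), (d, c + d, b + d)):
        exp = r * col / total
        stat += (obs - exp) ** 2 / exp
    return stat


def brute_force_paired_t(x, y) -> float:
    """Paired t statistic from the difference-mean formula."""
    d = [xi - yi for xi, yi in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((di - mean) ** 2 for di in d) / (n - 1)
    return mean / math.sqrt(var / n)
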