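# Methods

This note documents the models, conventions and numerical choices behind
`subfrac`, and what the synthetic validation does and does not demonstrate.

## Genome partitioning

Pericentromeric chromatin in grasses is recombination-suppressed, gene-poor
and repeat-rich. We measure gene density (genes/Mb; a gene is counted in a
window when its *start* lies in it, so sliding windows never double-count a
gene within one pass), repeat length (overlapping repeat bp per window bp)
and recombination rate in 1 Mb windows advancing by 500 kb. Recombination
comes from a piecewise-linear genetic map: the rate on a marker interval is
ΔcM/ΔMb, a window's rate is the interpolated cM difference across it, and a
decreasing cM column is rejected as a map inconsistency.

Segmentation is automatic where curated boundaries are unavailable: starting
from the window containing the centromere midpoint, the pericentromere grows
through every contiguous window whose 5-window running-mean recombination is
below `r_max` (default 1 cM/Mb) and whose repeat fraction exceeds `t_min`
(default: the chromosome's median repeat fraction). The result always tiles
the chromosome as arm1 | peri | arm2 with the centromere inside the
pericentromere. Degenerate cases warn explicitly: thresholds admitting every
window produce a whole-chromosome pericentromere and empty arms; a
centromere window failing the criteria restricts the pericentromere to the
centromere span. These defaults are calibration choices — the criteria are
qualitative in the literature — so `partition_from_boundaries` accepts
explicit intervals to reproduce a manual partition exactly. Features are
classified arm/peri by their midpoint: one unambiguous label per gene, as
the four-category scheme requires.

## Syntelog filtering, categories and blocks

The homoeolog table has one row per outgroup-anchored ancestral gene with
nullable copy ids for the two subgenomes. Rows are removed when flagged as
tandem duplicates (ambiguous retention status), when any retained copy's
outgroup Ks is below 0.05 (too recent to derive from the WGD), when any
copy's ω exceeds 2.0, or when a retained copy lacks Ks/ω ("incomplete");
every removal is logged with its reason. Retained pairs are assigned one of
four categories from the arm/peri class of each copy.

Blocks are maximal runs of consecutive rows (in ancestral gene order) whose
non-null subgenome chromosomes agree on one (chrom₁, chrom₂) pairing;
singleton rows extend any compatible run. Blocks with fewer than five genes
on either side are dropped. A block side's environment is the majority
region of its member genes (the block-level assignment rule is otherwise
underdetermined). Per-block retention follows

    retention_1 = (singletons_1 + WGD) / (singletons_1 + singletons_2 + WGD),

block recombination averages the map rate at the *paired* member genes'
midpoints (singletons are excluded from that paired comparison), and TE
content is summed interval overlap with the block span, total and per TE
class. Reported singleton:WGD ratios are rounded to one decimal in the
"x.y:1" convention; raw counts are always kept alongside.

## Molecular evolution

Ka/Ks uses Nei–Gojobori (1986)-style counting rather than a
maximum-likelihood codon model; acceptance is therefore against an internal
pathway-enumeration oracle and parameter recovery on simulated alignments,
not numerical equality with ML implementations. Conventions:

- Synonymous site fractions per codon position count only substitutions that
  do not create a stop codon (the denominator shrinks accordingly); each
  position still contributes exactly one site, and site totals are averaged
  over the two sequences.
- Codons differing at 2–3 positions are averaged with equal weight over the
  substitution orders whose intermediates are not stops; if every order
  passes through a stop, all orders are used so the counts stay defined.
- Codons containing a gap or non-ACGT character in either sequence are
  skipped entirely; an unmasked in-frame stop is an input error (stops
  introduced by alignment must be pre-masked to gaps).
- Both pS and pN receive the Jukes–Cantor correction d = −¾·ln(1 − 4p/3);
  p ≥ 0.75 raises a saturation error rather than returning a complex value.
  ω is undefined (NaN) when Ks = 0.

ACR divergence K uses plain JC69 on gap-filtered columns — the simplest
defensible model for short non-coding sequence; nothing downstream depends
on the substitution model beyond monotonicity in p.

Genetic load is the panel-mean count of derived alleles at deleterious
sites — nonsynonymous SNPs with GERP strictly greater than 0 — divided by
gene-body length in bp. GERP scores and ancestral-allele polarization are
inputs, not computed here.

## Expression dominance

The horse race: in each tissue, copy 1 dominates a pair iff
`v1 ≥ fold·v2` and `v1 ≥ min_expr` (defaults fold = 2, min_expr = 1 FPKM),
symmetrically for copy 2, else no call. Ties at exactly the fold threshold
count as dominant ("two-fold or greater"). The `min_expr` floor is our
addition: without it a (0, 0) pair would be "dominant" on both sides; it is
configurable. Percentages use all pairs of a category as denominator (the
per-tissue expressed-only alternative is a caller-side filter), so the three
percentages sum to 100; headline numbers average the per-tissue percentages
across tissues. Protein-abundance matrices run through the identical
classifier. Mean-expression comparisons are paired t-tests across pairs of
tissue-averaged values, optionally on log2(x+1).

## Metagene profiles

All profiles anchor at the TSS (upstream flank) and TTS (downstream flank)
in gene orientation and truncate — never discard — flanks at chromosome
ends, tracking per-window gene counts so means use correct denominators.

- TE proportion & 24-nt siRNA: 100 bp windows sliding by 10 bp across 2 kb
  flanks → (2000 − 100)/10 + 1 = 191 windows per side. siRNA windows are
  normalized to TP10M (reads × 10⁷ / uniquely-and-perfectly-mapped library
  size) per gene, then averaged across genes (pooling counts before
  normalization is the rejected alternative; per-gene averaging weights
  genes equally).
- Methylation: weighted level Σ methylated / Σ total read calls over the
  cytosines of the requested context in non-overlapping 50 bp flank windows
  and 40 equal gene-body bins (bin k of a length-L gene spans
  [k·L/40, (k+1)·L/40), reversed for minus-strand genes). Windows with zero
  coverage are excluded from cross-gene means — weighted methylation is
  undefined there, and imputing 0 would bias flanks low.
- Histone marks: log2((treat + 1)/(input + 1)) per window, 100 bp
  non-overlapping flank windows plus the same 40 body bins (fixed-width
  windows across variable-length bodies would not aggregate across genes;
  the flank geometry stays at 100 bp).
- Genes shorter than 40 bp are skipped for body binning with a warning.

Signal tracks are position-indexed (bedGraph-like) tables; a record belongs
to a window when its position falls inside the half-open interval, which
makes window sums exact for per-base records and a ≤bin-width approximation
for binned ones.

## ACR analysis

ACRs are classed by edge distance to the nearest gene: genic (≥1 bp
overlap), proximal (0 < d ≤ 2000 bp — "within 2 kb" read inclusively),
distal (d > 2000). Retention is measured two ways: the near-singleton :
near-WGD ratio per subgenome (ACRs whose nearest gene lacks outgroup
synteny are excluded), and five categories for ACRs with outgroup-syntenic
support — (1) both duplicated copies retained near WGD genes, (2)/(3) only
the subgenome-1/-2 copy near WGD genes, (4)/(5) the same near singletons.
Category-1 ACRs appear once per surviving copy, so 2·n₁(pairs) + n₂ + n₃
equals the near-WGD syntenic count. ACR–ACR and ACR–outgroup homology is an
input table (the defining similarity search is upstream of this package);
the simulator emits ground-truth homology. Chromatin loops are assigned by
anchor midpoints to subgenome × region; loops whose anchors disagree are
tallied "mixed" and left out of the per-region comparison.

## Statistics

χ² on 2×2 tables is Pearson's without continuity correction (the
comparisons live in the thousands-of-genes regime where the correction is
immaterial; it is switchable). Paired/unpaired t-tests define the
degenerate cases the pipeline can produce: identical samples give t = 0,
P = 1; an exactly constant nonzero paired difference reports P = 0.
Benjamini–Hochberg q-values are available as a clearly-labelled extension;
raw P-values are what the report tables carry.

## The synthetic genome

The generator emulates a maize-like paleotetraploid descended from a shared
sorghum-like ancestor, with one config (`SimConfig`) and one seed; identical
config + seed reproduce byte-identical files.

Geography: each chromosome (default 2 per subgenome, 100 Mb) has a central
pericentromeric band (40% of length) with gene density 5/Mb vs 15/Mb in
arms, TE occupancy 0.7 vs 0.3, and recombination 0.2 vs 2.5 cM/Mb (lognormal
interval noise on a 500 kb marker lattice). Ancestral chromosomes are cut
into 28 segments placed in both subgenomes; subgenome-2 segments keep their
relative chromosomal rank up to N(0, 0.05) jitter and move to the other
chromosome with probability 0.15. This yields ~75–85% of pairs sharing a
chromatin environment (the real-data figure is ~72%) and supplies the
pairing breaks that the block builder recovers.

Retention: per-copy loss probabilities are keyed by subgenome × region and
back-derived from observed singleton:WGD ratios via p = r/(1 + r): maize1
0.41 (arm) / 0.47 (peri), maize2 0.63 / 0.69. Fates are allocated by
stratified assignment within each (region₁ × region₂) stratum — realized
fractions match the configured probabilities exactly at simulation scale,
and the seed only permutes which gene draws which fate. This is deliberate
variance reduction: at ~2,200 ancestral genes the planted peri-vs-arm
contrast is within binomial noise under iid draws, and a validation
simulator should make its planted truth recoverable. Loss of both copies is
excluded (probabilities renormalized), so pairs + singletons exactly equal
the ancestral gene count. A small tandem fraction (3%) is flagged and left
for the filter to remove.

Sequences: ancestral CDS are uniform sense codons (default 300 codons,
ATG-initiated). Each surviving copy accumulates Poisson(rate × sites)
synonymous and nonsynonymous events placed by rejection sampling (random
codon/position/base, accepted when the change has the required effect and
creates no stop), so multiple hits and within-codon interactions occur
naturally; planted rates are Ks 0.28/0.32 (maize1/maize2 arms) and 0.24
(peri), Ka 0.045/0.06 (arms) and 0.05 (peri) — the recessive subgenome
evolves faster only in arms, matching the pattern the pipeline should
detect, at maize–sorghum divergence scale but below JC saturation.

Expression: a pair shares a lognormal baseline (log-mean 2, log-sd 1);
40% of pairs whose maize1 copy sits in an arm get a 2.5× maize1 multiplier;
per-tissue lognormal noise (log-sd 0.6) makes the non-dominant subgenome win
a realistic ~14% of races. 24 tissues, 10 protein samples from the same
model.

Chromatin: siRNA (10 bp bins), per-cytosine CHH methylation (5 bp lattice,
~20× coverage) and histone treat/input (100 bp bins) tracks cover each
gene ± 2 kb. Flanking islands are Gaussian bumps centred 200 bp beyond TSS
and TTS (σ = 150 bp); island height is *additive* over background so height
zero is an exact zero-effect limit; maize1 siRNA islands are scaled by 0.7
(shallower, as observed for dominant-subgenome genes). The siRNA library
size is the track's own total, so TP10M values are internally consistent
rather than realistically scaled. ACRs descend from ancestral ACRs near 80%
of genes (genic/proximal/distal mix 0.4/0.3/0.3) and survive per copy with
probability 0.75/0.55 (maize1 arm/peri) vs 0.55/0.45 (maize2); maize1-arm
accessibility scores are scaled 1.35×; ACR sequences evolve by JC at K
0.10–0.14. Loops connect ACRs to their gene's TSS with a 1.5× sampling bias
toward maize1 arms. SNP panels (20 individuals) carry beta-distributed
derived-allele frequencies with a 1.8× multiplier at deleterious sites of
maize2 arm genes.

What the simulator does *not* emulate: read-level data (tracks are count
level), realistic TE taxonomy or insertion-age structure, indels in
alignments, tissue-specific expression programs, linkage between
neighbouring genes' fates, or reference-bias in genotyping. Passing the
end-to-end tests therefore shows that the pipeline's bookkeeping, estimators
and comparisons recover planted truths through the full file-format round
trip — not that the biological defaults are correct for any real genome.

## Problem sizes and determinism

The default simulated genome is 2 chromosomes × 100 Mb per subgenome
(~2,200 ancestral genes, ~500 retained pairs after filtering), chosen so the
complete generate + analyse cycle runs in well under a minute on one CPU;
the test suite uses a 10 Mb toy genome for per-module checks and one
default-size run for the end-to-end signature. All randomness flows from a
single `numpy` Generator seeded from the config; pipelines re-run on the
same inputs byte-reproduce their reports (timing metadata aside).

## Known limitations

- NG86 with equal-weight pathways ignores transition/transversion bias and
  codon frequencies; on real data it will differ numerically from ML
  estimates (expected magnitude: a few percent at these divergences).
- Automatic pericentromere segmentation is threshold-based and snaps to the
  500 kb window grid; curated boundaries should be supplied where available.
- The block builder assumes the input table is ordered by ancestral
  (outgroup) gene position and defines blocks purely by chromosome-pairing
  runs; externally defined block boundaries can be imposed by splitting the
  table beforehand.
- `SignalTrack` indexes whole tracks in memory; tracks far beyond the
  simulated scale (whole-genome per-base real data) would need a
  tabix-backed variant.
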