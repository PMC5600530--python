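# Methods

## Coordinate conventions

All coordinates are 0-based, half-open (BED convention) past the reader
boundary; readers accept a 1-based dialect flag that subtracts one from
start coordinates on input. The transcription start site (TSS) of a gene
is a single base: `start` on the + strand, `end − 1` on the − strand.
Chromosome names are matched exactly (no "chr" prefix normalization).
Interval intersection is half-open throughout: `[a, b)` and `[c, d)`
overlap iff `a < d` and `c < b`, so abutting intervals share zero bases
and a 1 bp intersection is the smallest positive overlap.

Signed offsets from a TSS are strand-aware: `position − TSS` on the +
strand and `TSS − position` on the − strand, so negative always means
upstream in the gene's own orientation. All profiles, nearest-signal and
nearest-state distances use this convention by default; genome-oriented
variants are available behind flags where a user may want them.

## TSS metaprofiles

A profile evaluates total hotspot signal in a sliding window of width
*w* (default 200 bp) at every center offset `c ∈ {−flank, −flank+step,
…, +flank}` (defaults 5000 / 50 bp). In strand space the window at
offset *c* covers offsets `[c − w//2, c + w − w//2)`; the genomic image
of that set is computed per strand (on the − strand this introduces a
one-bp shift, which is the price of keeping the window a contiguous
half-open genomic interval while remaining per-base exact in strand
space).

"Signal in a window" is **score-weighted overlap**: each hotspot
contributes `score × (bp of overlap)`. This reduces to the hotspot's
full `score × length` when the window contains it, degrades
proportionally for partial overlap, and makes non-overlapping tilings
conserve total `score × bp` exactly. The cruder alternative — adding
the full score of every hotspot that touches the window regardless of
overlap length — is available as `mode="any_overlap"`.

Because windows are half-open, exact mirror symmetry under strand
reversal holds in the per-base sense: flipping a gene's strand *and*
mirroring its track around the TSS leaves the profile identical, base
for base (the test suite asserts this form). A pure index reversal of
the profile vector would be off by one base at window boundaries and is
not claimed.

Stratified profiles divide each category's summed profile by the
category's gene count, giving mean signal per gene per window, so
categories of different sizes are directly comparable.

## Co-occupancy and distance geometry

A TSS region is `[TSS − flank, TSS + flank)` clipped at zero (default
flank 5 kb). A region is marked by a track if any hotspot overlaps it by
at least one base. Co-occupancy calls are the 2×2 classification over
two tracks; `marked_total = a_only + b_only + both`.

Nearest-signal distances use hotspot **midpoints** (`⌊(start+end)/2⌋`):
among midpoints within the flanked region, the one minimizing absolute
strand-aware offset is reported with its sign. Exact up/downstream ties
resolve upstream (negative) for determinism. Box statistics per
fold-change group use numpy's linear-interpolation percentiles. Default
group boundaries on log2 fold change: ≥ 3 ("eightfold or higher"),
[1, 3) ("2- to 8-fold"), (−1, 1), and ≤ −1, with the eightfold boundary
assigned to the upper group. The distance analysis filters genes by
length (default ≥ 2 kb) and, by default, to genes whose region carries
both marks; the filter counts at each step are logged at INFO.

Nearest chromatin-state elements are found genome-wide per chromosome
(no flank cutoff) from per-(chromosome, class) sorted midpoint arrays;
the state proximity report drops genes excluded for zero FPKM in both
conditions and reports signed medians by default (absolute distances via
`signed=False`). Classes 3 and 12 carry the labels "poised_promoter"
and "repressed_region"; all 15 classes are reported.

Feature-class enrichment partitions the genome into promoter
(strand-aware `[TSS − 2000, TSS + 500)` by default, taking precedence),
genic (merged gene bodies minus promoters) and intergenic (the rest);
`enrichment = (fraction of score×bp signal in class) / (fraction of
genome bp in class)`. A uniform track therefore scores exactly 1.0
everywhere, and class ratios weighted by genome fraction average to 1
whenever all signal is classified. The three-way partition is the
default; the promoter definition is a parameter.

## Response classification

`log2 FC = log2(FPKM_treated) − log2(FPKM_control)`, with a pseudocount
(default 0.01 FPKM) added to **both** values only when exactly one is
zero; genes with zero FPKM in both conditions are excluded and carry no
fold change. Thresholds are boundary-inclusive on both sides: an exact
twofold increase is "up" and an exact twofold decrease is "down" (the
symmetric reading of a twofold criterion). Up/down fractions are
computed over non-excluded genes.

Basal-expression strata default to a dedicated zero stratum plus
half-open log10 FPKM decades [−4,−2), [−2,0), [0,2), [2,∞); nonzero
values below 10⁻⁴ are folded into the lowest stratum (operationally
indistinguishable from silenced). The silenced/active two-bin split
defaults to control FPKM in [10⁻⁴, 1) vs ≥ 1. Empty strata report an
undefined (NaN) frequency, never zero.

Venn region counts are exact set algebra over all 2^k − 1 membership
patterns. When classified tables with differing gene universes are
supplied, a warning reports the symmetric-difference size and counts are
taken over the intersection universe; raw gene-id collections carry no
universe and skip the check.

## qPCR arithmetic

* expression level relative to a reference gene:
  `2^(Cp_ref − Cp_gene)`;
* log2 fold change: `log2(level_treated / level_mock)`;
* plasmid-expression scaling: per-timepoint quotients
  `value_t / value_reference` (exactly 1 at the reference timepoint),
  applied multiplicatively to gene log2 fold changes. The quotient
  formula is implemented literally as the source protocol states it,
  with the quotient exposed so users can substitute their own
  compensation scheme;
* input adjustment: `Cp_input − log2(factor)` with factor default 20
  (20 % of the chromatin prep sampled, as printed in the protocol; a
  user reading "20 % input" as a 5× correction can pass factor 5);
* `%IP = 100 × 2^(Cp_input_adj − Cp_IP)`, not clamped at 100 % —
  over-recovery is a real measurement outcome and is reported as-is;
* enrichment = %IP − %mock-IP, preserved when negative;
* dose–response association: Pearson product-moment r and r², requiring
  ≥ 3 doses and nonzero variance.

Replicate Cp values are averaged per (sample, target, role, timepoint)
before any of the above.

## The synthetic epigenome

The generator plants the geometry the analyses are designed to detect,
so recovery is a meaningful end-to-end check:

* **Layout** — genes are placed at fixed 20 kb TSS spacing (configurable)
  on equal-length chromosomes, bodies 1–10 kb, random strand; spacing at
  least the maximum gene length is enforced, and an infeasible
  (n_genes, chrom_length) combination raises a configuration error
  rather than overlapping windows.
* **Response classes** — multinomial over up_strong / up_moderate /
  no_change / down with default probabilities 0.05 / 0.10 / 0.75 / 0.10,
  giving ~15 % up- and ~10 % down-regulated genes overall, the skew
  typical of effector-perturbation transcriptomes. Class-conditional
  log2 fold changes are N(3.5/2.0/0/−2.0, 0.3); the emitted expression
  table equals basal FPKM times 2^(true log2 FC) exactly, so the planted
  value is recoverable to floating precision. Basal FPKM is log-uniform,
  with up classes drawn from the silenced range (log10 ∈ [−4, 0)) and
  others from [−2, 2), reflecting that reactivation targets start from
  low expression.
* **Mark geometry** — each marked gene gets one repressive-mark hotspot
  (width 400 bp, log-normal(μ=1, σ=0.5) score; widths and score scales
  are free choices, as any positive values support recovery testing)
  whose midpoint offset is drawn from a class-conditional normal:
  up_moderate N(−2500, 300), up_strong N(−1300, 300), no_change and
  down N(−500, 200) — distal upstream marks at up-regulated genes,
  TSS-proximal marks at non-responders. Mark-presence probability per
  class defaults to 1.0 / 1.0 / 0.7 / 0.9 so that unmarked and
  singly-marked regions exist.
* **TSS depletion** — offsets are re-drawn until their absolute value
  exceeds `tss_depletion_halfwidth` (default 300 bp, boundary
  inclusive). 300 = window/2 + hotspot_width/2 guarantees the window at
  offset zero is mark-free, producing the nucleosome-free-region valley
  in aggregate profiles. The depletion applies to every mark placement;
  class distributions are therefore truncated normals — negligible for
  the distal up classes, and shifting the proximal classes' medians by
  under 50 bp, well inside the recovery tolerances. After 1000 rejected
  draws (only possible for pathological configurations) the offset is
  clamped to the zone boundary.
* **Effector** — a hotspot spanning the TSS with class-conditional
  probability (0.9 for up classes, 0.1 / 0.2 for no_change / down).
* **Segmentation** — chromosomes tiled with 2 kb elements drawn from the
  13 background states; one class-3 and one class-12 element planted per
  gene at N(−1500, 400) for responsive (up or down) genes and
  N(−8000, 2000) for non-responders, so state-proximity medians order
  responsive < non-responsive.
* **Cp tables** — `Cp_gene = Cp_ref − log2(level) + N(0, noise_sd)`; at
  zero noise the qPCR arithmetic recovers planted expression ratios and
  IP fractions exactly.

Everything is driven by one `numpy` Generator seeded from the config, so
identical configurations produce byte-identical output files.

What the generator does **not** emulate: read-level noise and coverage
variation, mappability and GC bias, fragment-size effects, broad
Polycomb domains (each gene carries at most one compact mark hotspot),
overlapping or nested genes, multiple transcripts per gene (inputs are
pre-flattened to one row per gene, so the TSS choice among transcripts
is an upstream decision), replicate structure in expression tables, and
inter-gene correlation. Passing recovery tests therefore demonstrates
the correctness of the interval geometry and arithmetic, not robustness
to sequencing artefacts.

## Problem sizes and tolerances

Unit and property tests run on small fixtures (≤ 50 intervals, ≤ 5 kb
spans) where per-base brute-force references are affordable; oracle
agreement is required to 1e-9 (window signal) or exactly (nearest
queries, set algebra). Recovery checks use a balanced four-class design
of 1200 genes (~300 per class), at which the planted medians are
recovered within ±100 bp and stratified-profile maxima within one step
(50 bp). The acceptance script uses the same sizes plus a 2000-gene run
at the default skewed class mix for response fractions. The full-suite
runtime is a few seconds on one CPU.

## Known limitations

* The one-bp minus-strand window shift means genome-oriented and
  strand-oriented profiles of the same data differ by one base at
  window boundaries; all aggregate conclusions are unaffected.
* `BoxStats` quartiles follow numpy's default linear interpolation;
  spreadsheet quartile conventions may differ slightly at small n.
* `feature_class_enrichment` merges overlapping gene bodies before
  partitioning, so per-gene attribution inside merged clusters is not
  available.
* The scaling-quotient compensation multiplies later-timepoint fold
  changes by quotients ≤ 1 when effector expression decays; whether
  that is the intended direction of compensation is a question about
  the protocol itself, so the implementation is literal and the factor
  is exposed.
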