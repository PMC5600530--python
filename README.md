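# epibridge

Promoter-epigenome analysis for effector/H3K27me3 geometry: TSS-centered
ChIP hotspot metaprofiles, promoter co-occupancy classification,
strand-signed nearest-signal distance statistics, chromatin-state
proximity, and qPCR/ChIP-qPCR quantification — with a synthetic-data
generator that plants known ground truth for every stage.

## The problem

Synthetic transcription factors that *read* histone marks — for example a
fusion of the Polycomb chromodomain (an H3K27me3 reader) with the VP64
activation domain — can reactivate silenced genes. Whether a given gene
responds appears to depend not merely on the *presence* of the silencing
mark near the promoter, but on its *position*: responsive genes tend to
carry H3K27me3 one to a few kilobases upstream of the transcription start
site (TSS) while the effector itself accumulates at the nucleosome-free
region at the TSS, suggesting a bridging interaction between a distal
mark and the transcription-initiation machinery.

Testing that "distal mark, proximal binding" picture from sequencing data
requires a small set of interval-geometry and quantification primitives,
which this package implements as a reusable, tested library:

* **TSS metaprofiles** — total hotspot signal in a sliding window
  (default 200 bp wide, 50 bp step) across ±5 kb around each TSS,
  aggregated in gene orientation and optionally stratified by gene
  category with per-category normalization. Signal is score-weighted
  overlap: each hotspot contributes `score × (bp of window overlap)`.
* **Co-occupancy** — a TSS region (±5 kb) counts as marked by a track if
  any hotspot overlaps it by ≥ 1 bp (half-open interval arithmetic);
  regions are classified as marked by the effector, the histone mark,
  both, or neither.
* **Nearest-signal distances** — the strand-aware signed offset (negative
  = upstream) of the nearest hotspot *midpoint* to each TSS, summarised
  per fold-change response group as box statistics (n, median, quartiles,
  extremes), after filtering genes by length (≥ 2 kb) and, optionally,
  co-occupancy.
* **Chromatin-state proximity** — per 15-state segmentation class
  (class 3 "poised promoter", class 12 "repressed region"), the signed
  distance of the nearest element midpoint to each TSS, with medians per
  state × response group.
* **Transcriptional response** — genes classified from control/treated
  FPKM as up (≥ twofold, boundary inclusive), down (≤ half), no-change,
  or excluded (FPKM zero in both); exact Venn-region set algebra across
  cell lines; stratification by basal expression.
* **qPCR arithmetic** — expression level `2^(Cp_ref − Cp_gene)`, log2
  fold change of treated vs mock levels, plasmid-expression scaling
  quotients, percent-input ChIP-qPCR
  `%IP = 100 × 2^(Cp_input_adj − Cp_IP)` with the input Cp adjusted by
  `−log2(20)` for a 20 % input sample, mock-IP subtraction, and Pearson
  dose–response correlation.

## Worked example

Simulate a 400-gene epigenome at the default study conditions (up-regulated
genes carry a mark hotspot ~2.5 kb or ~1.3 kb upstream; non-responders
carry it ~0.5 kb from the TSS; mark midpoints are excluded from ±300 bp
around the TSS), then run the analyses:

```python
import pandas as pd
from epibridge.synthetic_data import SimConfig, simulate_epigenome
from epibridge.expression_response import classify_table, response_summary
from epibridge.occupancy_geometry import (cooccupancy, distance_stats_by_group,
                                          nearest_signal_distance, fold_change_group)
from epibridge.tss_profiling import ProfileParams, tss_profile

sim = simulate_epigenome(SimConfig(seed=0))
classified = classify_table(sim.expression)
s = response_summary(classified)
print(f"{s.n_total} genes: {s.counts['up']} up ({s.fraction_up:.1f}%), "
      f"{s.counts['down']} down ({s.fraction_down:.1f}%)")

calls, counts = cooccupancy(sim.genes, sim.effector_track, sim.k27_track)
print(f"marked TSS regions: {counts['marked_total']} (both marks: {counts['both']})")

lfc = dict(zip(classified.gene_id, classified.log2_fc))
cooc = {c.gene_id: c.occupancy_class == "both" for c in calls}
records = pd.DataFrame(
    [(g.gene_id, nearest_signal_distance(g, sim.k27_track), g.length,
      fold_change_group(lfc[g.gene_id]), cooc[g.gene_id]) for g in sim.genes],
    columns=["gene_id", "signed_distance", "gene_length", "response_group", "cooccupied"])
for group, bs in distance_stats_by_group(records).items():
    if bs:
        print(f"{group:>12}: n={bs.n:3d} median={bs.median:8.1f} bp")

prof = tss_profile(sim.k27_track, sim.genes, ProfileParams())
at_zero = float(prof.signal[prof.offsets == 0][0])
print(f"H3K27me3 signal at TSS (offset 0): {at_zero:.1f}; "
      f"profile max {prof.signal.max():.1f} at {prof.argmax_offset()} bp")
```

prints

```
400 genes: 58 up (14.5%), 50 down (12.5%)
marked TSS regions: 319 (both marks: 74)
  up_8x_plus: n= 12 median= -1155.5 bp
    up_2x_8x: n= 30 median= -2544.5 bp
   no_change: n= 18 median=  -568.5 bp
down_2x_plus: n=  9 median=  -564.0 bp
H3K27me3 signal at TSS (offset 0): 0.0; profile max 111996.6 at -550 bp
```

Reading the output: among co-occupied genes ≥ 2 kb long, the 2–8-fold
up-regulated group carries its nearest H3K27me3 midpoint a median
~2.5 kb upstream and the ≥ 8-fold group ~1.2 kb upstream, whereas
non-responding and down-regulated genes have the mark within ~0.6 kb of
the TSS — the planted distal-vs-proximal geometry, recovered from the
emitted tracks. The aggregate mark profile is zero in the window at the
TSS (the nucleosome-free-region valley) and peaks upstream.

The same pipeline is available from the shell:

```bash
epibridge simulate --seed 0 --outdir sim/
epibridge response --expression sim/expression.tsv --outdir resp/
epibridge profile --genes sim/genes.bed --track sim/k27_hotspots.bed \
    --stratify-by resp/classified_expression.tsv --out profile.tsv
epibridge occupancy --genes sim/genes.bed --track-a sim/effector_hotspots.bed \
    --track-b sim/k27_hotspots.bed --expression sim/expression.tsv \
    --segmentation sim/segmentation.bed --outdir occ/
epibridge qpcr --cp-table cp.csv --outdir qpcr/
```

## Layout

```
src/epibridge/
  genomic_io.py           readers/writers, coordinate convention, domain types
  synthetic_data.py       planted-ground-truth epigenome and Cp simulators
  qpcr_quant.py           ΔCp expression, fold change, %IP, scaling, correlation
  expression_response.py  response classification, Venn sets, basal strata
  tss_profiling.py        sliding-window TSS metaprofiles
  occupancy_geometry.py   co-occupancy, nearest-signal/state distances, enrichment
  cli.py                  simulate / qpcr / response / profile / occupancy
docs/methods.md           model, parameters, numerical choices, limitations
```
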