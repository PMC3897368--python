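# h3k4diff

Differential H3K4Me3 ChIP-seq analysis at desk scale.

H3K4Me3 (trimethylation of lysine 4 on histone H3) marks the transcription
start sites (TSS) of active genes. Comparing its genome-wide enrichment
between two genotypes — for example wild-type pancreatic acinar cells
against a chronically stressed knockout — reveals *epigenetic
reprogramming*: promoters that gain or lose the mark even when steady-state
expression is unchanged. `h3k4diff` implements the complete post-alignment
side of such a study for epigenomics researchers and method developers:

* **Peak calling** — a window-Poisson caller over paired treatment/input
  fixed-step coverage tracks. The control is scaled to treatment depth,
  the per-bin rate is `λ = max(local 1-kb mean, local 10-kb mean,
  genome-wide mean)` of the scaled control, and a bin is significant when
  the upper Poisson tail `P(X ≥ k; λ) ≤ 1e-5`. Peaks carry a summit, an
  amplitude (maximum pileup height) and the browser score `−10·log10 p`.
* **Genomic annotation** — strand-aware classification of each peak as
  upstream (≤ 2 kb 5′ of a TSS), intragenic, downstream (≤ 2 kb 3′ of a
  TES) or intergenic (≥ 2 kb from any gene), CpG-island association,
  per-chromosome peak densities, and TSS/TES metagene profiles.
* **Differential enrichment** — genes are *called* when a peak lies within
  1 kb of their TSS; differences come in two disjoint tiers:
  *unique* (called in exactly one genotype) and *preferential*
  (amplitude ratio ≥ 2 with max amplitude ≥ 10 within 1 kb of the gene).
* **Expression integration** — overlap of the enrichment tiers with a
  differential-expression table (fold ≥ 1.5, p < 0.01,
  direction-matched), plus plain gene-list export for pathway tools.
* **Bench validation arithmetic** — ChIP-qPCR percent of input with
  explicit input-dilution correction, ΔΔCt relative expression, and
  exact-permutation Mann-Whitney / Welch t comparisons with Bonferroni
  correction.
* **Synthetic data** — a fully seeded generator that plants a
  two-genotype peak landscape (category mix, CpG co-location, unique and
  preferential differences, partially concordant expression) together
  with its ground truth, so the entire pipeline is testable end to end on
  a laptop.

## Worked example

Simulate a 10-Mb genome with 300 genes, 10 unique and 15 preferential
genes planted per genotype, then run the full pipeline:

```bash
h3k4diff simulate --seed 42 --outdir sim
h3k4diff callpeaks --treatment sim/treatment_wt.wig --control sim/control_wt.wig --out wt.bed
h3k4diff callpeaks --treatment sim/treatment_ko.wig --control sim/control_ko.wig --out ko.bed
h3k4diff annotate  --peaks wt.bed --genes sim/genes.bed --cpg sim/cpg_islands.bed \
                   --out annotated.bed --summary summary.json
h3k4diff diff      --wt wt.bed --ko ko.bed --genes sim/genes.bed \
                   --out diff.tsv --summary diff_summary.json
h3k4diff integrate --diff diff.tsv --expr sim/expression.tsv --out overlap.json
```

which prints (seed 42):

```
simulated 300 genes, 396/396 wt/ko peaks -> sim
396 peaks -> wt.bed
396 peaks -> ko.bed
{"upstream": 72.5, "intragenic": 7.3, "downstream": 8.6, "intergenic": 11.6}
{... "called_wt": 290, "called_ko": 290,
     "unique_wt": 10, "unique_ko": 10,
     "expanded_wt": 25, "expanded_ko": 25, ...}
```

Reading: 396 peaks are re-called per genotype from the coverage tracks;
~73% of them sit within 2 kb upstream of a TSS; 290 genes are
H3K4Me3-called per genotype, and the differential tiers recover exactly
the planted 10 unique and 15 preferential genes per genotype
(`expanded = unique + preferential = 25`).

The same summary arithmetic can audit published counts without any data:

```bash
echo '{"called_wt": 12280, "called_ko": 12123, "unique_wt": 519,
       "unique_ko": 362, "expanded_wt": 769, "expanded_ko": 625}' > counts.json
h3k4diff diff --audit-counts counts.json
# -> unique_pct_wt 4.2, unique_pct_ko 3.0, expanded_pct_wt 6.3, expanded_pct_ko 5.2
```

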