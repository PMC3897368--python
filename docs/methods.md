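# Methods

## The analysis model

`h3k4diff` analyses H3K4Me3 ChIP-seq for two genotypes after alignment.
All coverage is binned at a fixed step (default 50 bp, matching the
wiggle spacing of MACS-style callers) with reads extended to the library
fragment length (default 300 bp, tag size 49 bp). The pipeline stages and
their decision rules are:

1. **Peak calling.** The input (control) track is linearly scaled to the
   treatment depth (`total_reads_t / total_reads_c`). For every bin the
   background rate is `λ = max(mean_1kb, mean_10kb, mean_genome)` of the
   scaled control — the local-rate idea of MACS, with the genome-wide
   mean as a floor so unsequenced regions never produce a zero rate. A
   bin with treatment count `k` is significant when the upper Poisson
   tail `P(X ≥ k; λ)` is at or below the p-value threshold (default
   1e-5). Significant bins are merged across gaps of at most one bin
   (50-bp quantization otherwise fragments single summits), and merged
   stretches shorter than the fragment extension (300 bp) are dropped.
   Summit = the middle of the tied maximal significant bins (centred and
   strand-unbiased for flat-topped peaks); amplitude = maximum treatment
   pileup inside the peak; score = `−10·log10 p` at the summit, capped at
   3100 (configurable) when `p` underflows double precision. MACS's
   fragment-model estimation is *not* reproduced: extension is a
   configuration value, and the mfold bounds are accepted and only used
   to warn when no region reaches the lower bound. A bandwidth parameter
   is accepted and logged but has no role in this window caller.

2. **Annotation.** Each peak receives exactly one category by summit
   position with priority upstream > intragenic > downstream >
   intergenic, strand-aware ("upstream" is 5′ of the TSS on the gene's
   strand; windows default to 2 kb). Intergenic status additionally
   requires the whole peak interval to lie ≥ 2 kb from every gene
   interval; the rare wide peak whose body is proximal while its summit
   escapes every window is assigned to its nearest gene's flank, keeping
   the partition total. The priority order resolves peaks near short
   genes in favour of the TSS, which carries the headline statistic.
   CpG association counts a peak as island-associated on ≥ 1 bp interval
   overlap, and is therefore invariant to island fragmentation and peak
   order. Chromosome densities are peaks per megabase, including
   zero-count chromosomes. Metagene profiles aggregate signal over
   `[TSS−flank, TSS)`, the gene body rescaled to `n_body_bins` by linear
   interpolation, and `(TES, TES+flank]`, reversing minus-strand genes;
   genes longer than `n_body_bins · step` or without complete flanks
   inside the track are excluded with a logged count, so `n_body_bins`
   should be chosen to cover the longest gene of interest (default 300 =
   15 kb at 50 bp).

3. **Differential enrichment.** A gene is *called* when a peak interval
   comes within 1 kb of its TSS; all distances are measured between
   covered bases, and the 1-kb boundary is inclusive ("within one
   kilobase" reads as ≤). *Unique* genes are the strict set difference of
   the two call sets. For shared genes, peaks are matched across
   genotypes when their intervals overlap or their summits lie within
   one bin; a gene is *preferential* when any matched pair within 1 kb of
   its gene interval (the body, deliberately looser than the TSS-based
   call rule) has amplitude ratio ≥ 2 — inclusive at exactly 2 — with the
   larger amplitude ≥ 10. Unique beats preferential, so the five statuses
   partition the union of the call sets. Percentages in summaries are
   rounded half-up to one decimal, the convention of printed tables.

4. **Expression integration.** A gene is differentially expressed toward
   a genotype when its fold change is ≥ 1.5 (inclusive) and its p-value
   is < 0.01 (strict). Overlaps with the enrichment tiers are
   direction-matched: a gene counts only when its higher-expression
   genotype equals its enrichment genotype. Published DE totals can be
   audited from counts alone; the package never re-derives them from raw
   microarray data.

5. **qPCR arithmetic.** Percent of input corrects the input Ct for the
   chromatin dilution: `adjusted = mean(Ct_input) − log_E(1/f)` with
   efficiency `E` (default 2.0, perfect doubling) and input fraction `f`
   (mandatory and explicit — defaulting to undiluted input would inflate
   every recovery). IgG is reported alongside, never subtracted.
   Relative expression is standard ΔΔCt against a named calibrator with a
   required reference gene. Two-group comparisons use the Mann-Whitney U
   with a fully enumerated permutation null for combined n ≤ 12 (exact
   even under ties; two-sided p is the permutation fraction with
   `|U − n₁n₂/2|` at least the observed) and the tie-corrected normal
   approximation above; t tests are two-tailed unpaired Welch. Bonferroni
   adjustment is `min(1, p·m)`.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not raw sequencing: there are no FASTQ reads, alignment errors,
duplicates or mappability gaps, and H3K27Me3-style broad domains are out
of scope. Defaults describe the study conditions used throughout the
tests: one 10-Mb chromosome, 300 genes of 2–15 kb placed non-overlapping
with ≥ 5-kb gaps (so each peak has one defensible category and 1- and
2-kb windows never straddle two genes), 10 unique and 15 preferential
genes per genotype at planted fold 3, and 30,000 reads per track.

* **Category mix.** Peak counts follow the genome-wide proportions
  observed for this mark (74.1% upstream / 6.3% intragenic / 8.3%
  downstream / 11.3% intergenic). Every enriched gene carries one
  TSS-proximal peak (summit 100–500 bp 5′ of the TSS); intragenic,
  downstream and intergenic peaks are landscape texture shared by both
  genotypes.
* **CpG islands.** Islands (±500 bp) cover 94% of TSSs, chosen so the
  genome-wide island association of peaks lands near the observed 74%;
  intergenic peaks are placed on a dedicated intergenic island with
  probability 0.401 and in island-free space otherwise. The per-peak flag
  is recorded in the truth table.
* **Amplitudes.** Log-normal with median 30 and σ = 0.4, with a
  detectability floor of 18 at the default depth. The floor is a
  deliberate design choice: the generator's contract is that planted
  truth is *exactly* recoverable (the recovery tests demand set equality,
  not approximate recall), which is only well-posed if no planted peak is
  marginal against the Poisson background. Real data of course contain
  marginal peaks; passing recovery tests therefore demonstrates the
  correctness of the decision rules, not the sensitivity of the caller at
  the detection limit. Preferential pairs are built as
  `low = max(draw, 10/fold)`, `high = fold · low`, so the planted ratio
  is exactly the configured fold and the larger amplitude satisfies the
  ≥ 10 rule. Shared genes get one base amplitude jittered independently
  per genotype (±10% multiplicative, log-uniform; set
  `amplitude_jitter = 0` for exact-recovery experiments).
* **Coverage.** Signal fragments are stacked exactly at the summit, so a
  planted peak is a rectangle of `extension + step` bp whose height
  equals its amplitude — planted amplitude is exactly recoverable and the
  calling geometry is noise-free, while uniform background reads supply
  Poisson texture. `reads_per_condition` is the total depth per track:
  the control is uniform background at full depth; the treatment spends
  its depth on signal first and background for the remainder, giving a
  depth-scaling factor near 1. Read-position dispersion around summits is
  *not* emulated.
* **Expression.** A `de_concordance` fraction (default 0.11, the
  observed order of magnitude for this contrast) of differentially
  enriched genes receive fold ≥ 1.5 with p < 0.01 in the direction of
  their enrichment; all other genes are null (fold ≈ 1, uniform p), so
  DE status never arises among unchanged genes by construction.
* **Determinism.** Every output is a pure function of the configuration;
  per-component streams are derived from the seed with fixed offsets
  (`numpy.random.default_rng([seed, offset])`), so adding a generator
  never perturbs earlier outputs, and identical seeds give byte-identical
  BED/WIG/TSV serializations.

## Numerical choices

* Poisson tails come from `scipy.stats.poisson.sf` (log-space at the
  summit for the score); the test suite checks them against a direct
  summation of the mass function to 1e-12 relative error wherever the
  tail is representable in double precision.
* Fractional bin values are rounded up before the tail test (a bin with
  pileup k is at least as surprising as ⌈k⌉ − 1 events are common).
* WIG values serialize via `repr` (integers as integers), making
  read∘write bit-stable; peaks serialize as BED6+3 with the full-precision
  score in the ninth column and the p-value recovered as `10^(−score/10)`.
* Percentages use decimal half-up rounding, not banker's rounding, to
  match printed tables.
* Empty denominators (no peaks in a filtered category, an empty DE set, a
  zero called-gene total) raise an undefined-statistic error instead of
  reporting 0, so absence of data is never confused with a zero rate.

## Problem sizes used in tests

The default test suite and the acceptance script run the full pipeline on
the 10-Mb / 300-gene configuration (about 400 peaks and 200k bins per
track, a few seconds end to end), the oracle-equivalence checks on
20 × 1000 random peaks, and the null-calibration of the Poisson test on
10⁶–1.2 × 10⁶ bins. These sizes keep every property testable at desk
scale while leaving the decision rules identical to a genome-scale run.

## Known limitations

* The caller has no duplicate filtering, paired-end support, control-swap
  FDR or BAM input; it consumes binned fixed-step tracks only.
* Cross-genotype peak matching (overlap or one-bin summit distance) is a
  formalization of what the original visual browser comparison left
  unstated; genuinely shifted summits beyond one bin at non-overlapping
  intervals would not be matched.
* The generator's detectability floor means recovery statistics say
  nothing about behaviour on marginal peaks; lower the floor and raise
  `amplitude_jitter` to study degradation.
* Pathway enrichment over curated knowledge bases is out of scope; the
  package exports plain gene lists instead.
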