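# Methods

This note documents the models and numerical choices behind `dipscan`:
what each stage computes, why the defaults are what they are, what the
simulator does and does not emulate, and what passing the test suite does
and does not establish about real data.

## Coordinates, windows and counting

All internal coordinates are 0-based half-open (BED convention); GTF and
SAM are converted at the I/O boundary. A window grid tiles each
chromosome with fixed-width windows (200 bp default, the resolution at
which hydroxymethylation enrichment is conventionally smoothed); the last
window is truncated at the chromosome end rather than dropped, so no base
is silently excluded, and a sliding grid (step < width) is supported with
the same guarantee.

Each mapped read contributes to exactly one window — the window containing
its alignment midpoint (`start + aligned_length // 2`; on a sliding grid,
the right-most containing window, which keeps the assignment a partition).
Midpoint assignment was chosen over overlap counting because it conserves
totals (`sum(window counts) + skipped = mapped reads`), which makes every
downstream normalization exact and testable; with 200 bp windows and
~140 bp reads the practical difference from overlap counting is marginal.
Reads on chromosomes absent from the grid are tallied, not fatal.

Depth normalization is counts-per-million. Enrichment is
`log2((IP_cpm + c) / (input_cpm + c))` with pseudocount `c = 0.5`
(configurable): windows empty in both samples get exactly 0 and are
retained, so grids stay comparable across samples and conditions.

## Read QC and the 50 bp cutoff

Semiconductor-style libraries are diagnosed by their read-length
distribution: a healthy run has most reads above 100 bp with a mean
around 125–150 bp, while adapter carry-over and degraded input accumulate
below 50 bp, where mapping accuracy collapses. The QC report histograms
query lengths (10 bp bins — fine enough to resolve the 50 bp boundary and
the 125–150 bp mode) and computes mapping rate per bin on the unfiltered
stream; the exclusion filter is applied downstream and is strict
("shorter than 50 bp"): a 50 bp read passes. Filtering acts on query
length, not aligned length, since the diagnostic concerns the sequenced
fragment. Duplicate-flagged alignments (0x400) are excluded everywhere by
default because low-cycle whole-genome amplification inflates duplicate
rates; `include_duplicates=True` retains them.

## Peak calling

Window-level testing: IP count against
`Poisson(max(input_i × N_IP / N_in, λ0))` (one-sided upper tail), with a
background floor `λ0 = floor_fraction × N_IP / n_windows`
(`floor_fraction = 0.1`) that prevents zero-coverage input windows from
producing unbounded significance. p-values are BH-adjusted across all
windows; significant windows require both `q ≤ alpha` (0.05) and a log2
CPM ratio ≥ `min_log2` (1.0, i.e. two-fold), so statistical significance
at high depth cannot promote a biologically negligible excess. Runs of
adjacent significant windows merge into peaks carrying the maximum window
log2 ratio and the minimum q. This window-Poisson + BH + merge scheme is
the standard approach for windowed DIP-seq enrichment; every constant is
exposed. No local-lambda estimation, broad/narrow dual modes or
differential calling are attempted — condition contrasts are handled as
difference tracks.

## Compartment annotation

Peaks map to one of five compartments by their midpoint with strict
precedence promoter core > promoter proximal > promoter distal >
intragenic > intergenic. Promoter zones are symmetric around every
annotated TSS (core ± 500 bp, proximal ± 2 kb, distal ± 10 kb by
default — radii are conventions of this package, chosen to be well-ordered
and configurable, not a reconstruction of any published scheme), and they
take precedence over gene-body overlap, so a point 1.5 kb into a gene is
promoter-proximal, not intragenic. Midpoint classification guarantees one
label per peak, which makes the compartment distribution an exact
partition (percentages sum to 100). Gene models are per-gene transcript
unions; no isoform or exon/intron substructure is used.

## Concordance and metagene profiles

Replicate and cross-platform agreement is computed as Pearson r over a
large random sample of windows (500k by default, without replacement,
seeded); R² is reported as r², which is symmetric and avoids choosing a
regression direction. The multi-sample correlation matrix is clustered by
average linkage on distance 1 − r with scipy's deterministic leaf
ordering. Correlations are computed on the tracks' stored units, which are
recorded in the output.

Metagene profiles divide each gene body into 100 equal bins and each
flank — 25% of the body length — into 25 bins, so every bin within a gene
has the same genomic width. Per-bin values are exact length-weighted means
of the piecewise-constant window signal (computed from a cumulative
integral, so profile linearity holds to rounding error); minus-strand
genes are reversed so bin 0 is always 5′; flank bins extending past a
chromosome end are dropped for that gene only, with per-bin gene counts
reported. The profile is the unweighted mean over genes.

## The generative model

The simulator reproduces the enrichment protocol stage by stage on a
synthetic genome:

1. **CpG sites**: Poisson process, mean spacing 100 bp (mammalian
   genome-wide CpG density scale).
2. **Marking**: each site carries the modification with probability
   `hmc_fraction` (default 0.02, inside the 0.1–7% range reported for
   non-CNS mammalian tissues) times a per-region multiplier, capped at 1.
   Planted regions are gene-body-sized (20 kb in the bundled
   configuration) with multipliers spanning 8–44, i.e. marking from ~16%
   to ~88% of regional CpGs.
3. **Fragmentation**: uniform starts; truncated-normal lengths,
   mean 300 bp, sd 75 bp, support [100, 500] bp (sheared genomic DNA).
4. **Input reserve**: 10% of fragments, taken before capture.
5. **Capture**: a fragment with `k` marked sites is retained with
   probability `1 − (1 − e)^k` (`e = 0.85`), or with the nonspecific rate
   0.05 when unmarked. Independent per-site binding is a tractability
   choice, not a claim about antibody chemistry; it makes the closed-form
   oracle below exact.
6. **Amplification**: every retained fragment receives `2^10` expected
   copies, modulated by a per-fragment lognormal efficiency
   (sd 0 = unbiased default). Expectation scaling was chosen over
   cycle-by-cycle branching: it reproduces the bias structure at a
   fraction of the cost.
7. **Size selection**: fragments kept in [100, 250] bp (library-stage
   bead selection).
8. **Sequencing**: the library is multinomially resampled to the
   requested depth (200k reads per sample by default); extra copies of a
   fragment are flagged as duplicates the way a post-alignment dedup step
   would mark them. Reads start at a uniformly random end of the fragment
   (the post-WGA library is double-stranded) with length
   `min(fragment, truncnorm(137, 15))`, mapq 60, and an optional
   adapter-contamination mode that replaces a fraction of reads with
   15–49 bp stubs for QC testing.

All draws flow through one seeded generator; identical config and seed
give byte-identical SAM text.

**Pool sizing.** The default pre-selection pool is 12 million fragments.
The protocol's losses multiply: 10% input reserve, ~10% capture at 2%
marking, and ~25% surviving size selection leave roughly 2–3% of fragments
in each final library. A real library prepared from hundreds of nanograms
of DNA starts from ~10⁹ fragments, so sampled reads are essentially all
distinct; 12M is the smallest pool for which the 200k-read libraries
remain majority-distinct (~25% duplicates, a realistic rate for 10 WGA
cycles) rather than duplicate-dominated. Named configurations
(`default_config`, `null_config`, `oracle_benchmark_config`,
`replicate_config`) fix the study conditions used by the test suite and
the acceptance script; their genome sizes were set by power analysis
(e.g. the null genome gives ~25 distinct reads per window at 100k reads,
deep enough that log-ratio small-count bias is negligible; the replicate
genome provides the 50k windows the concordance analysis samples).

**Closed-form oracle.** `expected_window_enrichment` computes, per
window, the capture probability averaged over fragment midpoints in the
window and over the post-selection fragment-length distribution (numeric
integration: 8 midpoint offsets, 10 bp length grid), normalized to the
genome-wide mean. It shares no code path with the Monte-Carlo simulation,
so their agreement (r ≥ 0.95 over enriched windows in the bundled
benchmark) is a genuine cross-check of stage 5.

**Recovery metric.** Precision counts a peak as correct when it overlaps
a planted region *or* lies within one fragment length of any marked CpG:
with genome-wide background marking and an efficient antibody, isolated
marked sites are genuinely captured and correctly called, so treating
them as false positives would measure the simulated biology rather than
the caller. Recall is per planted region.

## What the simulations do not emulate

No sequencing-error or homopolymer model (flow chemistry is out of
scope); no mappability structure, GC bias or repeats — every position is
equally alignable, so the mapping-rate diagnostics exercise bookkeeping,
not aligner behavior; no fragment-level melting or denaturation effects;
capture saturates per site rather than per molarity; duplicates are
flagged from ground truth rather than inferred from coordinates. Passing
the suite therefore demonstrates the pipeline's statistical calibration,
conservation properties and recovery behavior under the stated model —
not robustness to alignment artifacts or real antibody specificity.

## Numerical choices and degenerate inputs

Poisson tails come from `scipy.stats.poisson.sf` (verified against exact
term summation to 1e-10 relative error across the calling regime); BH
from `statsmodels`. bedGraph values are written with six decimals, so
round trips are exact to 1e-6. Zero-read libraries, empty gene sets, and
zero-variance tracks raise explicit errors rather than propagating NaNs;
empty streams in QC return zero-total reports. Correlation matrices are
symmetrized and clipped to [−1, 1] before clustering; distances are
clipped at 0. The pipeline driver validates the full configuration before
writing any output and records a hash of the semantic parameters plus the
seed in its manifest, so a manifest identifies the analysis that produced
it.

## Known limitations

- The Poisson test assumes duplicate-free counts; running with
  `include_duplicates=True` on heavily amplified libraries will be
  anticonservative.
- The background floor is global; strong copy-number structure would call
  spurious peaks (no local-lambda correction).
- Cross-platform comparison resamples foreign tracks onto the window grid
  by length-weighted means; probe-level microarray processing is out of
  scope.
- Compartment radii and the peak score scaling (250 × log2, capped at
  1000) are conventions of this package, documented in output headers.
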