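# dipscan

Windowed enrichment analysis for DNA-immunoprecipitation sequencing
(DIP-seq) experiments — the IP-vs-input half of a 5hmC/5mC profiling
study — plus a protocol-faithful read simulator so every stage can be
exercised and validated without any external data.

## Who this is for

Groups profiling low-abundance DNA modifications (5-hydroxymethylcytosine
in particular, which marks roughly 0.1–7% of modified cytosines in
non-CNS mammalian tissues) by antibody pulldown of sheared genomic DNA
followed by sequencing of the enriched (IP) library alongside a matched
input aliquot. `dipscan` takes coordinate-sorted alignments for both
libraries and produces the standard downstream products:

- **read QC** — read-length histograms and mapping rate per length bin;
  reads shorter than 50 bp (adapter carry-over, degraded input) map poorly
  and are excluded by default;
- **window quantification** — each mapped read is assigned to exactly one
  fixed-width window (200 bp default) by its fragment midpoint, so window
  counts partition the library; counts are depth-normalized to CPM;
- **enrichment tracks** — per-window `log2((IP + c) / (input + c))` on the
  CPM scale (pseudocount `c = 0.5`), the sequencing analogue of a
  two-channel array ratio;
- **peak calling** — per-window one-sided Poisson test of the IP count
  against the depth-scaled input count, Benjamini–Hochberg adjustment
  across windows, and merging of adjacent significant windows
  (`q ≤ 0.05` and log2 ratio ≥ 1 by default) into a binary map of the most
  strongly modified regions;
- **compartment annotation** — each peak is assigned, by midpoint with
  strict precedence, to promoter core (TSS ± 500 bp), promoter proximal
  (± 2 kb), promoter distal (± 10 kb), intragenic or intergenic;
- **concordance and profiling** — Pearson r / R² over large random window
  samples, clustered correlation matrices across samples, metagene
  profiles over gene bodies rescaled to a common axis with 25%-length
  flanks, and per-window condition-difference tracks.

The statistical core, for a window *i* with IP count $x_i$, input count
$y_i$ and library sizes $N_{\mathrm{IP}}, N_{\mathrm{in}}$:

$$p_i = P\left(X \ge x_i\right),\quad X \sim \mathrm{Poisson}\!\left(\max\!\left(y_i \tfrac{N_{\mathrm{IP}}}{N_{\mathrm{in}}},\ \lambda_0\right)\right)$$

with a background floor $\lambda_0$ (10% of the genome-mean IP rate) so
zero-coverage input windows cannot yield unbounded significance, followed
by BH adjustment and the log2-ratio effect-size filter.

## Worked example

Simulate a small experiment (two 1 Mb chromosomes, four planted enriched
regions, 200k reads per sample) and call peaks:

```sh
$ cat sim.yaml
genome: {simA: 1000000, simB: 1000000}
seed: 17
n_fragments: 12000000
n_reads: 200000
enriched_regions:
  - {chrom: simA, start: 100000, end: 120000, multiplier: 8}
  - {chrom: simA, start: 460000, end: 480000, multiplier: 24}
  - {chrom: simB, start: 280000, end: 300000, multiplier: 20}
  - {chrom: simB, start: 820000, end: 840000, multiplier: 44}

$ dipscan simulate --config sim.yaml --out sim
ip: 200000 reads from 275432 fragments (57678 duplicates)
input: 200000 reads from 304271 fragments (53417 duplicates)
wrote sim/ip.sam, sim/input.sam, sim/truth_regions.bed

$ printf 'simA\t1000000\nsimB\t1000000\n' > chrom.sizes
$ dipscan callpeaks --ip sim/ip.sam --input sim/input.sam \
      --chrom-sizes chrom.sizes --out peaks.bed
ip: 142322 reads counted, 0 short reads removed, 0 skipped
input: 146583 reads counted, 0 short reads removed, 0 skipped
wrote peaks.bed (379 peaks)

$ head -5 peaks.bed
#chrom	start	end	name	score	strand	log2_enrichment	q_value
#score = round(min(1000, 250 * log2_enrichment))
simA	4400	4800	peak_1	638	.	2.5525	1.53955e-26
simA	6400	6800	peak_2	748	.	2.9932	2.98619e-53
simA	8600	9000	peak_3	516	.	2.0639	6.85808e-19
```

The duplicate tallies reflect the simulated 10-cycle whole-genome
amplification; duplicate-flagged reads are excluded before counting
(142k/147k of 200k survive dedup and length filtering). Of the 379 peaks,
the wide ones sit on the planted regions — the widest,
`simB:829400-838200` (44 windows, log2 enrichment 3.92, q ≈ 2e-115), is
the multiplier-44 region — while the narrow one- and two-window peaks
mark isolated background 5hmC sites, which the antibody also captures.

The same analysis from Python:

```python
from dipscan import (WindowGrid, read_alignments, filter_by_length,
                     count_reads, to_cpm, log2_ratio, call_peaks)

grid = WindowGrid({"simA": 1_000_000, "simB": 1_000_000}, window_size=200)
ip = count_reads(filter_by_length(read_alignments("sim/ip.sam"))[0], grid, "ip")
inp = count_reads(filter_by_length(read_alignments("sim/input.sam"))[0], grid, "input")
ratio = log2_ratio(to_cpm(ip), to_cpm(inp))   # bedGraph-ready enrichment track
peaks = call_peaks(ip, inp, min_log2=1.0, alpha=0.05)
```

`dipscan run` chains qc → filter → windows → normalize → callpeaks →
annotate → metagene → correlate and writes a manifest recording every
output, its row count, the config hash and the seed; identical inputs and
config reproduce the manifest byte for byte.

## The simulator

`dipscan.simulate` generates the experiment stage by stage: CpG placement
(Poisson process), probabilistic 5hmC marking with per-region
multipliers, fragmentation (truncated normal, 100–500 bp, mode ~300 bp),
a 10% input reserve, antibody capture with probability
`1 − (1 − e)^k` for `k` marked sites per fragment, 10-cycle WGA with
optional per-fragment lognormal bias, 100–250 bp size selection, and
reads (~137 bp mean) emitted from either fragment end with amplification
duplicates flagged. It returns ground truth (marked sites, regions, and a
closed-form expected-enrichment track computed by numeric integration,
independent of the Monte-Carlo path) for recovery and calibration
testing. See `docs/methods.md` for the model, parameter rationale and
limitations.

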