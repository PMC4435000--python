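"""Window-based enrichment peak calling and genomic compartment annotation.

The caller tests each window's IP count against the depth-scaled input
count with a one-sided Poisson tail, adjusts across windows by
Benjamini-Hochberg, and merges runs of adjacent significant windows into
peaks — the standard windowed approach for DIP-seq style data, yielding a
binary map of the most strongly modified regions. Peaks are then assigned
to one of five genomic compartments relative to annotated genes: promoter
core, promoter proximal, promoter distal, intragenic, intergenic, with
strict precedence in that order.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, GenomicInterval
from .window_quant import WindowTrack, log2_ratio, to_cpm

__all__ = [
    "Peak",
    "CompartmentScheme",
    "COMPARTMENTS",
    "call_peaks",
    "assign_compartment",
    "compartment_distribution",
    "CompartmentClassifier",
    "evaluate_recovery",
]

COMPARTMENTS = (
    "promoter_core",
    "promoter_proximal",
    "promoter_distal",
    "intragenic",
    "intergenic",
)


@dataclass(frozen=True)
class Peak:
    """A merged run of significantly enriched windows.

    ``log2_enrichment`` is the maximum window-level log2 CPM ratio inside
    the peak; ``q_value`` the smallest BH-adjusted p-value.
    """

    interval: GenomicInterval
    n_windows: int
    log2_enrichment: float
    q_value: float

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("peak must contain at least one window")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q_value must lie in [0, 1]")


@dataclass(frozen=True)
class CompartmentScheme:
    """Distance thresholds (bp, symmetric around each TSS) for the promoter
    zones. Defaults: core ±500, proximal ±2000, distal ±10000."""

    core_radius: int = 500
    proximal_radius: int = 2000
    distal_radius: int = 10000

    def __post_init__(self) -> None:
        if not 0 < self.core_radius < self.proximal_radius < self.distal_radius:
            raise ValueError("require 0 < core < proximal < distal radius")


def poisson_upper_tail(observed: float, lam: float) -> float:
    """P(X >= observed) for X ~ Poisson(lam), the caller's per-window test."""
    return float(stats.poisson.sf(observed - 1, lam))


def call_peaks(
    ip: WindowTrack,
    input: WindowTrack,
    min_log2: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    floor_fraction: float = 0.1,
) -> list[Peak]:
    """Call enriched peaks from raw-count IP and input window tracks.

    Per window the IP count is tested against an expectation of
    ``input_i * (ip_library / input_library)``, floored at
    ``floor_fraction`` of the genome-mean IP rate so that zero-coverage
    input windows cannot produce unbounded significance. Windows with BH
    q <= ``alpha`` and log2 CPM ratio >= ``min_log2`` are significant;
    adjacent significant windows merge. Output is sorted by (chrom, start).
    """
    for name, t in (("ip", ip), ("input", input)):
        if t.units != "raw_count":
            raise ValueError(f"call_peaks expects raw_count tracks; {name} has {t.units!r}")
    if not input.library_size:
        raise ValueError("zero input library")
    if not ip.library_size:
        raise ValueError("zero IP library")
    if ip.grid != input.grid:
        from .genome import describe_grid_mismatch

        raise ValueError(f"window grids differ: {describe_grid_mismatch(ip.grid, input.grid)}")

    grid = ip.grid
    scale = ip.library_size / input.library_size
    floor = ip.library_size / grid.total_windows * floor_fraction
    lam = np.maximum(input.values * scale, floor)
    pvals = stats.poisson.sf(ip.values - 1, lam)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    ratios = log2_ratio(to_cpm(ip), to_cpm(input), pseudocount=pseudocount).values
    significant = (qvals <= alpha) & (ratios >= min_log2)

    peaks: list[Peak] = []
    for chrom in grid.chroms:
        off = grid.offset(chrom)
        n = grid.n_windows(chrom)
        run_start: int | None = None
        for i in range(n + 1):
            if i < n and significant[off + i]:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                lo = grid.window_bounds(chrom, run_start)[0]
                hi = grid.window_bounds(chrom, i - 1)[1]
                sl = slice(off + run_start, off + i)
                peaks.append(
                    Peak(
                        interval=GenomicInterval(chrom, lo, hi),
                        n_windows=i - run_start,
                        log2_enrichment=float(np.max(ratios[sl])),
                        q_value=float(np.min(qvals[sl])),
                    )
                )
                run_start = None
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


class CompartmentClassifier:
    """Index a gene set for repeated compartment queries.

    Classification uses the peak midpoint with strict precedence
    promoter_core > promoter_proximal > promoter_distal > intragenic >
    intergenic. Promoter zones are symmetric around every TSS regardless of
    gene-body overlap, so a point 1.5 kb into a gene body is still
    promoter-proximal, not intragenic.
    """

    def __init__(self, genes: Iterable[GeneModel], scheme: CompartmentScheme | None = None):
        self.scheme = scheme or CompartmentScheme()
        self._tss: dict[str, list[int]] = {}
        self._bodies: dict[str, IntervalTree] = {}
        seen: set[str] = set()
        for gene in genes:
            if gene.gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            chrom = gene.body.chrom
            self._tss.setdefault(chrom, []).append(gene.tss)
            self._bodies.setdefault(chrom, IntervalTree()).addi(
                gene.body.start, gene.body.end, gene.gene_id
            )
        for positions in self._tss.values():
            positions.sort()

    def _tss_distance(self, chrom: str, pos: int) -> int | None:
        positions = self._tss.get(chrom)
        if not positions:
            return None
        i = bisect.bisect_left(positions, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(pos - positions[j])
                best = d if best is None else min(best, d)
        return best

    def classify_point(self, chrom: str, pos: int) -> str:
        d = self._tss_distance(chrom, pos)
        s = self.scheme
        if d is not None:
            if d <= s.core_radius:
                return "promoter_core"
            if d <= s.proximal_radius:
                return "promoter_proximal"
            if d <= s.distal_radius:
                return "promoter_distal"
        tree = self._bodies.get(chrom)
        if tree is not None and tree.overlaps_point(pos):
            return "intragenic"
        return "intergenic"

    def classify(self, peak: Peak) -> str:
        return self.classify_point(peak.interval.chrom, peak.interval.midpoint)

    def distribution(self, peaks: Sequence[Peak]) -> dict[str, float]:
        if not peaks:
            raise ValueError("no peaks to classify")
        counts = {c: 0 for c in COMPARTMENTS}
        for peak in peaks:
            counts[self.classify(peak)] += 1
        return {c: 100.0 * n / len(peaks) for c, n in counts.items()}


def assign_compartment(
    peak: Peak, genes: Iterable[GeneModel], scheme: CompartmentScheme | None = None
) -> str:
    """Classify a single peak; see :class:`CompartmentClassifier`."""
    return CompartmentClassifier(genes, scheme).classify(peak)


def compartment_distribution(
    peaks: Sequence[Peak],
    genes: Iterable[GeneModel],
    scheme: CompartmentScheme | None = None,
) -> dict[str, float]:
    """Percentage of peaks per compartment (sums to 100; each peak counted once)."""
    return CompartmentClassifier(genes, scheme).distribution(peaks)


def evaluate_recovery(
    peaks: Sequence[Peak],
    truth_regions: Sequence[GenomicInterval],
    marked_sites: Mapping[str, "np.ndarray"] | None = None,
    site_slop: int = 300,
) -> tuple[float, float]:
    """Overlap-based precision/recall of called peaks against simulation truth.

    Recall is per planted region: the fraction of ``truth_regions``
    overlapped by at least one peak. Precision is the fraction of peaks
    covering genuinely modified sequence: a peak counts as correct if it
    overlaps a truth region or (when ``marked_sites`` is given) lies within
    ``site_slop`` bp of any marked site. Isolated marked sites outside the
    planted regions are real signal under the capture model — fragments
    covering them are captured — so peaks over them are recoveries, not
    false positives; ``site_slop`` should be about one fragment length.
    """
    if not peaks:
        return 0.0, 0.0
    hit = [False] * len(truth_regions)
    n_true_peaks = 0
    for peak in peaks:
        matched = False
        for i, region in enumerate(truth_regions):
            if peak.interval.overlaps(region):
                hit[i] = True
                matched = True
        if not matched and marked_sites is not None:
            sites = marked_sites.get(peak.interval.chrom)
            if sites is not None and len(sites):
                lo = peak.interval.start - site_slop
                hi = peak.interval.end + site_slop
                if np.searchsorted(sites, hi) > np.searchsorted(sites, lo):
                    matched = True
        if matched:
            n_true_peaks += 1
    precision = n_true_peaks / len(peaks)
    recall = sum(hit) / len(truth_regions) if truth_regions else 1.0
    return precision, recall
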