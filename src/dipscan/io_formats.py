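"""Readers and writers for the standard formats the pipeline touches.

This is the single boundary where external dialects are handled: SAM/BAM
(1-based on disk, converted here), bedGraph and BED-style peak output
(0-based half-open, as used internally everywhere).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence, Union

import numpy as np
import pysam

from .genome import GenomicInterval, WindowGrid
from .window_quant import WindowTrack

__all__ = [
    "AlignedRead",
    "read_alignments",
    "write_bedgraph",
    "read_bedgraph",
    "write_peaks",
]

_SECONDARY = 0x100
_SUPPLEMENTARY = 0x800
_DUPLICATE = 0x400


@dataclass(frozen=True)
class AlignedRead:
    """A minimal alignment record.

    ``read_length`` is the sequenced (query) length; ``aligned_length`` the
    reference span of the alignment. Unmapped reads carry ``chrom=None`` and
    ``aligned_length=0``.
    """

    chrom: str | None
    start: int
    aligned_length: int
    mapped: bool
    mapq: int
    read_length: int

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.mapped and (self.chrom is None or self.aligned_length <= 0):
            raise ValueError("mapped read requires chrom and positive aligned_length")


def read_alignments(
    source: Union[str, "os.PathLike[str]"],
    region: GenomicInterval | None = None,
    include_duplicates: bool = False,
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file.

    Secondary (0x100) and supplementary (0x800) records are always skipped.
    Duplicates (0x400) are skipped by default: low-cycle whole-genome
    amplification inflates duplicate rates, and retaining them distorts
    window counts; pass ``include_duplicates=True`` to keep them. Unmapped
    records are yielded with ``mapped=False``. A ``region`` restricts output
    to overlapping reads (streaming filter, so it works on plain SAM).
    """
    with pysam.AlignmentFile(os.fspath(source), check_sq=True) as af:
        if af.header.nreferences == 0:
            raise ValueError(f"{source}: SAM/BAM header has no sequence dictionary")
        if region is not None and region.chrom not in af.references:
            raise ValueError(
                f"region chromosome {region.chrom!r} absent from {source} header"
            )
        for rec in af:
            if rec.flag & (_SECONDARY | _SUPPLEMENTARY):
                continue
            if not include_duplicates and rec.flag & _DUPLICATE:
                continue
            read_length = rec.query_length or rec.infer_query_length() or 0
            if rec.is_unmapped:
                if read_length <= 0:
                    continue  # no usable length information
                yield AlignedRead(None, -1 if rec.reference_start is None else rec.reference_start,
                                  0, False, rec.mapping_quality, read_length)
                continue
            aligned_length = rec.reference_length or 0
            if read_length <= 0:
                read_length = aligned_length
            if aligned_length <= 0 or read_length <= 0:
                continue
            if region is not None:
                if rec.reference_name != region.chrom:
                    continue
                if not (rec.reference_start < region.end
                        and region.start < rec.reference_start + aligned_length):
                    continue
            yield AlignedRead(
                chrom=rec.reference_name,
                start=rec.reference_start,
                aligned_length=aligned_length,
                mapped=True,
                mapq=rec.mapping_quality,
                read_length=read_length,
            )


Sink = Union[str, "os.PathLike[str]", IO[str]]


def _open_sink(sink: Sink):
    if hasattr(sink, "write"):
        return sink, False
    return open(os.fspath(sink), "w"), True


def _iter_source_lines(source) -> Iterator[str]:
    if hasattr(source, "read"):
        yield from source
    elif isinstance(source, str) and "\n" in source:
        yield from io.StringIO(source)
    else:
        with open(os.fspath(source)) as fh:
            yield from fh


def write_bedgraph(track: WindowTrack, sink: Sink) -> None:
    """Serialize a window track as bedGraph, one line per window in grid order.

    Values are rendered with six decimal places so a write/read round trip
    restores them within 1e-6.
    """
    fh, close = _open_sink(sink)
    try:
        grid = track.grid
        i = 0
        for chrom in grid.chroms:
            for start, end in (
                grid.window_bounds(chrom, j) for j in range(grid.n_windows(chrom))
            ):
                fh.write(f"{chrom}\t{start}\t{end}\t{track.values[i]:.6f}\n")
                i += 1
    finally:
        if close:
            fh.close()


def read_bedgraph(source, grid: WindowGrid, units: str = "log2_ratio",
                  sample_id: str = "") -> WindowTrack:
    """Resample bedGraph content onto a window grid.

    Grid-aligned intervals pass through unchanged; other intervals are
    distributed as a length-weighted mean over the windows they overlap.
    Windows with no source coverage get value 0 and are flagged in
    ``track.covered``. Intervals outside the grid's chromosomes are errors.
    """
    wsum = np.zeros(grid.total_windows)
    weight = np.zeros(grid.total_windows)
    w, step = grid.window_size, grid.step
    for lineno, line in enumerate(_iter_source_lines(source), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"bedGraph line {lineno}: expected 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if chrom not in grid.chrom_sizes:
            raise ValueError(f"bedGraph line {lineno}: unknown chromosome {chrom!r}")
        size = grid.chrom_sizes[chrom]
        if not (0 <= start < end <= size):
            raise ValueError(
                f"bedGraph line {lineno}: interval [{start},{end}) outside "
                f"{chrom} (length {size})"
            )
        off = grid.offset(chrom)
        n = grid.n_windows(chrom)
        i_min = max(0, (start - w) // step + 1)
        i_max = min(n - 1, (end - 1) // step)
        for i in range(i_min, i_max + 1):
            ws = i * step
            we = min(ws + w, size)
            ov = min(end, we) - max(start, ws)
            if ov > 0:
                wsum[off + i] += value * ov
                weight[off + i] += ov
    covered = weight > 0
    values = np.where(covered, wsum / np.where(covered, weight, 1.0), 0.0)
    return WindowTrack(grid=grid, values=values, units=units, sample_id=sample_id,
                       covered=covered)


# peak score column: log2 enrichment scaled by 250 and capped at 1000, the
# BED score convention used in this package's peak output (documented in the
# file header written below).
def _bed_score(log2_enrichment: float) -> int:
    return int(round(min(1000.0, max(0.0, 250.0 * log2_enrichment))))


def write_peaks(peaks: Sequence, sink: Sink) -> None:
    """Write peaks as BED6+2: name, score (250*log2 capped at 1000), strand '.',
    then log2_enrichment and q_value columns. Input must be coordinate-sorted."""
    key = [(p.interval.chrom, p.interval.start) for p in peaks]
    if key != sorted(key):
        raise ValueError("write_peaks requires peaks sorted by (chrom, start)")
    fh, close = _open_sink(sink)
    try:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tlog2_enrichment\tq_value\n")
        fh.write("#score = round(min(1000, 250 * log2_enrichment))\n")
        for n, p in enumerate(peaks, start=1):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{n}\t"
                f"{_bed_score(p.log2_enrichment)}\t.\t"
                f"{p.log2_enrichment:.4f}\t{p.q_value:.6g}\n"
            )
    finally:
        if close:
            fh.close()
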