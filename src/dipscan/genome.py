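"""Core genomic coordinate types: intervals, window grids and gene models.

All coordinates are 0-based half-open (BED convention). 1-based formats
(GTF, SAM) are converted at the I/O boundary, never downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

__all__ = [
    "GenomicInterval",
    "WindowGrid",
    "GeneModel",
    "make_windows",
    "load_genes",
    "read_chrom_sizes",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


class WindowGrid:
    """A deterministic tiling/sliding window grid over a set of chromosomes.

    Windows on a chromosome of length ``L`` start at multiples of ``step``;
    the last start is the smallest multiple of ``step`` whose window reaches
    the chromosome end, and that final window is truncated at ``L`` when the
    length is not a multiple of the step. Every base is covered by at least
    one window and no base is silently dropped.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        window_size: int = 200,
        step: int | None = None,
    ) -> None:
        if window_size <= 0:
            raise ValueError("window_size must be positive")
        step = window_size if step is None else step
        if not (0 < step <= window_size):
            raise ValueError("require 0 < step <= window_size")
        if not chrom_sizes:
            raise ValueError("chrom_sizes is empty")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.window_size = int(window_size)
        self.step = int(step)
        self._n: dict[str, int] = {}
        self._offset: dict[str, int] = {}
        off = 0
        for chrom, size in self.chrom_sizes.items():
            n = self._n_windows(size)
            self._n[chrom] = n
            self._offset[chrom] = off
            off += n
        self.total_windows = off

    def _n_windows(self, length: int) -> int:
        if length <= self.window_size:
            return 1
        last_start = math.ceil((length - self.window_size) / self.step) * self.step
        return last_start // self.step + 1

    # -- introspection -------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_windows(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return self._n[chrom]

    def offset(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return self._offset[chrom]

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r} (not in grid)")

    # -- coordinate arithmetic ----------------------------------------
    def window_bounds(self, chrom: str, i: int) -> tuple[int, int]:
        """Half-open bounds of the ``i``-th window on ``chrom``."""
        self._check_chrom(chrom)
        if not 0 <= i < self._n[chrom]:
            raise IndexError(f"window {i} out of range on {chrom}")
        start = i * self.step
        end = min(start + self.window_size, self.chrom_sizes[chrom])
        return start, end

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window a position is assigned to.

        With a sliding grid a position can lie in several windows; the
        assignment is to the right-most window containing it, which makes
        midpoint binning a partition of the genome.
        """
        self._check_chrom(chrom)
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        i = min(pos // self.step, self._n[chrom] - 1)
        return self._offset[chrom] + i

    def locate(self, index: int) -> GenomicInterval:
        """Inverse of global indexing: the window interval at ``index``."""
        if not 0 <= index < self.total_windows:
            raise IndexError(f"window index {index} out of range")
        for chrom in reversed(self.chrom_sizes):
            if index >= self._offset[chrom]:
                start, end = self.window_bounds(chrom, index - self._offset[chrom])
                return GenomicInterval(chrom, start, end)
        raise AssertionError("unreachable")

    def windows(self, chrom: str) -> Iterator[GenomicInterval]:
        self._check_chrom(chrom)
        for i in range(self._n[chrom]):
            start, end = self.window_bounds(chrom, i)
            yield GenomicInterval(chrom, start, end)

    def all_windows(self) -> Iterator[GenomicInterval]:
        for chrom in self.chrom_sizes:
            yield from self.windows(chrom)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WindowGrid):
            return NotImplemented
        return (
            self.chrom_sizes == other.chrom_sizes
            and self.window_size == other.window_size
            and self.step == other.step
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WindowGrid({len(self.chrom_sizes)} chroms, "
            f"window={self.window_size}, step={self.step}, "
            f"n={self.total_windows})"
        )


def describe_grid_mismatch(a: WindowGrid, b: WindowGrid) -> str:
    """Human-readable description of the first difference between two grids."""
    if a.window_size != b.window_size:
        return f"window_size differs: {a.window_size} vs {b.window_size}"
    if a.step != b.step:
        return f"step differs: {a.step} vs {b.step}"
    for chrom in a.chrom_sizes:
        if chrom not in b.chrom_sizes:
            return f"chromosome {chrom!r} missing from second grid"
        if a.chrom_sizes[chrom] != b.chrom_sizes[chrom]:
            return (
                f"chromosome {chrom!r} length differs: "
                f"{a.chrom_sizes[chrom]} vs {b.chrom_sizes[chrom]}"
            )
    for chrom in b.chrom_sizes:
        if chrom not in a.chrom_sizes:
            return f"chromosome {chrom!r} missing from first grid"
    return "grids are identical"


def make_windows(grid: WindowGrid, chrom: str) -> list[GenomicInterval]:
    """Ordered windows of ``grid`` on one chromosome.

    Pure function of its inputs; the final window is truncated at the
    chromosome end when the length is not a multiple of the step.
    """
    return list(grid.windows(chrom))


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: the union span of its transcripts plus a strand.

    The TSS is the 5' end of the body: ``body.start`` on the plus strand and
    ``body.end - 1`` on the minus strand (0-based).
    """

    gene_id: str
    body: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1


Source = Union[str, TextIO, Iterable[str]]


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, str):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def read_chrom_sizes(source: Source) -> dict[str, int]:
    """Read a two-column UCSC-style chrom.sizes TSV into an ordered dict."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"chrom.sizes line {lineno}: expected 2 columns")
        try:
            size = int(fields[1])
        except ValueError as exc:
            raise ValueError(f"chrom.sizes line {lineno}: bad length {fields[1]!r}") from exc
        sizes[fields[0]] = size
    if not sizes:
        raise ValueError("chrom.sizes input is empty")
    return sizes


def _sniff_format(first_data_line: str) -> str:
    fields = first_data_line.rstrip("\n").split("\t")
    if len(fields) >= 8 and fields[3].isdigit() and fields[4].isdigit():
        return "gtf"
    return "bed"


def load_genes(source: Source, format: str | None = None) -> list[GeneModel]:
    """Load gene models from BED (6+ columns) or GTF content.

    Transcripts sharing a ``gene_id`` are unioned into a single body span.
    A gene appearing on two chromosomes or with conflicting strands is an
    error; malformed records report their line number. The format is
    sniffed from the first data line when not given.
    """
    lines = list(_iter_lines(source))
    data = [
        (i + 1, ln.rstrip("\n"))
        for i, ln in enumerate(lines)
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    if not data:
        raise ValueError("annotation input contains no records")
    fmt = format or _sniff_format(data[0][1])
    if fmt not in ("bed", "gtf"):
        raise ValueError(f"unknown annotation format {fmt!r}")

    # gene_id -> (chrom, min_start, max_end, strand)
    spans: dict[str, list] = {}

    def _merge(lineno: int, gid: str, chrom: str, start: int, end: int, strand: str) -> None:
        if start >= end:
            raise ValueError(f"annotation line {lineno}: empty span for {gid!r}")
        if gid in spans:
            rec = spans[gid]
            if rec[0] != chrom:
                raise ValueError(
                    f"annotation line {lineno}: gene {gid!r} on both "
                    f"{rec[0]!r} and {chrom!r}"
                )
            if rec[3] != strand:
                raise ValueError(
                    f"annotation line {lineno}: gene {gid!r} has conflicting strands"
                )
            rec[1] = min(rec[1], start)
            rec[2] = max(rec[2], end)
        else:
            spans[gid] = [chrom, start, end, strand]

    for lineno, line in data:
        fields = line.split("\t")
        if fmt == "bed":
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"annotation line {lineno}: BED needs >= 6 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"annotation line {lineno}: bad coordinates") from exc
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ValueError(f"annotation line {lineno}: bad strand {strand!r}")
            _merge(lineno, fields[3], fields[0], start, end, strand)
        else:  # gtf
            if len(fields) < 9:
                raise ValueError(f"annotation line {lineno}: GTF needs 9 columns")
            feature = fields[2]
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start = int(fields[3]) - 1  # GTF is 1-based inclusive
                end = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"annotation line {lineno}: bad coordinates") from exc
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ValueError(f"annotation line {lineno}: bad strand {strand!r}")
            gid = _gtf_gene_id(fields[8])
            if gid is None:
                raise ValueError(f"annotation line {lineno}: missing gene_id attribute")
            _merge(lineno, gid, fields[0], start, end, strand)

    genes = [
        GeneModel(gid, GenomicInterval(chrom, start, end, strand), strand)
        for gid, (chrom, start, end, strand) in spans.items()
    ]
    if not genes:
        raise ValueError("annotation contained no usable gene records")
    return genes


def _gtf_gene_id(attributes: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("gene_id"):
            value = part[len("gene_id"):].strip()
            return value.strip('"')
    return None
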