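"""Per-window read quantification and IP-vs-input normalization.

The quantification model is deliberately simple: every mapped read is
assigned to exactly one window — the window containing its fragment
midpoint — so window counts partition the library and totals are conserved.
Depth normalization is counts-per-million (CPM), and enrichment is the
elementwise log2 ratio of pseudocounted IP over input CPM, the sequencing
analogue of a two-channel array ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .genome import WindowGrid, describe_grid_mismatch

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .io_formats import AlignedRead

__all__ = ["WindowTrack", "count_reads", "to_cpm", "log2_ratio"]

#: units a WindowTrack may carry. "ratio" is a linear IP/input ratio (used by
#: the simulator's closed-form enrichment oracle).
VALID_UNITS = ("raw_count", "cpm", "log2_ratio", "ratio")


@dataclass
class WindowTrack:
    """One numeric value per window of a :class:`WindowGrid`.

    ``units`` disciplines what the values mean; operations refuse to mix
    units. ``library_size`` is the number of reads the values were derived
    from (absent for ratio-type units). ``covered`` optionally flags windows
    that had source data (used when resampling bedGraph input).
    """

    grid: WindowGrid
    values: np.ndarray
    units: str
    sample_id: str = ""
    library_size: int | None = None
    covered: np.ndarray | None = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.total_windows,):
            raise ValueError(
                f"track has {self.values.size} values for "
                f"{self.grid.total_windows} windows"
            )
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")
        if self.units == "raw_count":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("raw_count values must be non-negative integers")
        elif self.units in ("cpm", "ratio"):
            if np.any(self.values < 0):
                raise ValueError(f"{self.units} values must be non-negative")

    def chrom_values(self, chrom: str) -> np.ndarray:
        off = self.grid.offset(chrom)
        return self.values[off : off + self.grid.n_windows(chrom)]

    def interval_mean(self, chrom: str, start: float, end: float) -> float:
        """Length-weighted mean track value over ``[start, end)``.

        Requires a tiling grid (step == window size) so the signal is a
        piecewise-constant function of position. Bin edges may be fractional
        (metagene bins are). The interval must lie within the chromosome.
        """
        if self.grid.step != self.grid.window_size:
            raise ValueError("interval_mean requires a tiling grid")
        size = self.grid.chrom_sizes[chrom]
        if not (0 <= start < end <= size):
            raise ValueError(f"interval [{start},{end}) outside {chrom} (length {size})")
        cum = self._cumulative(chrom)
        return (self._integral(chrom, cum, end) - self._integral(chrom, cum, start)) / (
            end - start
        )

    # piecewise-constant signal integral, cached per chromosome
    def _cumulative(self, chrom: str) -> np.ndarray:
        cache = getattr(self, "_cum_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_cum_cache", cache)
        if chrom not in cache:
            vals = self.chrom_values(chrom)
            w = self.grid.window_size
            size = self.grid.chrom_sizes[chrom]
            lengths = np.full(vals.size, w, dtype=float)
            lengths[-1] = size - (vals.size - 1) * w
            cache[chrom] = np.concatenate([[0.0], np.cumsum(vals * lengths)])
        return cache[chrom]

    def _integral(self, chrom: str, cum: np.ndarray, x: float) -> float:
        w = self.grid.window_size
        n = self.grid.n_windows(chrom)
        i = min(int(x // w), n - 1)
        vals = self.chrom_values(chrom)
        return cum[i] + vals[i] * (x - i * w)


def _check_same_grid(a: WindowTrack, b: WindowTrack) -> None:
    if a.grid != b.grid:
        raise ValueError(f"window grids differ: {describe_grid_mismatch(a.grid, b.grid)}")


def count_reads(
    reads: Iterable["AlignedRead"], grid: WindowGrid, sample_id: str = ""
) -> WindowTrack:
    """Bin mapped reads into grid windows by fragment midpoint.

    The midpoint is ``start + aligned_length // 2``. Reads on chromosomes
    absent from the grid are tallied in ``track.n_skipped`` rather than
    raising; unmapped reads are ignored. ``library_size`` is the number of
    reads actually assigned, so counts are conserved:
    ``sum(values) + n_skipped == number of mapped reads seen``.
    """
    counts = np.zeros(grid.total_windows, dtype=np.int64)
    skipped = 0
    sizes = grid.chrom_sizes
    for read in reads:
        if not read.mapped:
            continue
        chrom = read.chrom
        if chrom not in sizes:
            skipped += 1
            continue
        mid = read.start + read.aligned_length // 2
        if not 0 <= mid < sizes[chrom]:
            skipped += 1
            continue
        counts[grid.window_index(chrom, mid)] += 1
    return WindowTrack(
        grid=grid,
        values=counts.astype(float),
        units="raw_count",
        sample_id=sample_id,
        library_size=int(counts.sum()),
        n_skipped=skipped,
    )


def to_cpm(track: WindowTrack) -> WindowTrack:
    """Depth-normalize a raw-count track to counts per million."""
    if track.units != "raw_count":
        raise ValueError(f"to_cpm expects raw_count input, got {track.units!r}")
    if not track.library_size:
        raise ValueError("empty library: cannot normalize a track with zero reads")
    return WindowTrack(
        grid=track.grid,
        values=track.values * (1e6 / track.library_size),
        units="cpm",
        sample_id=track.sample_id,
        library_size=track.library_size,
        n_skipped=track.n_skipped,
    )


def log2_ratio(
    ip: WindowTrack, input: WindowTrack, pseudocount: float = 0.5
) -> WindowTrack:
    """Elementwise ``log2((ip + c) / (input + c))`` of two CPM tracks.

    The pseudocount ``c`` keeps sparse windows finite; windows empty in both
    samples get exactly 0 by construction and are retained so grids stay
    comparable across samples.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for name, t in (("ip", ip), ("input", input)):
        if t.units != "cpm":
            raise ValueError(f"log2_ratio expects cpm tracks; {name} has {t.units!r}")
    _check_same_grid(ip, input)
    values = np.log2((ip.values + pseudocount) / (input.values + pseudocount))
    sid = f"{ip.sample_id or 'ip'}_vs_{input.sample_id or 'input'}"
    return WindowTrack(grid=ip.grid, values=values, units="log2_ratio", sample_id=sid)
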