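"""Concordance and profiling analyses across samples and platforms.

Replicate and cross-platform agreement is measured the way two-channel
array data used to be compared: Pearson correlation (and its square) over a
large random sample of fixed-width windows, a clustered correlation matrix
across all samples, scaled metagene profiles over gene bodies with 25%
flanks, and simple per-window difference tracks between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genome import GeneModel, WindowGrid, describe_grid_mismatch
from .window_quant import WindowTrack

__all__ = [
    "MetageneProfile",
    "CorrelationMatrix",
    "sample_random_windows",
    "pairwise_concordance",
    "correlation_matrix",
    "metagene",
    "difference_track",
]


@dataclass
class MetageneProfile:
    """Mean signal over genes rescaled to a common axis.

    The axis is ``n_flank_bins`` upstream bins, ``n_body_bins`` body bins,
    ``n_flank_bins`` downstream bins; each flank spans 25% of the gene-body
    length so with ``n_flank_bins = n_body_bins / 4`` every bin within a
    gene has the same genomic width. Bin 0 is always the 5' end (minus
    strand genes are reversed). ``n_per_bin`` counts how many genes
    contributed to each bin (flanks running off a chromosome end are
    dropped for that gene only).
    """

    n_body_bins: int
    n_flank_bins: int
    values: np.ndarray
    n_per_bin: np.ndarray
    n_genes: int

    @property
    def n_bins(self) -> int:
        return self.n_body_bins + 2 * self.n_flank_bins


@dataclass
class CorrelationMatrix:
    """All-pairs Pearson matrix plus a clustered leaf order."""

    sample_ids: list[str]
    r: np.ndarray
    linkage_order: list[int]
    units: str = ""


def sample_random_windows(grid: WindowGrid, n: int = 500_000, seed: int = 0) -> np.ndarray:
    """``n`` distinct window indices, uniform without replacement.

    Deterministic for a fixed seed. Asking for more windows than the grid
    holds is an error that reports the maximum.
    """
    total = grid.total_windows
    if n <= 0:
        raise ValueError("n must be positive")
    if n > total:
        raise ValueError(f"cannot sample {n} windows from a grid of {total}; maximum is {total}")
    rng = np.random.default_rng(seed)
    return rng.choice(total, size=n, replace=False)


def _select(track: WindowTrack, indices: np.ndarray, name: str) -> np.ndarray:
    x = track.values[np.asarray(indices, dtype=np.intp)]
    if float(np.std(x)) == 0.0:
        raise ValueError(f"degenerate track {name or track.sample_id!r}: zero variance over selected windows")
    return x


def pairwise_concordance(
    a: WindowTrack, b: WindowTrack, indices: np.ndarray
) -> tuple[float, float]:
    """Sample Pearson r and R^2 = r^2 between two tracks over selected windows.

    R^2 is reported as the square of Pearson r, which is symmetric in the
    two tracks and does not require choosing a regression direction.
    """
    if a.grid != b.grid:
        raise ValueError(f"window grids differ: {describe_grid_mismatch(a.grid, b.grid)}")
    if len(indices) < 3:
        raise ValueError("need at least 3 windows for a correlation")
    x = _select(a, indices, "a")
    y = _select(b, indices, "b")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


def correlation_matrix(
    tracks: Sequence[WindowTrack], indices: np.ndarray
) -> CorrelationMatrix:
    """Pairwise Pearson matrix over shared windows, with average-linkage
    hierarchical clustering on distance 1 - r for the leaf order."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    grid = tracks[0].grid
    for t in tracks[1:]:
        if t.grid != grid:
            raise ValueError(f"window grids differ: {describe_grid_mismatch(grid, t.grid)}")
    data = np.vstack([_select(t, indices, t.sample_id) for t in tracks])
    r = np.corrcoef(data)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    dist = np.clip(1.0 - r, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [int(i) for i in hierarchy.leaves_list(link)]
    ids = [t.sample_id or f"track_{i}" for i, t in enumerate(tracks)]
    units = tracks[0].units if len({t.units for t in tracks}) == 1 else "mixed"
    return CorrelationMatrix(sample_ids=ids, r=r, linkage_order=order, units=units)


def metagene(
    track: WindowTrack,
    genes: Iterable[GeneModel],
    n_body_bins: int = 100,
    n_flank_bins: int | None = None,
) -> MetageneProfile:
    """Average a window track over genes rescaled to a common body axis.

    Each gene body is split into ``n_body_bins`` equal bins and each flank
    (25% of the body length) into ``n_flank_bins`` bins (default
    ``n_body_bins // 4``). Per-bin values are length-weighted means of the
    piecewise-constant window signal; the profile is the unweighted mean
    over genes. Requires a tiling grid.
    """
    gene_list = list(genes)
    if not gene_list:
        raise ValueError("empty gene set")
    if n_body_bins < 1:
        raise ValueError("n_body_bins must be >= 1")
    n_flank = n_body_bins // 4 if n_flank_bins is None else n_flank_bins
    n_bins = n_body_bins + 2 * n_flank
    total = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)
    for gene in gene_list:
        body = gene.body
        chrom = body.chrom
        if chrom not in track.grid.chrom_sizes:
            continue
        size = track.grid.chrom_sizes[chrom]
        flank = 0.25 * body.length
        edges = np.concatenate(
            [
                np.linspace(body.start - flank, body.start, n_flank + 1)[:-1],
                np.linspace(body.start, body.end, n_body_bins + 1)[:-1],
                np.linspace(body.end, body.end + flank, n_flank + 1),
            ]
        )
        vals = np.full(n_bins, np.nan)
        for i in range(n_bins):
            lo, hi = edges[i], edges[i + 1]
            if lo < 0 or hi > size:
                continue  # flank runs off the chromosome: bin undefined
            vals[i] = track.interval_mean(chrom, lo, hi)
        if gene.strand == "-":
            vals = vals[::-1]
        defined = ~np.isnan(vals)
        total[defined] += vals[defined]
        count[defined] += 1
    values = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return MetageneProfile(
        n_body_bins=n_body_bins,
        n_flank_bins=n_flank,
        values=values,
        n_per_bin=count,
        n_genes=len(gene_list),
    )


def difference_track(a: WindowTrack, b: WindowTrack) -> WindowTrack:
    """Elementwise ``a - b`` of two log2-ratio tracks (condition difference)."""
    if a.units != b.units:
        raise ValueError(f"units mismatch: {a.units!r} vs {b.units!r}")
    if a.units != "log2_ratio":
        raise ValueError("difference_track operates on log2_ratio tracks")
    if a.grid != b.grid:
        raise ValueError(f"window grids differ: {describe_grid_mismatch(a.grid, b.grid)}")
    sid = f"{a.sample_id or 'A'}_minus_{b.sample_id or 'B'}"
    return WindowTrack(
        grid=a.grid, values=a.values - b.values, units="log2_ratio", sample_id=sid
    )
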