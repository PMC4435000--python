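"""Shared fixtures: in-memory SAM builders and a small cached simulation."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pytest

from dipscan.genome import GenomicInterval, WindowGrid
from dipscan.io_formats import AlignedRead, read_alignments
from dipscan.read_qc import filter_by_length
from dipscan.simulate import EnrichedRegion, SimulationConfig, simulate_run
from dipscan.window_quant import count_reads


def sam_text(chrom_sizes: dict[str, int], records: list[tuple]) -> str:
    """Build SAM content from (qname, flag, chrom, pos0, mapq, cigar, seq) tuples.

    ``pos0`` is 0-based (converted to SAM's 1-based on output); unmapped
    records pass chrom ``*``.
    """
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom, size in chrom_sizes.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{size}")
    for qname, flag, chrom, pos0, mapq, cigar, seq in records:
        pos = 0 if chrom == "*" else pos0 + 1
        lines.append(f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_sam(tmp_path):
    def _write(chrom_sizes, records, name="reads.sam"):
        path = tmp_path / name
        path.write_text(sam_text(chrom_sizes, records))
        return path

    return _write


def mapped_read(chrom="chr1", start=0, length=100, mapq=60, read_length=None):
    return AlignedRead(
        chrom=chrom,
        start=start,
        aligned_length=length,
        mapped=True,
        mapq=mapq,
        read_length=read_length if read_length is not None else length,
    )


def small_sim_config(seed: int = 5) -> SimulationConfig:
    """A fast (~1 s) simulation used for smoke and integration tests."""
    regions = tuple(
        EnrichedRegion(GenomicInterval(chrom, start, start + 10_000), mult)
        for chrom in ("simA", "simB")
        for start, mult in ((40_000, 20.0), (120_000, 35.0))
    )
    return SimulationConfig(
        seed=seed,
        genome={"simA": 200_000, "simB": 200_000},
        enriched_regions=regions,
        n_fragments=600_000,
        n_reads=30_000,
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Simulated IP/input SAM files plus grid and counted tracks."""
    outdir = tmp_path_factory.mktemp("small_sim")
    config = small_sim_config()
    result = simulate_run(config)
    paths = result.write(outdir)
    grid = WindowGrid(config.genome, 200)
    ip_reads, _ = filter_by_length(read_alignments(paths["ip"]))
    input_reads, _ = filter_by_length(read_alignments(paths["input"]))
    return {
        "config": config,
        "result": result,
        "paths": paths,
        "grid": grid,
        "ip": count_reads(ip_reads, grid, "ip"),
        "input": count_reads(input_reads, grid, "input"),
    }
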