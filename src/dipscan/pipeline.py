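"""End-to-end pipeline driver: validate-then-run with a reproducible manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import compare, io_formats, peaks_annotation, read_qc, window_quant
from .genome import WindowGrid, load_genes, read_chrom_sizes

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated parameters and paths for a full IP-vs-input analysis."""

    ip_bam: str = ""
    input_bam: str = ""
    chrom_sizes: str = ""
    genes: str | None = None
    out_dir: str = "dipscan_out"
    window_size: int = 200
    step: int | None = None
    min_read_length: int = 50
    pseudocount: float = 0.5
    alpha: float = 0.05
    min_log2: float = 1.0
    core_radius: int = 500
    proximal_radius: int = 2000
    distal_radius: int = 10000
    n_corr_windows: int = 500_000
    metagene_bins: int = 100
    seed: int = 17

    SEMANTIC_FIELDS = (
        "window_size", "step", "min_read_length", "pseudocount", "alpha",
        "min_log2", "core_radius", "proximal_radius", "distal_radius",
        "n_corr_windows", "metagene_bins", "seed",
    )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def semantic_hash(self) -> str:
        payload = {k: getattr(self, k) for k in self.SEMANTIC_FIELDS}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def validate(self) -> None:
        step = self.step if self.step is not None else self.window_size
        if self.window_size <= 0 or not (0 < step <= self.window_size):
            raise ValueError("require window_size > 0 and 0 < step <= window_size")
        if self.min_read_length < 0:
            raise ValueError("min_read_length must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.core_radius < self.proximal_radius < self.distal_radius:
            raise ValueError("require 0 < core < proximal < distal radius")
        for name in ("ip_bam", "input_bam", "chrom_sizes"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise ValueError(f"{name}: missing input file {path!r}")
        if self.genes and not Path(self.genes).exists():
            raise ValueError(f"genes: missing input file {self.genes!r}")


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for line in fh if line.strip() and not line.startswith("#"))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run qc -> filter -> windows -> normalize -> callpeaks -> annotate ->
    metagene -> correlate, writing every product plus a manifest TSV.

    Validation happens before any output is written; a stage failure raises
    :class:`PipelineError` naming the stage. Returns the manifest path.
    """
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("validate", str(exc)) from exc

    out = Path(config.out_dir)
    outputs: dict[str, Path] = {}

    def _stage(name: str):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return deco

    sizes = _stage("load_inputs")(lambda: read_chrom_sizes(config.chrom_sizes))
    grid = WindowGrid(sizes, config.window_size, config.step)
    genes = (
        _stage("load_inputs")(lambda: load_genes(config.genes)) if config.genes else None
    )
    out.mkdir(parents=True, exist_ok=True)

    tracks = {}
    for label, path in (("ip", config.ip_bam), ("input", config.input_bam)):
        def build(label=label, path=path):
            reads = list(io_formats.read_alignments(path))
            report = read_qc.qc_report(reads, length_cutoff=config.min_read_length)
            qc_path = out / f"qc.{label}.tsv"
            with open(qc_path, "w") as fh:
                report.to_tsv(fh)
            outputs[f"qc_{label}"] = qc_path
            passed, _ = read_qc.filter_by_length(reads, config.min_read_length)
            raw = window_quant.count_reads(passed, grid, sample_id=label)
            cpm = window_quant.to_cpm(raw)
            bg = out / f"{label}.cpm.bedgraph"
            io_formats.write_bedgraph(cpm, bg)
            outputs[f"{label}_cpm"] = bg
            return raw, cpm
        tracks[label] = _stage(f"windows_{label}")(build)

    def normalize():
        ratio = window_quant.log2_ratio(
            tracks["ip"][1], tracks["input"][1], pseudocount=config.pseudocount
        )
        path = out / "log2_ratio.bedgraph"
        io_formats.write_bedgraph(ratio, path)
        outputs["log2_ratio"] = path
        return ratio
    _stage("normalize")(normalize)

    def callpeaks():
        peaks = peaks_annotation.call_peaks(
            tracks["ip"][0], tracks["input"][0],
            min_log2=config.min_log2, alpha=config.alpha,
            pseudocount=config.pseudocount,
        )
        path = out / "peaks.bed"
        io_formats.write_peaks(peaks, path)
        outputs["peaks"] = path
        return peaks
    peaks = _stage("callpeaks")(callpeaks)

    if genes:
        def annotate():
            scheme = peaks_annotation.CompartmentScheme(
                config.core_radius, config.proximal_radius, config.distal_radius
            )
            clf = peaks_annotation.CompartmentClassifier(genes, scheme)
            path = out / "peaks.annotated.tsv"
            with open(path, "w") as fh:
                fh.write("#chrom\tstart\tend\tlog2_enrichment\tq_value\tcompartment\n")
                for p in peaks:
                    fh.write(
                        f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                        f"{p.log2_enrichment:.4f}\t{p.q_value:.6g}\t{clf.classify(p)}\n"
                    )
            outputs["annotated_peaks"] = path
            if peaks:
                dist = clf.distribution(peaks)
                dpath = out / "compartment_distribution.tsv"
                with open(dpath, "w") as fh:
                    fh.write("#compartment\tpercent_of_peaks\n")
                    for comp, pct in dist.items():
                        fh.write(f"{comp}\t{pct:.4f}\n")
                outputs["compartment_distribution"] = dpath
        _stage("annotate")(annotate)

        def run_metagene():
            ratio_track = window_quant.log2_ratio(
                tracks["ip"][1], tracks["input"][1], pseudocount=config.pseudocount
            )
            profile = compare.metagene(ratio_track, genes, config.metagene_bins)
            path = out / "metagene.tsv"
            with open(path, "w") as fh:
                fh.write("#bin\tzone\tmean_signal\tn_genes\n")
                for i, v in enumerate(profile.values):
                    if i < profile.n_flank_bins:
                        zone = "upstream"
                    elif i < profile.n_flank_bins + profile.n_body_bins:
                        zone = "body"
                    else:
                        zone = "downstream"
                    fh.write(f"{i}\t{zone}\t{v:.6f}\t{profile.n_per_bin[i]}\n")
            outputs["metagene"] = path
        _stage("metagene")(run_metagene)

    def correlate():
        n = min(config.n_corr_windows, grid.total_windows)
        idx = compare.sample_random_windows(grid, n, seed=config.seed)
        r, r2 = compare.pairwise_concordance(tracks["ip"][1], tracks["input"][1], idx)
        path = out / "correlation.tsv"
        with open(path, "w") as fh:
            fh.write("#sample_a\tsample_b\tn_windows\tunits\tpearson_r\tr_squared\n")
            fh.write(f"ip\tinput\t{n}\tcpm\t{r:.6f}\t{r2:.6f}\n")
        outputs["correlation"] = path
    _stage("correlate")(correlate)

    manifest = out / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("#output\tpath\tn_rows\tconfig_hash\tseed\n")
        for name in sorted(outputs):
            path = outputs[name]
            fh.write(
                f"{name}\t{path.name}\t{_count_rows(path)}\t"
                f"{config.semantic_hash()}\t{config.seed}\n"
            )
    return manifest
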