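"""End-to-end orchestration: VCF -> segments -> summaries -> islands -> genes.

A run is driven by a single :class:`RunConfig` (loadable from YAML), writes
every stage's table under one output directory, and records a manifest of
parameters, file checksums and package version. The manifest carries no
timestamps, so rerunning an identical config on identical inputs yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import gene_report, overlap_islands_genes
from .detect import ROHParameters, call_segments
from .io import read_gene_models, read_vcf, write_segments
from .islands import (incidence_threshold, manhattan_export, merge_islands,
                      snp_incidence, write_islands_bed)
from .summaries import (froh_per_sample, genome_span, length_class_table,
                        per_chromosome_summary, DEFAULT_CLASS_BOUNDS_KB)

logger = logging.getLogger("rohscan")

OUTPUT_FILES = (
    "segments.tsv",
    "length_classes.tsv",
    "per_chromosome.tsv",
    "froh.tsv",
    "incidence.tsv",
    "islands.bed",
    "gene_report.tsv",
)


@dataclass
class IslandSettings:
    mode: str = "fixed"       # 'fixed' or 'quantile'
    value: float = 0.30
    max_gap_snps: int = 0
    min_snps: int = 2


@dataclass
class RunConfig:
    vcf: str = ""
    genes: str | None = None
    out_dir: str = "rohscan_out"
    min_site_quality: float = 10.0
    autosomes_only: bool = True
    roh: ROHParameters = field(default_factory=ROHParameters)
    islands: IslandSettings = field(default_factory=IslandSettings)
    class_bounds_kb: tuple[float, ...] = DEFAULT_CLASS_BOUNDS_KB
    seed: int = 0
    log_level: str = "INFO"
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        roh = ROHParameters(**raw.pop("roh", {}))
        islands = IslandSettings(**raw.pop("islands", {}))
        bounds = tuple(raw.pop("class_bounds_kb", DEFAULT_CLASS_BOUNDS_KB))
        return cls(roh=roh, islands=islands, class_bounds_kb=bounds, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_bounds_kb"] = list(self.class_bounds_kb)
        d.pop("force")  # execution flag, not an analysis parameter
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest dictionary."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    vcf_path = Path(config.vcf)
    if not vcf_path.exists():
        raise FileNotFoundError(f"input VCF does not exist: {vcf_path}")
    genes_path = Path(config.genes) if config.genes else None
    if genes_path is not None and not genes_path.exists():
        raise FileNotFoundError(f"gene-model file does not exist: {genes_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.force:
        existing = [f for f in OUTPUT_FILES if (out / f).exists()]
        if existing:
            raise FileExistsError(
                f"outputs already present in {out} (use force=True): {existing}")

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result

    matrix = stage("read_vcf", read_vcf, vcf_path,
                   min_site_quality=config.min_site_quality,
                   autosomes_only=config.autosomes_only)
    segments = stage("call_segments", call_segments, matrix, config.roh)
    stage("write_segments", write_segments, segments, out / "segments.tsv")

    l_genome = stage("genome_span", genome_span, matrix)
    table = stage("length_class_table", length_class_table, segments,
                  config.class_bounds_kb, l_genome)
    table.to_csv(out / "length_classes.tsv", sep="\t", index=False,
                 float_format="%.4f")
    per_chrom = stage("per_chromosome_summary", per_chromosome_summary,
                      segments, matrix)
    per_chrom.to_csv(out / "per_chromosome.tsv", sep="\t", index=False,
                     float_format="%.4f")
    froh = stage("froh", froh_per_sample, segments, matrix.samples, l_genome)
    froh.to_tsv(out / "froh.tsv")

    track = stage("snp_incidence", snp_incidence, segments, matrix)
    threshold = stage("incidence_threshold", incidence_threshold, track,
                      config.islands.mode, config.islands.value)
    stage("manhattan_export", manhattan_export, track, threshold,
          out / "incidence.tsv")
    islands = stage("merge_islands", merge_islands, track, threshold,
                    config.islands.max_gap_snps, config.islands.min_snps)
    stage("write_islands", write_islands_bed, islands, out / "islands.bed")

    if genes_path is not None:
        genes = stage("read_gene_models", read_gene_models, genes_path)
        hits, _ = stage("overlap", overlap_islands_genes, islands, genes)
    else:
        hits = []
    stage("gene_report", gene_report, hits, out / "gene_report.tsv")

    manifest = {
        "package": "rohscan",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "inputs": {
            str(vcf_path): _sha256(vcf_path),
            **({str(genes_path): _sha256(genes_path)} if genes_path else {}),
        },
        "outputs": {f: _sha256(out / f) for f in OUTPUT_FILES},
        "n_samples": matrix.n_samples,
        "n_sites": matrix.n_sites,
        "n_segments": len(segments),
        "n_islands": len(islands),
        "n_gene_hits": len(hits),
        "mean_froh": froh.mean_froh,
        "threshold": threshold,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
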