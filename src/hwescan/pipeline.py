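"""End-to-end pipeline: filter -> test -> classify -> features ->
association -> optional region scan, with files in and files out."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__, genomic_scan, io as _io
from .model import HWEDepartureModel
from .types import GenomicInterval

logger = logging.getLogger("hwescan")


@dataclass
class RunConfig:
    """Configuration for one pipeline run; round-trips through JSON."""

    counts_path: Optional[str] = None
    vcf_path: Optional[str] = None
    sample_map_path: Optional[str] = None  # TSV: sample <tab> population
    cnv_bed_path: Optional[str] = None
    out_dir: str = "hwescan_out"
    total_n: Optional[int] = None
    alpha: float = 1e-5
    dof: int = 2
    min_call_rate: float = 0.80
    strict_call_rate: float = 0.98
    strict: bool = False
    min_maf: float = 0.01
    pop_min_maf: float = 0.001
    scan_population: Optional[str] = None
    scan_region: Optional[str] = None  # "chrom:start-end", 1-based inclusive
    cluster_window_bp: int = 10_000
    cluster_min_size: int = 5
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (1-based inclusive) into a 0-based interval."""
    chrom, _, span = text.partition(":")
    start_s, _, end_s = span.partition("-")
    start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    if not chrom or start < 1 or end < start:
        raise ValueError(f"bad region string: {text!r}")
    return GenomicInterval(chrom=chrom, start=start - 1, end=end)


def read_sample_map(path: str | Path) -> dict[str, str]:
    mapping = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sample, _, pop = line.partition("\t")
        mapping[sample.strip()] = pop.strip()
    return mapping


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the pipeline described by ``config``; returns output paths.

    Writes: ``results.tsv`` (per-distribution tests), ``features.tsv``,
    ``filter_log.tsv``, ``association.tsv`` (feature-comparison table),
    ``track.tsv`` + ``clusters.bed`` when a scan is requested, and
    ``run_log.json`` with the config, package version and record counts
    at each stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    if config.counts_path:
        variants = _io.read_counts_table(config.counts_path)
    elif config.vcf_path:
        if not config.sample_map_path:
            raise ValueError("vcf input needs sample_map_path")
        variants = _io.read_vcf_counts(
            config.vcf_path,
            read_sample_map(config.sample_map_path),
            total_n=config.total_n,
        )
    else:
        variants = []
    stage_counts["variants_read"] = len(variants)

    intervals = (
        _io.read_cnv_bed(config.cnv_bed_path) if config.cnv_bed_path else []
    )
    model = HWEDepartureModel(
        variants,
        total_n=config.total_n,
        alpha=config.alpha,
        dof=config.dof,
        min_call_rate=config.strict_call_rate if config.strict else config.min_call_rate,
        min_maf=config.min_maf,
        pop_min_maf=config.pop_min_maf,
        cnv_intervals=intervals,
    )
    res = model.fit()
    stage_counts["variants_included"] = (
        int(res.filter_log["included"].sum()) if len(res.filter_log) else 0
    )
    stage_counts["distributions_tested"] = len(res.results)
    stage_counts["loh"] = int((res.results["classification"] == "LOH").sum())
    stage_counts["goh"] = int((res.results["classification"] == "GOH").sum())

    paths = {
        "results": str(out / "results.tsv"),
        "features": str(out / "features.tsv"),
        "filter_log": str(out / "filter_log.tsv"),
        "run_log": str(out / "run_log.json"),
    }
    _io.write_tsv(
        res.results.sort_values(["variant_id", "population"]), paths["results"]
    )
    _io.write_tsv(res.features.sort_values("variant_id"), paths["features"])
    _io.write_tsv(res.filter_log, paths["filter_log"])

    has_departure = stage_counts["loh"] + stage_counts["goh"] > 0
    has_control = (res.results["classification"] == "NONE").any()
    if len(res.results) and has_departure and has_control:
        paths["association"] = str(out / "association.tsv")
        _io.write_tsv(res.association_report(), paths["association"])
    else:
        logger.warning("association report skipped (no departures or no controls)")

    if config.scan_population:
        region = parse_region(config.scan_region) if config.scan_region else None
        track = res.scan_track(
            config.scan_population, region=region, min_maf=config.min_maf
        )
        clusters = genomic_scan.detect_clusters(
            track,
            window_bp=config.cluster_window_bp,
            min_cluster_size=config.cluster_min_size,
        )
        paths["track"] = str(out / "track.tsv")
        paths["clusters"] = str(out / "clusters.bed")
        _io.write_track(track, paths["track"])
        _io.write_clusters_bed(clusters, paths["clusters"])
        stage_counts["track_variants"] = len(track)
        stage_counts["clusters"] = len(clusters)
        stage_counts["missingness_usable"] = int(track.missingness_usable)

    log = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "stage_counts": stage_counts,
        "outputs": paths,
    }
    Path(paths["run_log"]).write_text(json.dumps(log, indent=2) + "\n")
    return paths
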