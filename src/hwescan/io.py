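"""Readers and writers for the package's file formats.

Formats handled here:

* genotype-count tables — TSV, one row per variant x population, header
  ``variant_id chrom pos ref alt population n_aa n_ab n_bb n_missing``
  (allele A is the REF allele; counts are strict integers);
* multi-sample VCF 4.x (read via cyvcf2; biallelic non-symbolic records
  only) and a minimal GT-only VCF 4.2 writer for simulated cohorts;
* BED for CNV intervals (0-based half-open; 4th column ``loss``/``gain``,
  optional 5th column allele frequency) and for cluster calls;
* TSV result/track tables.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genomic_scan import ClusterCall, ScanTrack
from .synthetic_data import SimulatedCohort
from .types import (
    GenomicInterval,
    GenotypeCounts,
    IntervalKind,
    VariantRecord,
    normalize_chrom,
)

logger = logging.getLogger("hwescan")

COUNTS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "population",
    "n_aa",
    "n_ab",
    "n_bb",
    "n_missing",
]


def _parse_int(text: str, line_no: int, col: str) -> int:
    s = text.strip()
    if not s or not s.lstrip("-").isdigit():
        raise ValueError(
            f"line {line_no}: column {col!r} must be a plain integer, got {text!r}"
        )
    return int(s)


def read_counts_table(path: str | Path) -> list[VariantRecord]:
    """Read a genotype-count TSV into VariantRecords (grouped by variant).

    Parsing is strict: the header must match, counts must be plain
    non-negative integers (thousands separators rejected), and a duplicate
    variant x population row is an error.  Malformed rows report their
    line number.
    """
    path = Path(path)
    records: dict[str, VariantRecord] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != COUNTS_COLUMNS:
            raise ValueError(
                f"{path}: bad header; expected {COUNTS_COLUMNS}, got {header}"
            )
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(COUNTS_COLUMNS):
                raise ValueError(
                    f"{path}: line {line_no}: expected "
                    f"{len(COUNTS_COLUMNS)} fields, got {len(fields)}"
                )
            row = dict(zip(COUNTS_COLUMNS, fields))
            pos = _parse_int(row["pos"], line_no, "pos")
            counts = GenotypeCounts(
                *(
                    _parse_int(row[c], line_no, c)
                    for c in ("n_aa", "n_ab", "n_bb", "n_missing")
                )
            )
            vid = row["variant_id"]
            rec = records.get(vid)
            if rec is None:
                rec = VariantRecord(
                    variant_id=vid,
                    chrom=row["chrom"],
                    pos=pos,
                    ref=row["ref"],
                    alt=row["alt"],
                )
                records[vid] = rec
            if row["population"] in rec.per_pop:
                raise ValueError(
                    f"{path}: line {line_no}: duplicate row for "
                    f"{vid} x {row['population']}"
                )
            rec.per_pop[row["population"]] = counts
    return list(records.values())


def write_counts_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in variants:
        for pop in sorted(v.per_pop):
            c = v.per_pop[pop]
            rows.append(
                [v.variant_id, v.chrom, v.pos, v.ref, v.alt, pop,
                 c.n_aa, c.n_ab, c.n_bb, c.n_missing]
            )
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# VCF

_VALID_BASES = set("ACGTN")


def read_vcf_counts(
    path: str | Path,
    sample_to_population: Mapping[str, str],
    region: Optional[GenomicInterval] = None,
    total_n: Optional[int] = None,
) -> list[VariantRecord]:
    """Count per-population genotypes from a multi-sample VCF.

    Only biallelic records with sequence alleles are counted; multi-allelic
    and symbolic records are skipped (the number skipped is logged).
    Half-calls and missing GTs count as missing; phased and unphased
    genotypes are treated identically.  Samples in the map but absent from
    the VCF trigger a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = set(sample_to_population) - set(samples)
    if unknown:
        warnings.warn(f"{len(unknown)} mapped sample(s) not in VCF; excluded")
    pop_of = [sample_to_population.get(s) for s in samples]
    pops = sorted({p for p in pop_of if p is not None})
    records: list[VariantRecord] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if not (set(ref.upper()) <= _VALID_BASES and set(alt.upper()) <= _VALID_BASES):
            n_skipped += 1
            continue
        if region is not None and not region.contains_pos(var.CHROM, var.POS):
            continue
        tallies = {p: [0, 0, 0, 0] for p in pops}  # aa, ab, bb, missing
        for sample_idx, gt in enumerate(var.genotypes):
            pop = pop_of[sample_idx]
            if pop is None:
                continue
            alleles = gt[:-1]
            if len(alleles) != 2 or -1 in alleles:
                tallies[pop][3] += 1
            else:
                tallies[pop][alleles[0] + alleles[1]] += 1
        vid = var.ID or f"{var.CHROM}:{var.POS}:{ref}:{alt}"
        records.append(
            VariantRecord(
                variant_id=vid,
                chrom=normalize_chrom(var.CHROM),
                pos=var.POS,
                ref=ref,
                alt=alt,
                per_pop={p: GenotypeCounts(*tallies[p]) for p in pops},
                total_n=total_n,
            )
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic/symbolic records", n_skipped)
    return records


def write_vcf(
    cohort: SimulatedCohort, path: str | Path, seed: int = 0
) -> dict[str, list[str]]:
    """Write a simulated cohort as a GT-only VCF 4.2 with per-sample genotypes.

    Sample genotypes are assigned consistently with each variant's counts
    and permuted with a generator seeded from ``seed`` and the variant
    index, so output is byte-identical for a given cohort and seed.
    Returns the sample -> population map used (as population -> samples).
    """
    pops = sorted({p for v in cohort.variants for p in v.per_pop})
    pop_sizes = {
        p: max(v.per_pop[p].n_total for v in cohort.variants if p in v.per_pop)
        for p in pops
    }
    sample_names = {
        p: [f"{p}_{i:05d}" for i in range(pop_sizes[p])] for p in pops
    }
    all_samples = [s for p in pops for s in sample_names[p]]
    lines = ["##fileformat=VCFv4.2"]
    for chrom in sorted({v.chrom for v in cohort.variants}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(all_samples)
    )
    variants = sorted(cohort.variants, key=lambda v: (v.chrom, v.pos))
    for i, v in enumerate(variants):
        rng = np.random.default_rng((seed, i))
        gts: list[str] = []
        for p in pops:
            c = v.per_pop.get(p)
            if c is None:
                gts.extend(["./."] * pop_sizes[p])
                continue
            block = (
                ["0/0"] * c.n_aa
                + ["0/1"] * c.n_ab
                + ["1/1"] * c.n_bb
                + ["./."] * (pop_sizes[p] - c.n_called)
            )
            gts.extend(np.array(block)[rng.permutation(len(block))].tolist())
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return sample_names


# --------------------------------------------------------------------------
# BED

_KIND_NAMES = {"loss": IntervalKind.LOSS, "gain": IntervalKind.GAIN}


def read_cnv_bed(path: str | Path) -> list[GenomicInterval]:
    """CNV intervals from BED: chrom, start, end, loss|gain[, frequency]."""
    intervals = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}: line {line_no}: need >= 4 BED columns")
        kind = _KIND_NAMES.get(fields[3].strip().lower())
        if kind is None:
            raise ValueError(
                f"{path}: line {line_no}: 4th column must be loss or gain"
            )
        freq = float(fields[4]) if len(fields) > 4 and fields[4].strip() else None
        intervals.append(
            GenomicInterval(
                chrom=fields[0],
                start=_parse_int(fields[1], line_no, "start"),
                end=_parse_int(fields[2], line_no, "end"),
                kind=kind,
                frequency=freq,
            )
        )
    return intervals


def write_clusters_bed(clusters: Sequence[ClusterCall], path: str | Path) -> None:
    """Cluster calls as BED (0-based half-open) with direction in the name."""
    lines = [
        f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.direction.value}"
        f"\t{c.n_significant}"
        for c in clusters
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_truth_bed(cohort: SimulatedCohort, path: str | Path) -> None:
    """Ground-truth mechanism intervals of a simulated region as BED."""
    lines = []
    for iv in cohort.layout:
        name = iv.kind.value if iv.kind else "INTERVAL"
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_track(track: ScanTrack, path: str | Path) -> None:
    track.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
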