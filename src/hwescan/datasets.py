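"""Small published example datasets shipped with the package.

These are the printed worked examples from the ExAC-based study of
directional Hardy-Weinberg departure: three variants' genotype counts
across the six ExAC super-populations, the per-population departure
counts used for the heterogeneity tests, and the chromosome-17
indel-vs-SNP departure table from the 1000 Genomes replication.  They are
inputs (typed from the published tables), used by the examples, tests and
the acceptance script.
"""

from __future__ import annotations

import pandas as pd

from .types import GenotypeCounts, VariantRecord

#: ExAC cohort size (denominator for missingness).
EXAC_TOTAL_N = 60706

#: Super-population labels.
POPULATIONS = ("AFR", "AMR", "EAS", "FIN", "NFE", "SAS")

# Published genotype counts (AA, AB, BB) per super-population for the three
# worked-example variants.  Allele A is as printed.
_EXAMPLE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    # C1orf62 — SNP inside the common deletion polymorphism esv3587138
    "rs7551421": {
        "AFR": (691, 2455, 2051),
        "EAS": (2392, 1463, 429),
        "FIN": (864, 1630, 812),
        "NFE": (5564, 15393, 12372),
        "AMR": (1658, 2593, 1523),
        "SAS": (2149, 3760, 2333),
    },
    # C11orf10 — SNP with strong allele-frequency differences across populations
    "rs509360": {
        "AFR": (3552, 1468, 173),
        "EAS": (968, 1914, 1434),
        "FIN": (416, 1503, 1380),
        "NFE": (3423, 14518, 15378),
        "AMR": (195, 1396, 4190),
        "SAS": (4205, 3292, 749),
    },
    # C1orf31 — insertion/deletion variant with excess heterozygotes everywhere
    "rs58896934": {
        "AFR": (110, 1620, 2198),
        "EAS": (829, 2124, 622),
        "FIN": (917, 1632, 416),
        "NFE": (5685, 16989, 4949),
        "AMR": (531, 2895, 1412),
        "SAS": (1943, 4079, 941),
    },
}

_EXAMPLE_META = {
    "rs7551421": {"chrom": "1", "pos": 108826383, "ref": "A", "alt": "G"},
    "rs509360": {"chrom": "11", "pos": 61781087, "ref": "A", "alt": "G"},
    # insertion/deletion type
    "rs58896934": {"chrom": "1", "pos": 193122703, "ref": "CT", "alt": "C"},
}

#: Published directional-departure labels per variant x population
#: (empty string = no departure).
EXAMPLE_LABELS: dict[str, dict[str, str]] = {
    "rs7551421": {
        "AFR": "",
        "EAS": "LOH",
        "FIN": "",
        "NFE": "LOH",
        "AMR": "LOH",
        "SAS": "LOH",
    },
    "rs509360": {
        "AFR": "",
        "EAS": "LOH",
        "FIN": "",
        "NFE": "",
        "AMR": "LOH",
        "SAS": "",
    },
    "rs58896934": {pop: "GOH" for pop in POPULATIONS},
}

#: Per-population counts of control (in-HWE) distributions and of LoH / GoH
#: departures from the published association table.
HETEROGENEITY_CONTROL = {
    "AFR": 533, "AMR": 509, "EAS": 491, "FIN": 528, "NFE": 493, "SAS": 516,
}
HETEROGENEITY_LOH = {"AFR": 3, "AMR": 19, "EAS": 2, "FIN": 2, "NFE": 5, "SAS": 10}
HETEROGENEITY_GOH = {"AFR": 7, "AMR": 15, "EAS": 10, "FIN": 7, "NFE": 45, "SAS": 9}

#: 1000 Genomes chromosome-17 replication: departure counts by variant type,
#: as a 2x2 table [[indel_departing, indel_ok], [snp_departing, snp_ok]].
CHR17_INDEL_SNP_TABLE = [[1281, 31650 - 1281], [2661, 229021 - 2661]]


def example_variants() -> list[VariantRecord]:
    """The three published worked-example variants as VariantRecords.

    Missing counts are not printed per population; they are set to zero,
    and ``total_n`` is left unset so the records carry only what the
    source table states.
    """
    records = []
    for vid, pops in _EXAMPLE_COUNTS.items():
        meta = _EXAMPLE_META[vid]
        records.append(
            VariantRecord(
                variant_id=vid,
                chrom=meta["chrom"],
                pos=meta["pos"],
                ref=meta["ref"],
                alt=meta["alt"],
                per_pop={
                    pop: GenotypeCounts(*pops[pop]) for pop in POPULATIONS
                },
            )
        )
    return records


def example_counts(variant_id: str, population: str) -> GenotypeCounts:
    """Genotype counts for one example variant in one super-population."""
    return GenotypeCounts(*_EXAMPLE_COUNTS[variant_id][population])


def example_counts_frame() -> pd.DataFrame:
    """All example counts as a tidy DataFrame (one row per variant x population)."""
    rows = []
    for vid, pops in _EXAMPLE_COUNTS.items():
        meta = _EXAMPLE_META[vid]
        for pop in POPULATIONS:
            aa, ab, bb = pops[pop]
            rows.append(
                {
                    "variant_id": vid,
                    "chrom": meta["chrom"],
                    "pos": meta["pos"],
                    "ref": meta["ref"],
                    "alt": meta["alt"],
                    "population": pop,
                    "n_aa": aa,
                    "n_ab": ab,
                    "n_bb": bb,
                    "n_missing": 0,
                }
            )
    return pd.DataFrame(rows)
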