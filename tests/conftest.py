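import pytest

from hwescan import datasets

# Published per-cell values for the three worked-example variants:
# (exp_aa, exp_ab, exp_bb, allele_a_freq, p, oe_ratio, label) per population.
# Non-significant p-values are printed to 2 decimals, significant ones to
# 2 significant figures; labels are "" (none), "LOH" or "GOH".
TABLE2_PRINTED = {
    "rs7551421": {
        "AFR": (708, 2421, 2068, 0.37, "0.59", 1.01, ""),
        "EAS": (2277, 1692, 314, 0.73, "8.4e-18", 0.86, "LOH"),
        "FIN": (853, 1653, 801, 0.51, "0.73", 0.99, ""),
        "NFE": (5276, 15969, 12084, 0.40, "3.8e-10", 0.96, "LOH"),
        "AMR": (1512, 2885, 1377, 0.51, "1.3e-13", 0.90, "LOH"),
        "SAS": (1970, 4119, 2154, 0.49, "2.6e-14", 0.91, "LOH"),
    },
    "rs509360": {
        "AFR": (3537, 1497, 158, 0.83, "0.37", 0.98, ""),
        "EAS": (859, 2133, 1325, 0.45, "1.4e-10", 0.90, "LOH"),
        "FIN": (413, 1509, 1377, 0.35, "0.98", 1.00, ""),
        "NFE": (3425, 14515, 15380, 0.32, "1.00", 1.00, ""),
        "AMR": (138, 1510, 4133, 0.15, "6.8e-08", 0.92, "LOH"),
        "SAS": (4152, 3399, 696, 0.71, "0.02", 0.97, ""),
    },
    "rs58896934": {
        "AFR": (215, 1409, 2303, 0.23, "7.6e-20", 1.15, "GOH"),
        "EAS": (1000, 1782, 793, 0.53, "2.0e-29", 1.19, "GOH"),
        "FIN": (1013, 1440, 512, 0.58, "3.8e-12", 1.13, "GOH"),
        "NFE": (7279, 13802, 6543, 0.51, "0", 1.23, "GOH"),
        "AMR": (809, 2339, 1690, 0.41, "3.8e-60", 1.24, "GOH"),
        "SAS": (2278, 3409, 1276, 0.57, "4.8e-59", 1.20, "GOH"),
    },
}

# Per-population allele-A frequencies printed for the two SNP examples
# (the MAF column of their six rows).
PRINTED_FREQS = {
    "rs509360": {
        "AFR": 0.83, "EAS": 0.45, "FIN": 0.35, "NFE": 0.32, "AMR": 0.15, "SAS": 0.71,
    },
    "rs7551421": {
        "AFR": 0.37, "EAS": 0.73, "FIN": 0.51, "NFE": 0.40, "AMR": 0.51, "SAS": 0.49,
    },
}


@pytest.fixture(scope="session")
def table2_printed():
    return TABLE2_PRINTED


@pytest.fixture(scope="session")
def example_variants():
    return datasets.example_variants()
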