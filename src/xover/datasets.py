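"""Published summary counts bundled for worked examples.

Population sizes and total detected male crossovers for twelve
*Brassica* hybrid testcross populations segregating for extra C
chromosomes (diploid AA controls, single/multiple C-addition hybrids,
and AAC allotriploids). Only these two printed counts per population
are public; the per-individual genotype matrices are not, so everything
derivable here is arithmetic on (n, total): per-meiocyte means
(2 x total / n), fold changes, and spans of variation explained.
"""

from __future__ import annotations

import pandas as pd

#: (hybrid, n individuals genotyped, total crossovers detected)
_COUNTS = [
    ("ArAr'",           429, 2953),
    ("ArAr'+1Co(9)",    125, 1352),
    ("ArAr'Co",         126, 1826),
    ("AnAr'",           298, 2608),
    ("AnAr'+1Cn(4)",    136, 1329),
    ("AnAr'+1Cn(8)",    127, 1198),
    ("AnAr'+1Cn(9)",    129, 1063),
    ("AnAr'+2Cn(4,8)",  123, 1398),
    ("AnAr'+2Cn(4,9)",  134, 1539),
    ("AnAr'+2Cn(8,9)",  121, 1296),
    ("AnAr'+3Cn(4,8,9)", 128, 1753),
    ("AnAr'Cn",         162, 2618),
]


def brassica_testcross_counts() -> pd.DataFrame:
    """The twelve (hybrid, n, total crossovers) records as a DataFrame."""
    return pd.DataFrame(_COUNTS,
                        columns=["hybrid", "n_individuals",
                                 "total_crossovers"])
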