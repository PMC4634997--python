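"""Bundled reference data: published per-gene p-values from a human TRB study.

A published vaccination study compared the beta-chain (TRB) clonotype
diversity of two T cell populations (CD4- vs CD4+) from one H1N1-vaccinated
donor at four time points: pre-vaccination ("Pre") and days 3, 8 and 26
post-vaccination ("d3", "d8", "d26").  For each comparison the study printed
the per-gene unadjusted p-values below 0.05 of the pooled two-proportion
z-test, in increasing order; all other family members had larger p-values.

These printed values are bundled here as inputs for re-running the
adjustment stage: they exercise the truncated-family support of
:func:`clonostat.adjust.adjust_pvalues` (only the r smallest of m family
p-values are available) and anchor the package's validation suite.

Family sizes were not printed; they are recovered from the ratio of the
printed Bonferroni-adjusted to unadjusted p-value of a top-ranked gene
(for d3 the rank-2 row is used because the rank-1 raw value is truncated
by its display precision).  The counted candidates per comparison are 48
non-pseudogene V genes, 2 D genes and 13 J genes, minus the genes failing
the expected-count validity rule, giving 61 (Pre, d26) and 59 (d3, d8).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "COMPARISONS",
    "FAMILY_SIZES",
    "WORKED_EXAMPLE",
    "reference_pvalues",
    "derive_family_size",
]

#: gene -> printed unadjusted p-value, per comparison, in printed order.
COMPARISONS: dict[str, list[tuple[str, float]]] = {
    "Pre": [
        ("TRBV5-1", 1.3e-08), ("TRBV27", 4.81e-07), ("TRBJ2-1", 1.2e-05),
        ("TRBV7-2", 7e-05), ("TRBV7-9", 0.00011), ("TRBV20-1", 0.00012),
        ("TRBV7-6", 0.00243), ("TRBJ2-5", 0.00304), ("TRBV25-1", 0.00439),
        ("TRBJ2-7", 0.00597), ("TRBV4-1", 0.00940), ("TRBV6-4", 0.01023),
        ("TRBV11-2", 0.01067), ("TRBJ1-5", 0.01314), ("TRBV12-4", 0.01334),
        ("TRBV9", 0.02552), ("TRBV12-3", 0.04187),
    ],
    "d3": [
        ("TRBV5-1", 1.00e-15), ("TRBV27", 8.72e-13), ("TRBV7-2", 1.03e-12),
        ("TRBJ2-7", 1.32e-08), ("TRBV7-9", 5.45e-08), ("TRBV4-1", 7.79e-08),
        ("TRBJ2-5", 9.18e-08), ("TRBV4-3", 8.52e-05), ("TRBJ2-1", 0.00041),
        ("TRBV20-1", 0.00061), ("TRBV15", 0.00088), ("TRBV7-6", 0.00190),
        ("TRBV12-4", 0.00288), ("TRBV24-1", 0.00476), ("TRBJ1-5", 0.01167),
        ("TRBJ2-2", 0.01221), ("TRBV9", 0.01517), ("TRBV18", 0.01726),
        ("TRBV25-1", 0.01860), ("TRBJ1-3", 0.02756), ("TRBV14", 0.03018),
        ("TRBD2", 0.04008), ("TRBD1", 0.04008), ("TRBV12-3", 0.04966),
    ],
    "d8": [
        ("TRBV27", 1.36e-13), ("TRBJ2-7", 6.45e-10), ("TRBV5-1", 7.24e-10),
        ("TRBV4-1", 6.44e-08), ("TRBV7-2", 8.27e-07), ("TRBJ2-5", 1.08e-05),
        ("TRBJ2-1", 0.00024), ("TRBV7-9", 5.00e-04), ("TRBJ2-3", 0.00150),
        ("TRBJ1-1", 0.00212), ("TRBJ2-2", 0.00471), ("TRBV25-1", 0.00914),
        ("TRBV4-3", 0.01085), ("TRBV5-4", 0.01423), ("TRBV7-7", 0.01423),
        ("TRBV9", 0.01776), ("TRBV20-1", 0.01828), ("TRBV12-3", 0.02632),
        ("TRBV18", 0.04074),
    ],
    "d26": [
        ("TRBV27", 2.14e-26), ("TRBJ2-7", 4.54e-17), ("TRBV7-2", 1.70e-14),
        ("TRBV5-1", 9.10e-14), ("TRBV4-1", 2.41e-10), ("TRBV4-3", 1.66e-07),
        ("TRBJ2-1", 3.15e-07), ("TRBJ2-5", 5.49e-07), ("TRBV20-1", 6.34e-07),
        ("TRBV6-2", 1.17e-06), ("TRBV25-1", 1.23e-06), ("TRBJ2-3", 0.00005),
        ("TRBV12-4", 0.00011), ("TRBV18", 0.00048), ("TRBJ1-4", 0.00080),
        ("TRBV6-1", 0.00154), ("TRBV7-9", 0.00301), ("TRBV7-6", 0.00303),
        ("TRBV13", 0.00666), ("TRBV12-3", 0.01313), ("TRBV29-1", 0.01522),
        ("TRBJ1-2", 0.02597), ("TRBV11-2", 0.02979), ("TRBV6-4", 0.03543),
        ("TRBV5-4", 0.03570), ("TRBV9", 0.04172), ("TRBJ1-3", 0.04207),
    ],
}

#: Family sizes (valid tests per comparison), derived as described above.
FAMILY_SIZES: dict[str, int] = {"Pre": 61, "d3": 59, "d8": 59, "d26": 61}

#: The study's fully worked single-gene example (Pre comparison, TRBV5-1):
#: clonotype counts per set and the group totals.
WORKED_EXAMPLE = {
    "gene": "TRBV5-1", "group": "TRBV",
    "set_i": "MID1", "set_j": "MID2",
    "count_i": 244, "n_i": 2234,
    "count_j": 420, "n_j": 2523,
}


def reference_pvalues(comparison: str) -> pd.DataFrame:
    """Printed unadjusted p-values of one comparison as a tidy frame.

    Columns: gene, raw_p; rows in increasing raw_p order as printed.
    """
    if comparison not in COMPARISONS:
        raise KeyError(
            f"unknown comparison {comparison!r}; choose from {sorted(COMPARISONS)}")
    rows = COMPARISONS[comparison]
    return pd.DataFrame(rows, columns=["gene", "raw_p"])


def derive_family_size(raw_p: float, bonferroni_adjusted: float) -> int:
    """Recover m from a printed Bonferroni-adjusted / raw p-value pair."""
    if raw_p <= 0 or bonferroni_adjusted <= 0:
        raise ValueError("p-values must be positive")
    return round(bonferroni_adjusted / raw_p)
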