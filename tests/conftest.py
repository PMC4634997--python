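"""Shared fixtures: handcrafted record sets and a worked-example builder."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from clonostat import ClonotypeRecord

# Derandomise hypothesis so the suite is reproducible everywhere.
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_records(v_counts: dict[str, int], set_id: str,
                 j_genes: tuple[str, ...] = ("TRBJ1-1", "TRBJ2-1", "TRBJ2-7"),
                 d_gene: str | None = "TRBD1",
                 cdr3: str = "CASSLGTDTQYF", in_frame: bool = True,
                 n_sequences: int = 1) -> list[ClonotypeRecord]:
    """Expand a V-gene -> clonotype-count map into records.

    J genes are assigned round-robin; every record shares the same CDR3
    template (identity of the CDR3 is irrelevant to counting).
    """
    j_cycle = itertools.cycle(j_genes)
    records = []
    for v_gene, count in v_counts.items():
        for k in range(count):
            records.append(ClonotypeRecord(
                v_gene=v_gene, j_gene=next(j_cycle), cdr3_aa=cdr3,
                in_frame=in_frame, n_sequences=n_sequences, d_gene=d_gene,
                clonotype_id=f"{set_id}-{v_gene}-{k}", set_id=set_id))
    return records


@pytest.fixture(scope="session")
def worked_example_pair() -> tuple[list[ClonotypeRecord], list[ClonotypeRecord]]:
    """Two sets reproducing the reference single-gene comparison:
    TRBV5-1 carried by 244 of 2234 clonotypes in set i and 420 of 2523
    in set j, with the remainder spread over filler V genes."""
    filler_i = {"TRBV2": 700, "TRBV19": 650, "TRBV28": 640}
    filler_j = {"TRBV2": 750, "TRBV19": 703, "TRBV28": 650}
    counts_i = {"TRBV5-1": 244, **filler_i}
    counts_j = {"TRBV5-1": 420, **filler_j}
    assert sum(counts_i.values()) == 2234
    assert sum(counts_j.values()) == 2523
    return (make_records(counts_i, "MID1"), make_records(counts_j, "MID2"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
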