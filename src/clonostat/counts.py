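"""Per-gene count tables for one sequencing set and gene group.

Two counting modes exist.  *Diversity* counts distinct clonotypes per gene:
each clonotype contributes exactly once to one gene of a group, so the group
total equals the number of clonotypes carrying a gene of that group.
*Expression* sums the read counts (``n_sequences``) instead.  Clonotypes
lacking a gene for a group (typically an unresolved D) are omitted from that
group's table and its total.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import ClonotypeRecord, normalize_gene_name

__all__ = [
    "GeneCountTable",
    "NormalizedTable",
    "count_by_gene",
    "normalize_per_10000",
    "union_gene_inventory",
    "natural_gene_key",
]

_ROLES = {"V": "v_gene", "D": "d_gene", "J": "j_gene"}


def _role_of(group: str) -> str:
    """Map a group label ('V', 'J', 'TRBV', 'IGHJ', ...) to a gene role."""
    role = group[-1].upper()
    if role not in _ROLES:
        raise ValueError(f"unknown gene group {group!r}; expected a V, D or J group")
    return role


def natural_gene_key(gene: str) -> tuple:
    """Sort key comparing digit runs numerically: TRBV5-1 < TRBV12-3."""
    parts = re.split(r"(\d+)", gene)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class GeneCountTable:
    """Gene -> count for one set, group and mode, with the group total."""

    set_id: str
    group: str
    mode: str  # "diversity" or "expression"
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in {"diversity", "expression"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def count(self, gene: str) -> int:
        return self.counts.get(gene, 0)


@dataclass(frozen=True)
class NormalizedTable:
    """Counts rescaled to a common total of 10,000 for display."""

    set_id: str
    group: str
    mode: str
    values: Mapping[str, float]


def count_by_gene(records: Sequence[ClonotypeRecord], group: str,
                  mode: str = "diversity") -> GeneCountTable:
    """Tally clonotypes (diversity) or reads (expression) per gene of a group.

    Gene names are normalised so counts aggregate per gene, not per allele.
    """
    if mode not in {"diversity", "expression"}:
        raise ValueError(f"unknown mode {mode!r}")
    attr = _ROLES[_role_of(group)]
    set_ids = {r.set_id for r in records}
    if len(set_ids) > 1:
        raise ValueError(f"records span several sets: {sorted(set_ids)}")
    counts: dict[str, int] = {}
    for rec in records:
        raw = getattr(rec, attr)
        if raw is None:
            continue
        gene = normalize_gene_name(raw)
        weight = rec.n_sequences if mode == "expression" else 1
        counts[gene] = counts.get(gene, 0) + weight
    return GeneCountTable(set_id=next(iter(set_ids), ""), group=group,
                          mode=mode, counts=counts)


def normalize_per_10000(table: GeneCountTable) -> NormalizedTable:
    """Rescale a count table so its values sum to 10,000."""
    n = table.n_total
    if n == 0:
        raise ValueError(f"empty group {table.group!r}: nothing to normalize")
    values = {g: c * 10000.0 / n for g, c in table.counts.items()}
    return NormalizedTable(set_id=table.set_id, group=table.group,
                           mode=table.mode, values=values)


def union_gene_inventory(
    table_i: GeneCountTable,
    table_j: GeneCountTable,
    reference_order: Sequence[str] | None = None,
) -> list[str]:
    """Genes observed in at least one of the two tables, in display order.

    Genes absent from both sets carry no information (their difference in
    proportions is identically zero) and are excluded.  With a reference
    order (locus position), listed genes come first in that order and any
    others follow in natural order; otherwise the whole inventory is
    natural-ordered.
    """
    if table_i.group != table_j.group or table_i.mode != table_j.mode:
        raise ValueError("tables must share group and mode")
    present = ({g for g, c in table_i.counts.items() if c > 0}
               | {g for g, c in table_j.counts.items() if c > 0})
    if reference_order is not None:
        ref = [g for g in reference_order if g in present]
        rest = sorted(present - set(ref), key=natural_gene_key)
        return ref + rest
    return sorted(present, key=natural_gene_key)
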