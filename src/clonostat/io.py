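"""Reading, validating and filtering clonotype summary tables.

The canonical input is a minimal tab-separated dialect standing in for the
very wide clonotype summaries produced by high-throughput V-(D)-J annotation
portals: one row per amino-acid clonotype with its gene assignments, CDR3
amino-acid sequence, junction frame status and the number of sequencing reads
assigned to it.  A column-mapping argument lets other exports be adapted.

Lines starting with ``#`` are comments.  The writer emits the same dialect,
so ``write(read(x))`` round-trips field-for-field.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ClonotypeRecord",
    "FilterConfig",
    "GeneFunctionalityMap",
    "ClonotypeFormatError",
    "ClonotypeParseError",
    "DEFAULT_TRB_PSEUDOGENES",
    "AA_ALPHABET",
    "normalize_gene_name",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_functionality_map",
    "filter_clonotypes",
]

#: The 20 standard amino-acid one-letter codes accepted in CDR3 sequences.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

#: Human TRBV pseudogenes that cannot yield a productive receptor chain and
#: are excluded by default when comparing beta-chain repertoires.
DEFAULT_TRB_PSEUDOGENES = frozenset(
    {"TRBV1", "TRBV3-2", "TRBV12-1", "TRBV12-2", "TRBV21-1", "TRBV26"}
)

_REQUIRED_COLUMNS = ("v_gene", "j_gene", "cdr3_aa", "in_frame", "n_sequences")
_ALL_COLUMNS = ("clonotype_id", "set_id", "v_gene", "d_gene", "j_gene",
                "cdr3_aa", "in_frame", "n_sequences")

_TRUE_TOKENS = {"true", "t", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n"}


class ClonotypeFormatError(ValueError):
    """The table as a whole is malformed (missing columns, empty file)."""


class ClonotypeParseError(ValueError):
    """A single data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True, slots=True)
class ClonotypeRecord:
    """One amino-acid clonotype: a unique V-(D)-J rearrangement.

    ``n_sequences`` is the clonotype's expression count, i.e. the number of
    reads unambiguously assigned to it; diversity analyses count each record
    once regardless of this value.
    """

    v_gene: str
    j_gene: str
    cdr3_aa: str
    in_frame: bool
    n_sequences: int = 1
    d_gene: str | None = None
    clonotype_id: str = ""
    set_id: str = ""

    def __post_init__(self) -> None:
        if not self.v_gene or not self.j_gene:
            raise ValueError("v_gene and j_gene must be non-empty")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        bad = set(self.cdr3_aa) - _AA_SET
        if bad:
            raise ValueError(
                f"cdr3_aa contains non-standard characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Clonotype retention rules applied before any counting.

    The CDR3 length bounds are an inclusive keep-range: the defaults drop
    outlier junctions shorter than 4 or longer than 60 amino acids, keeping
    lengths 4 and 60 themselves.
    """

    cdr3_min_len: int = 4
    cdr3_max_len: int = 60
    require_in_frame: bool = True
    exclude_pseudogenes: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.cdr3_min_len <= self.cdr3_max_len):
            raise ValueError("need 1 <= cdr3_min_len <= cdr3_max_len")


@dataclass(frozen=True)
class GeneFunctionalityMap:
    """Gene name -> functionality class (F, ORF or P) plus a pseudogene list.

    Genes without an entry are classed ``unknown`` and kept (with a warning
    at filter time).  The pseudogene exclusion list is keyed on the V gene
    only; ORF genes are retained.
    """

    classes: Mapping[str, str] = field(default_factory=dict)
    pseudogene_exclusions: frozenset[str] = DEFAULT_TRB_PSEUDOGENES

    def classify(self, gene: str) -> str:
        return self.classes.get(normalize_gene_name(gene), "unknown")


_SPECIES_PREFIX = re.compile(r"^[A-Z][a-z]+$")  # e.g. "Homsap", "Musmus"
_ALLELE_SUFFIX = re.compile(r"\*\d+\S*$")


def normalize_gene_name(raw: str) -> str:
    """Reduce a decorated gene label to the bare gene name.

    Strips a species prefix ("Homsap TRBV5-1 F (F)"), an allele suffix
    ("TRBV5-1*01") and trailing functionality tokens, so counts aggregate
    per gene rather than per allele.  Idempotent.
    """
    if not raw or not raw.strip():
        raise ValueError("empty gene name")
    tokens = raw.split()
    if len(tokens) > 1 and _SPECIES_PREFIX.match(tokens[0]):
        tokens = tokens[1:]
    gene = _ALLELE_SUFFIX.sub("", tokens[0])
    if not gene:
        raise ValueError(f"cannot extract a gene name from {raw!r}")
    return gene


def _parse_bool(token: str, line: int) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise ClonotypeParseError(f"cannot parse in_frame value {token!r}", line)


def _check_gene_field(value: str, column: str, line: int) -> str:
    if "," in value:
        raise ClonotypeParseError(
            f"{column} holds a multi-gene list {value!r}; the canonical "
            "schema requires a unique gene per rearrangement", line
        )
    return value.strip()


def read_clonotype_table(
    path: str | Path,
    set_id: str = "",
    column_map: Mapping[str, str] | None = None,
) -> list[ClonotypeRecord]:
    """Read the canonical clonotype TSV into a list of records.

    Parameters
    ----------
    path:
        Tab-separated file with a header row; ``#`` lines are ignored.
    set_id:
        Identifier stamped on every record (overrides any set_id column).
    column_map:
        Optional mapping from canonical column names to the names used in
        the file, for adapting other exports.
    """
    path = Path(path)
    column_map = dict(column_map or {})

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        records: list[ClonotypeRecord] = []
        n_rows = 0
        for line_no, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                # column_map maps canonical name -> name used in the file
                reverse = {v: k for k, v in column_map.items()}
                header = [reverse.get(c, c) for c in row]
                missing = [c for c in _REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise ClonotypeFormatError(
                        f"missing mandatory column(s): {', '.join(missing)}"
                    )
                idx = {c: header.index(c) for c in header}
                continue
            n_rows += 1
            if len(row) < len(header):
                raise ClonotypeParseError(
                    f"expected {len(header)} fields, got {len(row)}", line_no
                )
            get = lambda col: row[idx[col]].strip() if col in idx else ""
            raw_n = get("n_sequences")
            try:
                n_seq = int(raw_n)
            except ValueError:
                raise ClonotypeParseError(
                    f"non-integer n_sequences {raw_n!r}", line_no
                ) from None
            cdr3 = get("cdr3_aa")
            bad = set(cdr3) - _AA_SET
            if bad:
                raise ClonotypeParseError(
                    f"cdr3_aa contains invalid characters {sorted(bad)}", line_no
                )
            d_gene = get("d_gene") or None
            if d_gene is not None:
                d_gene = _check_gene_field(d_gene, "d_gene", line_no)
            try:
                rec = ClonotypeRecord(
                    v_gene=_check_gene_field(get("v_gene"), "v_gene", line_no),
                    j_gene=_check_gene_field(get("j_gene"), "j_gene", line_no),
                    cdr3_aa=cdr3,
                    in_frame=_parse_bool(get("in_frame"), line_no),
                    n_sequences=n_seq,
                    d_gene=d_gene,
                    clonotype_id=get("clonotype_id"),
                    set_id=set_id or get("set_id"),
                )
            except ValueError as exc:
                raise ClonotypeParseError(str(exc), line_no) from None
            records.append(rec)

    if header is None:
        raise ClonotypeFormatError(f"{path}: empty file (no header row)")
    if n_rows == 0:
        warnings.warn(f"{path}: header present but no data rows", stacklevel=2)
    return records


def write_clonotype_table(records: Iterable[ClonotypeRecord],
                          path: str | Path) -> None:
    """Write records in the canonical TSV dialect (all eight columns)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ALL_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.clonotype_id, rec.set_id, rec.v_gene,
                rec.d_gene or "", rec.j_gene, rec.cdr3_aa,
                "true" if rec.in_frame else "false", rec.n_sequences,
            ])


def read_functionality_map(path: str | Path) -> GeneFunctionalityMap:
    """Read a two-column (gene, class) TSV into a functionality map.

    Genes classed ``P`` populate the pseudogene exclusion list.
    """
    classes: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ClonotypeFormatError(
                    f"line {line_no}: expected two columns (gene, class)"
                )
            gene, cls = normalize_gene_name(row[0]), row[1].strip()
            if cls not in {"F", "ORF", "P"}:
                raise ClonotypeFormatError(
                    f"line {line_no}: unknown functionality class {cls!r}"
                )
            classes[gene] = cls
    pseudo = frozenset(g for g, c in classes.items() if c == "P")
    return GeneFunctionalityMap(classes=classes, pseudogene_exclusions=pseudo)


def filter_clonotypes(
    records: Sequence[ClonotypeRecord],
    cfg: FilterConfig | None = None,
    functionality: GeneFunctionalityMap | None = None,
) -> tuple[list[ClonotypeRecord], list[tuple[ClonotypeRecord, str]]]:
    """Partition records into (kept, exclusion log).

    A record is dropped, with the first matching reason, when it is
    out-of-frame (if ``require_in_frame``), its CDR3 length lies outside
    the inclusive keep-range, or its V gene is a listed pseudogene (if
    ``exclude_pseudogenes``).  Every input record lands in exactly one of
    the two outputs, in input order.
    """
    cfg = cfg or FilterConfig()
    functionality = functionality or GeneFunctionalityMap()
    kept: list[ClonotypeRecord] = []
    dropped: list[tuple[ClonotypeRecord, str]] = []
    warned_unknown: set[str] = set()
    for rec in records:
        if cfg.require_in_frame and not rec.in_frame:
            dropped.append((rec, "out_of_frame"))
            continue
        if not (cfg.cdr3_min_len <= len(rec.cdr3_aa) <= cfg.cdr3_max_len):
            dropped.append((rec, "cdr3_length"))
            continue
        v_bare = normalize_gene_name(rec.v_gene)
        if cfg.exclude_pseudogenes and v_bare in functionality.pseudogene_exclusions:
            dropped.append((rec, "pseudogene"))
            continue
        if functionality.classes and functionality.classify(rec.v_gene) == "unknown" \
                and v_bare not in warned_unknown:
            warnings.warn(
                f"gene {v_bare} has unknown functionality; kept", stacklevel=2
            )
            warned_unknown.add(v_bare)
        kept.append(rec)
    if records and not kept:
        warnings.warn("no clonotypes survive filtering", stacklevel=2)
    return kept, dropped
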