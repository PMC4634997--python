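"""End-to-end orchestration: records -> results table -> adjustments -> files.

`compare_sets` is the in-memory core: it turns two filtered record
collections into one tidy results DataFrame (one row per gene and group)
carrying counts, proportions, normalised values, the Wald CI, the pooled
z-test, validity flags, and adjusted p-values with significance calls.
`run_compare` wraps it with file I/O, plots and a machine-readable run
manifest; `adjust_table` re-adjusts a stand-alone p-value list (for
re-checking published tables); `run_simulate` drives the Monte-Carlo
harness and writes its summaries.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .adjust import METHODS, adjust_pvalues
from .counts import count_by_gene, normalize_per_10000, union_gene_inventory
from .io import (ClonotypeRecord, FilterConfig, GeneFunctionalityMap,
                 filter_clonotypes, read_clonotype_table)
from .simulate import SimulationSpec, estimate_error_rates
from .stats import two_proportion_arrays

__all__ = [
    "ComparisonConfig",
    "DegenerateComparisonError",
    "compare_sets",
    "run_compare",
    "adjust_table",
    "run_simulate",
]


class DegenerateComparisonError(RuntimeError):
    """No valid test in any family: nothing to adjust or report."""


@dataclass
class ComparisonConfig:
    """Everything `run_compare` needs; defaults follow the standard procedure
    (alpha 0.05, 95% CI, expected-count threshold 5, CDR3 keep-range [4, 60],
    one combined family across groups, all seven procedures)."""

    set_i: str | Path = ""
    set_j: str | Path = ""
    id_i: str = "set_i"
    id_j: str = "set_j"
    groups: Sequence[str] = ("V", "D", "J")
    mode: str = "diversity"
    ci_level: float = 0.95
    alpha: float = 0.05
    procedures: Sequence[str] = METHODS
    min_expected: float = 5.0
    filter: FilterConfig = field(default_factory=FilterConfig)
    functionality: GeneFunctionalityMap | None = None
    family: str = "combined"  # or "per-group"
    reference_order: Sequence[str] | None = None
    ci_critical: float | None = None
    out_dir: str | Path = "clonostat_out"
    plot_format: str = "png"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.procedures) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown procedures: {sorted(unknown)}")
        if self.family not in {"combined", "per-group"}:
            raise ValueError("family must be 'combined' or 'per-group'")
        if self.mode not in {"diversity", "expression"}:
            raise ValueError("mode must be 'diversity' or 'expression'")


#: Column order of the results TSV.
RESULT_COLUMNS = [
    "gene", "group", "count_i", "count_j", "n_i", "n_j", "p_i", "p_j",
    "per10000_i", "per10000_j", "diff", "sd", "ci_low", "ci_high",
    "pooled_p", "pooled_sd", "z", "raw_p", "valid", "invalid_reason",
]


def compare_sets(
    records_i: Sequence[ClonotypeRecord],
    records_j: Sequence[ClonotypeRecord],
    groups: Sequence[str] = ("V", "D", "J"),
    mode: str = "diversity",
    ci_level: float = 0.95,
    alpha: float = 0.05,
    procedures: Sequence[str] = METHODS,
    min_expected: float = 5.0,
    family: str = "combined",
    reference_order: Sequence[str] | None = None,
    ci_critical: float | None = None,
) -> pd.DataFrame:
    """Per-gene comparison of two already-filtered record collections.

    Returns one row per gene of each requested group with the full
    statistical record plus ``adj_<method>`` and ``sig_<method>`` columns.
    Genes failing the validity rule keep their row (flagged) but get NaN
    adjusted values and never count toward the family size.  Groups absent
    from both collections are skipped.
    """
    frames: list[pd.DataFrame] = []
    for grp in groups:
        t_i = count_by_gene(records_i, grp, mode)
        t_j = count_by_gene(records_j, grp, mode)
        if t_i.n_total == 0 and t_j.n_total == 0:
            continue
        if t_i.n_total == 0 or t_j.n_total == 0:
            raise DegenerateComparisonError(
                f"group {grp}: one set has no clonotypes with a {grp} gene")
        genes = union_gene_inventory(t_i, t_j, reference_order=reference_order)
        counts_i = np.array([t_i.count(g) for g in genes])
        counts_j = np.array([t_j.count(g) for g in genes])
        stats = two_proportion_arrays(
            counts_i, t_i.n_total, counts_j, t_j.n_total,
            ci_level=ci_level, min_expected=min_expected, z_crit=ci_critical)
        norm_i = normalize_per_10000(t_i).values
        norm_j = normalize_per_10000(t_j).values
        frames.append(pd.DataFrame({
            "gene": genes, "group": grp,
            "count_i": counts_i, "count_j": counts_j,
            "n_i": t_i.n_total, "n_j": t_j.n_total,
            "p_i": stats["p_i"], "p_j": stats["p_j"],
            "per10000_i": [norm_i.get(g, 0.0) for g in genes],
            "per10000_j": [norm_j.get(g, 0.0) for g in genes],
            "diff": stats["diff"], "sd": stats["sd"],
            "ci_low": stats["ci_low"], "ci_high": stats["ci_high"],
            "pooled_p": stats["pooled_p"], "pooled_sd": stats["pooled_sd"],
            "z": stats["z"], "raw_p": stats["raw_p"],
            "valid": stats["valid"], "invalid_reason": stats["invalid_reason"],
        }))
    if not frames:
        raise DegenerateComparisonError("no requested group present in the data")
    table = pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]

    if not bool(table["valid"].any()):
        raise DegenerateComparisonError("no valid tests in any family")

    family_ids = (table["group"] if family == "per-group"
                  else pd.Series("combined", index=table.index))
    for method in procedures:
        table[f"adj_{method}"] = np.nan
    for _fam, idx in table.groupby(family_ids).groups.items():
        sub = table.loc[idx]
        valid_idx = sub.index[sub["valid"]]
        if len(valid_idx) == 0:
            continue
        raw = table.loc[valid_idx, "raw_p"].to_numpy()
        for method in procedures:
            table.loc[valid_idx, f"adj_{method}"] = adjust_pvalues(raw, method=method)
    for method in procedures:
        table[f"sig_{method}"] = table[f"adj_{method}"].le(alpha).fillna(False)
    return table


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_compare(cfg: ComparisonConfig) -> pd.DataFrame:
    """Full file-to-file comparison: read, filter, test, adjust, plot, log.

    Writes ``results.tsv``, the requested plots and ``manifest.json`` (inputs
    with hashes, configuration, exclusion tallies and family sizes) under
    ``cfg.out_dir`` and returns the results DataFrame.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, exclusions = {}, {}
    for key, path, set_id in (("i", cfg.set_i, cfg.id_i), ("j", cfg.set_j, cfg.id_j)):
        recs = read_clonotype_table(path, set_id=set_id)
        kept, dropped = filter_clonotypes(recs, cfg.filter, cfg.functionality)
        records[key] = kept
        tally: dict[str, int] = {}
        for _rec, reason in dropped:
            tally[reason] = tally.get(reason, 0) + 1
        exclusions[set_id] = {"input": len(recs), "kept": len(kept), **tally}

    table = compare_sets(
        records["i"], records["j"], groups=cfg.groups, mode=cfg.mode,
        ci_level=cfg.ci_level, alpha=cfg.alpha, procedures=cfg.procedures,
        min_expected=cfg.min_expected, family=cfg.family,
        reference_order=cfg.reference_order, ci_critical=cfg.ci_critical)

    results_path = out / "results.tsv"
    table.to_csv(results_path, sep="\t", index=False, float_format="%.10g")

    family_sizes = (
        table[table["valid"]].groupby("group").size().to_dict()
        if cfg.family == "per-group"
        else {"combined": int(table["valid"].sum())})

    if cfg.make_plots:
        from . import plots
        plots.render_all(table, out_dir=out, alpha=cfg.alpha,
                         procedures=cfg.procedures, id_i=cfg.id_i,
                         id_j=cfg.id_j, fmt=cfg.plot_format)

    manifest = {
        "clonostat_version": __version__,
        "python": platform.python_version(),
        "inputs": {
            cfg.id_i: {"path": str(cfg.set_i), "sha256": _sha256(Path(cfg.set_i))},
            cfg.id_j: {"path": str(cfg.set_j), "sha256": _sha256(Path(cfg.set_j))},
        },
        "config": {
            "groups": list(cfg.groups), "mode": cfg.mode,
            "ci_level": cfg.ci_level, "alpha": cfg.alpha,
            "procedures": list(cfg.procedures),
            "min_expected": cfg.min_expected,
            "filter": asdict(cfg.filter), "family": cfg.family,
            "ci_critical": cfg.ci_critical,
        },
        "exclusions": exclusions,
        "family_sizes": family_sizes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def adjust_table(raw_p: Sequence[float] | Mapping[str, float],
                 m: int | None = None,
                 methods: Sequence[str] = METHODS,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Seven-column adjustment of a stand-alone p-value list.

    Accepts either a plain sequence or a gene -> p mapping; ``m`` may exceed
    the number supplied when only the smallest family p-values are known.
    Bonferroni, single-step Sidak and the step-down procedures are then
    exact; the step-up columns (Hochberg, BH, BY) assume all unsupplied
    values give larger step terms.  Rows come back sorted by raw p with
    ``sig_<method>`` flags at ``alpha``.
    """
    if isinstance(raw_p, Mapping):
        genes = list(raw_p)
        values = [float(raw_p[g]) for g in genes]
    else:
        values = [float(v) for v in raw_p]
        genes = [f"test_{i + 1}" for i in range(len(values))]
    table = pd.DataFrame({"gene": genes, "raw_p": values})
    for method in methods:
        table[f"adj_{method}"] = adjust_pvalues(values, m=m, method=method)
    table = table.sort_values("raw_p", kind="stable").reset_index(drop=True)
    for method in methods:
        table[f"sig_{method}"] = table[f"adj_{method}"] <= alpha
    return table


def run_simulate(spec: SimulationSpec,
                 procedures: Sequence[str] = METHODS,
                 alpha: float = 0.05, reps: int = 1000, seed: int = 0,
                 groups: Sequence[str] = ("V",),
                 out_dir: str | Path = "clonostat_sim") -> pd.DataFrame:
    """Run the error-rate harness and write its summary files.

    Writes ``summary.tsv`` (per procedure: FWER, FDR and Monte-Carlo SEs),
    ``rejections.tsv`` (per-replicate rejection counts) and ``run.json``
    (spec scale, seed, alpha) under ``out_dir``; returns the summary frame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = estimate_error_rates(spec, procedures=procedures, alpha=alpha,
                                  reps=reps, seed=seed, groups=groups)
    summary = pd.DataFrame({
        "procedure": list(procedures),
        "fwer": [result.fwer[m] for m in procedures],
        "fwer_mc_se": [result.fwer_se(m) for m in procedures],
        "fdr": [result.fdr[m] for m in procedures],
        "fdr_mc_se": [result.fdr_se(m) for m in procedures],
    })
    summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    pd.DataFrame(dict(result.rejection_counts)).to_csv(
        out / "rejections.tsv", sep="\t", index=False)
    (out / "run.json").write_text(json.dumps({
        "seed": seed, "reps": reps, "alpha": alpha, "groups": list(groups),
        "n_i": spec.n_i, "n_j": spec.n_j,
        "genes": {g: len(v) for g, v in spec.genes.items()},
        "sampling_model": spec.sampling_model,
    }, indent=2))
    return summary
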