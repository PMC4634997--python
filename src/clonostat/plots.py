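"""Standardized graphics for a two-set comparison.

Four plot families: juxtaposed normalised bar graphs of per-10,000 gene
usage, rejection-count-versus-alpha line graphs, volcano-style scatter plots
of -log10(p) against the z statistic, and a forest plot of differences in
proportions with CI bars coloured by significance class.  A synthesis figure
pairs the bars and the forest on a shared gene axis.

Significance classes are assigned by a pure function on the results table,
so the colour logic is testable without rendering; the plot functions only
draw and write files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .adjust import METHODS, rejections_vs_alpha

__all__ = [
    "PlotStyleConfig",
    "classify_significance",
    "plot_normalized_bars",
    "plot_rejections_vs_alpha",
    "plot_volcano",
    "plot_diff_forest",
    "plot_synthesis",
    "render_all",
]

#: Significance classes in precedence order (first match wins).
CLASSES = ("all_procedures", "two_or_more", "only_bh",
           "significant_raw", "nonsignificant_raw")


@dataclass(frozen=True)
class PlotStyleConfig:
    """Colours and reference level for the significance classes."""

    colors: Mapping[str, str] = field(default_factory=lambda: {
        "nonsignificant_raw": "red",
        "significant_raw": "lightblue",
        "all_procedures": "darkblue",
        "two_or_more": "pink",
        "only_bh": "green",
        "invalid": "lightgrey",
    })
    alpha: float = 0.05
    fmt: str = "png"

    def __post_init__(self) -> None:
        if len(set(self.colors[c] for c in CLASSES)) != len(CLASSES):
            raise ValueError("the five class colors must be distinct")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def classify_significance(table: pd.DataFrame, alpha: float = 0.05,
                          procedures: Sequence[str] = METHODS) -> pd.Series:
    """Assign each gene row exactly one significance class.

    Precedence: significant under all procedures > under two or more (but
    not all) > under BH alone > raw-significant only > non-significant.
    Rows flagged invalid get the class ``invalid``.  Pure function of the
    results table; rendering never changes the assignment.
    """
    sig_cols = [f"sig_{m}" for m in procedures if f"sig_{m}" in table.columns]
    n_sig = table[sig_cols].sum(axis=1) if sig_cols else pd.Series(0, index=table.index)
    total = len(sig_cols)
    bh_only = (n_sig == 1) & table.get(
        "sig_bh", pd.Series(False, index=table.index))
    raw_sig = table["raw_p"] <= alpha

    out = pd.Series("nonsignificant_raw", index=table.index)
    out[raw_sig] = "significant_raw"
    out[bh_only] = "only_bh"
    out[(n_sig >= 2) & (n_sig < total)] = "two_or_more"
    out[(n_sig == total) & (total > 0)] = "all_procedures"
    out[~table["valid"].astype(bool)] = "invalid"
    return out


def _finish(fig, out: str | Path):
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, bbox_inches="tight", dpi=110)
    plt.close(fig)
    return out


def _bars_on(ax, sub_i, sub_j, genes, id_i, id_j):
    y = np.arange(len(genes))
    height = 0.38
    ax.barh(y + height / 2, sub_i, height=height, color="tab:orange", label=id_i)
    ax.barh(y - height / 2, sub_j, height=height, color="tab:purple", label=id_j)
    ax.set_yticks(y, genes, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("clonotypes per 10,000")
    ax.legend(fontsize=7)


def plot_normalized_bars(norm_i, norm_j, out: str | Path,
                         id_i: str = "set_i", id_j: str = "set_j") -> Path:
    """Juxtaposed per-10,000 usage bars for the two sets of one group."""
    if norm_i.group != norm_j.group:
        raise ValueError("normalized tables must share a group")
    genes = sorted(set(norm_i.values) | set(norm_j.values))
    if not genes:
        raise ValueError("empty tables: nothing to plot")
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.18 * len(genes))))
    _bars_on(ax,
             [norm_i.values.get(g, 0.0) for g in genes],
             [norm_j.values.get(g, 0.0) for g in genes],
             genes, id_i, id_j)
    ax.set_title(f"{norm_i.group} usage, normalized to 10,000 per group")
    return _finish(fig, out)


_METHOD_COLORS = {
    "unadjusted": "black", "bonferroni": "purple", "sidak_ss": "orange",
    "holm": "brown", "sidak_sd": "olive", "hochberg": "teal",
    "bh": "red", "by": "magenta",
}


def plot_rejections_vs_alpha(curves: Mapping[str, np.ndarray],
                             alpha_grid: Sequence[float], out: str | Path,
                             alpha_ref: float = 0.05) -> Path:
    """Rejection-count step curves per procedure, dotted raw-p reference."""
    if not curves:
        raise ValueError("no curves to plot")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, curve in curves.items():
        style = dict(color=_METHOD_COLORS.get(name, None))
        if name == "unadjusted":
            style.update(linestyle=":", linewidth=2)
        ax.step(alpha_grid, curve, where="post", label=name, **style)
    ax.axvline(alpha_ref, color="grey", linewidth=1)
    ax.set_xlabel("type I error rate (alpha)")
    ax.set_ylabel("rejected null hypotheses")
    ax.legend(fontsize=7)
    return _finish(fig, out)


def plot_volcano(table: pd.DataFrame, out: str | Path, alpha: float = 0.05,
                 procedures: Sequence[str] = METHODS) -> Path:
    """-log10(p) against z; raw p black, adjusted per procedure coloured.

    Significance region above -log10(alpha) and outside +/-1.96 on z.
    """
    valid = table[table["valid"].astype(bool)]
    if valid.empty:
        raise ValueError("no valid tests to plot")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    with np.errstate(divide="ignore"):
        ax.scatter(valid["z"], -np.log10(valid["raw_p"]), s=14,
                   color="black", label="unadjusted")
        for m in procedures:
            col = f"adj_{m}"
            if col in valid:
                ax.scatter(valid["z"], -np.log10(valid[col]), s=8,
                           color=_METHOD_COLORS.get(m), label=m)
    ax.axhline(-np.log10(alpha), color="grey", linewidth=1)
    for v in (-1.959964, 1.959964):
        ax.axvline(v, color="grey", linewidth=1)
    ax.set_xlabel("z score")
    ax.set_ylabel("-log10(p)")
    ax.legend(fontsize=7)
    return _finish(fig, out)


def _forest_on(ax, table, classes, style):
    y = np.arange(len(table))
    for k, (idx, row) in enumerate(table.iterrows()):
        color = style.colors.get(classes.loc[idx], "black")
        ax.plot([row["ci_low"], row["ci_high"]], [y[k], y[k]],
                color=color, linewidth=1.6)
        ax.plot([row["diff"]], [y[k]], marker="o", markersize=3, color=color)
    ax.axvline(0.0, color="black", linewidth=1)
    ax.set_yticks(y, table["gene"], fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("difference in proportions")


def plot_diff_forest(table: pd.DataFrame, out: str | Path,
                     style: PlotStyleConfig | None = None,
                     procedures: Sequence[str] = METHODS,
                     sort_by_diff: bool = False) -> Path:
    """Forest plot: one CI bar per gene, coloured by significance class.

    Invalid genes are drawn greyed-out rather than omitted so their
    presence is auditable.  Default ordering follows the table (gene
    reference order); ``sort_by_diff`` orders by effect size instead.
    """
    style = style or PlotStyleConfig()
    if table.empty:
        raise ValueError("empty results table")
    plot_table = table.sort_values("diff") if sort_by_diff else table
    classes = classify_significance(plot_table, alpha=style.alpha,
                                    procedures=procedures)
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.18 * len(plot_table))))
    _forest_on(ax, plot_table, classes, style)
    return _finish(fig, out)


def plot_synthesis(table: pd.DataFrame, norm_i, norm_j, out: str | Path,
                   style: PlotStyleConfig | None = None,
                   procedures: Sequence[str] = METHODS,
                   id_i: str = "set_i", id_j: str = "set_j") -> Path:
    """Two aligned panels: normalised bars (left) and forest (right).

    Both panels share the gene row order of the results table.
    """
    style = style or PlotStyleConfig()
    genes = list(table["gene"])
    if not genes:
        raise ValueError("empty results table")
    classes = classify_significance(table, alpha=style.alpha,
                                    procedures=procedures)
    fig, (ax_l, ax_r) = plt.subplots(
        1, 2, figsize=(10, max(2.0, 0.18 * len(genes))), sharey=False)
    _bars_on(ax_l,
             [norm_i.values.get(g, 0.0) for g in genes],
             [norm_j.values.get(g, 0.0) for g in genes],
             genes, id_i, id_j)
    _forest_on(ax_r, table, classes, style)
    ax_r.set_yticks([])
    fig.tight_layout()
    return _finish(fig, out)


def render_all(table: pd.DataFrame, out_dir: str | Path, alpha: float,
               procedures: Sequence[str], id_i: str, id_j: str,
               fmt: str = "png") -> list[Path]:
    """Write the full plot set for every group in a results table."""
    from .counts import NormalizedTable

    out_dir = Path(out_dir)
    style = PlotStyleConfig(alpha=alpha, fmt=fmt)
    written: list[Path] = []
    stem = f"{id_i}_vs_{id_j}"
    valid = table[table["valid"].astype(bool)]
    if not valid.empty:
        grid = np.linspace(0.0, 1.0, 201)
        curves = rejections_vs_alpha(valid["raw_p"].to_numpy(), None,
                                     methods=procedures, alpha_grid=grid)
        written.append(plot_rejections_vs_alpha(
            curves, grid, out_dir / f"{stem}_rejections.{fmt}", alpha_ref=alpha))
        written.append(plot_volcano(
            table, out_dir / f"{stem}_volcano.{fmt}", alpha=alpha,
            procedures=procedures))
    for grp, sub in table.groupby("group", sort=False):
        norm_i = NormalizedTable(id_i, grp, "display", dict(
            zip(sub["gene"], sub["per10000_i"])))
        norm_j = NormalizedTable(id_j, grp, "display", dict(
            zip(sub["gene"], sub["per10000_j"])))
        written.append(plot_normalized_bars(
            norm_i, norm_j, out_dir / f"{stem}_{grp}_bars.{fmt}",
            id_i=id_i, id_j=id_j))
        written.append(plot_diff_forest(
            sub, out_dir / f"{stem}_{grp}_forest.{fmt}", style=style,
            procedures=procedures))
        written.append(plot_synthesis(
            sub, norm_i, norm_j, out_dir / f"{stem}_{grp}_synthesis.{fmt}",
            style=style, procedures=procedures, id_i=id_i, id_j=id_j))
    return written
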