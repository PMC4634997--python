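"""Seven multiple-testing adjustments, implemented from first principles.

When m hypotheses are tested at level alpha the chance of at least one false
rejection grows to roughly ``1 - (1 - alpha)^m``.  The procedures here
control either the family-wise error rate (FWER) - Bonferroni, single-step
Sidak, Holm, step-down Sidak, Hochberg - or the false discovery rate (FDR) -
Benjamini-Hochberg (BH) and Benjamini-Yekutieli (BY).  Each is expressed in
its adjusted-p-value form: the adjusted p of a hypothesis is the smallest
level at which the sequential procedure would reject it, so "adjusted p <=
alpha" reproduces the step-down / step-up rejection rule exactly.

With sorted p-values ``p_(1) <= ... <= p_(r)`` at ranks ``i = 1..r``:

====================  =========================================================
bonferroni            min(1, m p)
sidak_ss              1 - (1 - p)^m
holm                  cummax_i  min(1, (m - i + 1) p_(i))
sidak_sd              cummax_i  1 - (1 - p_(i))^(m - i + 1)
hochberg              cummin_(i desc)  min(1, (m - i + 1) p_(i))
bh                    cummin_(i desc)  min(1, (m / i) p_(i))
by                    cummin_(i desc)  min(1, c(m) (m / i) p_(i)),  c(m) = H_m
====================  =========================================================

``m`` may exceed the number of supplied p-values, for re-adjusting published
tables that print only the smallest values of a family.  Bonferroni, Sidak
and the step-down procedures are then still exact; the step-up procedures
assume every unsupplied p-value yields a larger step term (true whenever the
supplied values are the smallest of the family and, for rejection counts at
alpha, whenever all unsupplied raw p exceed alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stats import ZTestResult

__all__ = [
    "METHODS",
    "FWER_METHODS",
    "FDR_METHODS",
    "AdjustmentResult",
    "adjust_pvalues",
    "adjust_family",
    "build_family",
    "rejection_count",
    "rejections_vs_alpha",
    "harmonic_number",
]

#: The seven procedures, from most conservative single-step to FDR step-up.
METHODS = ("bonferroni", "sidak_ss", "holm", "sidak_sd", "hochberg", "bh", "by")
FWER_METHODS = ("bonferroni", "sidak_ss", "holm", "sidak_sd", "hochberg")
FDR_METHODS = ("bh", "by")


def harmonic_number(m: int) -> float:
    """H_m = sum_{u=1..m} 1/u, the BY dependence penalty (direct summation)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def _sidak_term(p: np.ndarray, exponent: np.ndarray | int) -> np.ndarray:
    # 1 - (1 - p)^k via expm1/log1p so tiny p do not underflow to 0.
    with np.errstate(divide="ignore"):  # log1p(-1) = -inf gives the right limit 1
        return -np.expm1(exponent * np.log1p(-p))


def adjust_pvalues(raw: Sequence[float], m: int | None = None,
                   method: str = "bh") -> np.ndarray:
    """Adjusted p-values for one procedure, aligned to the input order.

    Parameters
    ----------
    raw:
        Unadjusted p-values in [0, 1].
    m:
        Family size; defaults to ``len(raw)`` and must not be smaller.
    method:
        One of :data:`METHODS`.
    """
    p = np.asarray(raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("raw p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    r = p.size
    if m is None:
        m = r
    if m < r:
        raise ValueError(f"family size m={m} smaller than {r} supplied p-values")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")

    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, r + 1)

    if method == "bonferroni":
        adj = np.minimum(1.0, m * ps)
    elif method == "sidak_ss":
        adj = _sidak_term(ps, m)
    elif method == "holm":
        adj = np.maximum.accumulate(np.minimum(1.0, (m - i + 1) * ps))
    elif method == "sidak_sd":
        adj = np.maximum.accumulate(_sidak_term(ps, m - i + 1))
    elif method == "hochberg":
        steps = np.minimum(1.0, (m - i + 1) * ps)
        adj = np.minimum.accumulate(steps[::-1])[::-1]
    elif method == "bh":
        steps = np.minimum(1.0, (m / i) * ps)
        adj = np.minimum.accumulate(steps[::-1])[::-1]
    else:  # by
        c = harmonic_number(m)
        steps = np.minimum(1.0, c * (m / i) * ps)
        adj = np.minimum.accumulate(steps[::-1])[::-1]

    out = np.empty_like(adj)
    out[order] = adj
    return out


@dataclass(frozen=True)
class AdjustmentResult:
    """Raw and adjusted p-values of one comparison family."""

    family_id: str
    m: int
    alpha: float
    raw_p: Mapping[str, float]
    adjusted: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    rejected: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)


def adjust_family(raw_p: Mapping[str, float], m: int | None = None,
                  methods: Sequence[str] = METHODS, alpha: float = 0.05,
                  family_id: str = "") -> AdjustmentResult:
    """Run several procedures over one gene -> raw-p family."""
    genes = list(raw_p)
    values = [raw_p[g] for g in genes]
    adjusted: dict[str, dict[str, float]] = {}
    rejected: dict[str, dict[str, bool]] = {}
    for method in methods:
        adj = adjust_pvalues(values, m=m, method=method)
        adjusted[method] = dict(zip(genes, adj.tolist()))
        rejected[method] = dict(zip(genes, (adj <= alpha).tolist()))
    return AdjustmentResult(family_id=family_id, m=m if m is not None else len(genes),
                            alpha=alpha, raw_p=dict(raw_p),
                            adjusted=adjusted, rejected=rejected)


def build_family(test_results: Iterable[ZTestResult]) -> tuple[dict[str, float], int]:
    """Collect valid tests of one set-pair comparison into a family.

    Genes whose z-test failed the expected-count rule (or were absent from
    both sets) contribute neither a p-value nor to the family size m.
    """
    raw_p: dict[str, float] = {}
    for res in test_results:
        if res.valid:
            raw_p[res.gene] = res.raw_p
    if not raw_p:
        raise ValueError("no valid tests: the comparison family is empty")
    return raw_p, len(raw_p)


def rejection_count(raw: Sequence[float], m: int | None, method: str,
                    alpha: float) -> int:
    """Number of hypotheses rejected at level alpha (adjusted p <= alpha)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    adj = adjust_pvalues(raw, m=m, method=method)
    return int(np.sum(adj <= alpha))


def rejections_vs_alpha(
    raw: Sequence[float], m: int | None,
    methods: Sequence[str] = METHODS,
    alpha_grid: Sequence[float] | None = None,
) -> dict[str, np.ndarray]:
    """Step functions: rejections against the type-I error level.

    Includes an ``unadjusted`` curve (raw p <= alpha) alongside the
    requested procedures; every curve is a nondecreasing integer function
    of alpha.
    """
    grid = np.linspace(0.0, 1.0, 101) if alpha_grid is None else np.asarray(
        alpha_grid, dtype=float)
    if np.any(np.diff(grid) < 0) or np.any((grid < 0) | (grid > 1)):
        raise ValueError("alpha_grid must be increasing within [0, 1]")
    p = np.asarray(raw, dtype=float)
    curves: dict[str, np.ndarray] = {
        "unadjusted": np.sum(p[:, None] <= grid[None, :], axis=0).astype(int)
    }
    for method in methods:
        adj = adjust_pvalues(p, m=m, method=method)
        curves[method] = np.sum(adj[:, None] <= grid[None, :], axis=0).astype(int)
    return curves
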