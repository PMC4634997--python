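"""Per-gene two-proportion estimates, Wald confidence intervals and the
pooled two-proportion z-test with its expected-count validity rule.

For gene *k* with counts ``c_i`` of ``n_i`` and ``c_j`` of ``n_j``, the
proportion estimates are ``p_i = c_i/n_i`` and ``p_j = c_j/n_j``.  The
difference ``p_i - p_j`` gets an approximate Wald interval

    (p_i - p_j) +/- q * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j)

with q the standard-normal quantile at 1 - alpha/2.  Significance is
assessed with the pooled z statistic

    z = (p_i - p_j) / sqrt(p(1-p)(1/n_i + 1/n_j)),   p = (c_i + c_j)/(n_i + n_j)

whose two-tailed p-value is 2 P(Z >= |z|).  The normal tail is computed with
the complementary CDF, which stays accurate far beyond |z| = 5.

The z-test is a large-sample approximation: it is flagged invalid whenever
any of the four expected counts c_i, n_i - c_i, c_j, n_j - c_j falls below a
threshold (default 5), including the degenerate case of a gene absent from
one set.  Invalid genes are carried in outputs but excluded downstream from
p-value adjustment and from the family size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .counts import GeneCountTable

__all__ = [
    "ProportionComparison",
    "ZTestResult",
    "compare_proportions",
    "pooled_z_test",
    "check_validity",
    "two_proportion_arrays",
]


@dataclass(frozen=True)
class ProportionComparison:
    """Point estimates, difference and Wald CI for one gene."""

    gene: str
    group: str
    count_i: int
    count_j: int
    n_i: int
    n_j: int
    p_hat_i: float
    p_hat_j: float
    diff: float
    sd_unpooled: float
    ci_level: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ZTestResult:
    """Pooled z statistic and two-tailed p-value for one gene."""

    gene: str
    pooled_p: float
    pooled_sd: float
    z: float
    raw_p: float
    valid: bool
    invalid_reason: str  # "none", "zero_both" or "expected_count"


def check_validity(count_i: int, n_i: int, count_j: int, n_j: int,
                   threshold: float = 5.0) -> tuple[bool, str]:
    """Apply the expected-count rule for the pooled z approximation.

    Valid only when all four expected counts ``n*p`` and ``n*(1-p)`` in both
    sets reach the threshold; a gene with zero count in both sets is tagged
    ``zero_both``, any other failure ``expected_count``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if n_i <= 0 or n_j <= 0:
        raise ValueError("set totals must be positive")
    if count_i == 0 and count_j == 0:
        return False, "zero_both"
    expected = (count_i, n_i - count_i, count_j, n_j - count_j)
    if min(expected) < threshold:
        return False, "expected_count"
    return True, "none"


def compare_proportions(table_i: GeneCountTable, table_j: GeneCountTable,
                        gene: str, ci_level: float = 0.95,
                        z_crit: float | None = None) -> ProportionComparison:
    """Difference in per-gene proportions between two sets, with a Wald CI.

    ``z_crit`` overrides the critical value; by default the exact standard
    normal quantile at ``1 - alpha/2`` is used.  Published reports often use
    the conventional two-decimal value (1.96 at the 95% level), which can
    shift a bound by one unit in the sixth decimal place.
    """
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must lie in (0, 1)")
    n_i, n_j = table_i.n_total, table_j.n_total
    if n_i == 0 or n_j == 0:
        raise ValueError("empty set: both groups need a positive total")
    c_i, c_j = table_i.count(gene), table_j.count(gene)
    p_i, p_j = c_i / n_i, c_j / n_j
    diff = p_i - p_j
    sd = math.sqrt(p_i * (1 - p_i) / n_i + p_j * (1 - p_j) / n_j)
    q = float(norm.ppf(0.5 + ci_level / 2)) if z_crit is None else z_crit
    half = q * sd
    return ProportionComparison(
        gene=gene, group=table_i.group, count_i=c_i, count_j=c_j,
        n_i=n_i, n_j=n_j, p_hat_i=p_i, p_hat_j=p_j, diff=diff,
        sd_unpooled=sd, ci_level=ci_level,
        ci_low=diff - half, ci_high=diff + half,
    )


def pooled_z_test(table_i: GeneCountTable, table_j: GeneCountTable,
                  gene: str, min_expected: float = 5.0) -> ZTestResult:
    """Pooled two-proportion z-test for one gene of a group.

    The pooled proportion weights the two estimates by their sample sizes;
    under the null of equal proportions z is approximately standard normal.
    When the pooled proportion is degenerate (0 or 1) the statistic is
    defined as 0 and the result flagged invalid.
    """
    n_i, n_j = table_i.n_total, table_j.n_total
    if n_i == 0 or n_j == 0:
        raise ValueError("empty set: both groups need a positive total")
    c_i, c_j = table_i.count(gene), table_j.count(gene)
    pooled_p = (c_i + c_j) / (n_i + n_j)
    valid, reason = check_validity(c_i, n_i, c_j, n_j, threshold=min_expected)
    if pooled_p in (0.0, 1.0):
        return ZTestResult(gene=gene, pooled_p=pooled_p, pooled_sd=0.0,
                           z=0.0, raw_p=1.0, valid=False,
                           invalid_reason=reason if reason != "none" else "expected_count")
    pooled_sd = math.sqrt(pooled_p * (1 - pooled_p) * (1 / n_i + 1 / n_j))
    z = (c_i / n_i - c_j / n_j) / pooled_sd
    raw_p = float(2.0 * norm.sf(abs(z)))
    return ZTestResult(gene=gene, pooled_p=pooled_p, pooled_sd=pooled_sd,
                       z=z, raw_p=raw_p, valid=valid, invalid_reason=reason)


def two_proportion_arrays(
    counts_i: np.ndarray, n_i: int, counts_j: np.ndarray, n_j: int,
    ci_level: float = 0.95, min_expected: float = 5.0,
    z_crit: float | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised form of the per-gene comparison over an inventory.

    Returns aligned arrays: p_i, p_j, diff, sd, ci_low, ci_high, pooled_p,
    pooled_sd, z, raw_p, valid, invalid_reason.  Semantics match the scalar
    functions; used by the pipeline and the simulation harness.
    """
    ci_arr = np.asarray(counts_i, dtype=float)
    cj_arr = np.asarray(counts_j, dtype=float)
    if n_i <= 0 or n_j <= 0:
        raise ValueError("empty set: both groups need a positive total")
    p_i, p_j = ci_arr / n_i, cj_arr / n_j
    diff = p_i - p_j
    sd = np.sqrt(p_i * (1 - p_i) / n_i + p_j * (1 - p_j) / n_j)
    q = float(norm.ppf(0.5 + ci_level / 2)) if z_crit is None else z_crit
    pooled_p = (ci_arr + cj_arr) / (n_i + n_j)
    var = pooled_p * (1 - pooled_p) * (1 / n_i + 1 / n_j)
    degenerate = var <= 0
    pooled_sd = np.sqrt(np.where(degenerate, 1.0, var))
    z = np.where(degenerate, 0.0, diff / pooled_sd)
    pooled_sd = np.where(degenerate, 0.0, pooled_sd)
    raw_p = 2.0 * norm.sf(np.abs(z))
    expected_min = np.minimum.reduce(
        [ci_arr, n_i - ci_arr, cj_arr, n_j - cj_arr])
    zero_both = (ci_arr == 0) & (cj_arr == 0)
    valid = (expected_min >= min_expected) & ~zero_both & ~degenerate
    reason = np.where(valid, "none",
                      np.where(zero_both, "zero_both", "expected_count"))
    return {
        "p_i": p_i, "p_j": p_j, "diff": diff, "sd": sd,
        "ci_low": diff - q * sd, "ci_high": diff + q * sd,
        "pooled_p": pooled_p, "pooled_sd": pooled_sd, "z": z,
        "raw_p": raw_p, "valid": valid, "invalid_reason": reason,
    }
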