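"""Multiple-testing procedures: published values, oracles and invariants.

Two independent checks back the implementation: statsmodels' adjustments
for complete families, and a brute-force oracle that applies each
procedure's textbook sequential rejection rule over a fine alpha grid and
inverts it into adjusted p-values.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clonostat import (METHODS, adjust_pvalues, build_family, harmonic_number,
                       rejection_count, rejections_vs_alpha)
from clonostat.datasets import COMPARISONS, FAMILY_SIZES, derive_family_size
from clonostat.stats import ZTestResult

# ---------------------------------------------------------------------------
# brute-force sequential oracle


def _sequential_rejections(ps: np.ndarray, m: int, method: str,
                           alpha: float) -> np.ndarray:
    """Textbook rejection set: step-down stops at the first acceptance,
    step-up rejects everything below the last passing rank."""
    order = np.argsort(ps, kind="stable")
    sorted_p = ps[order]
    r = ps.size
    i = np.arange(1, r + 1)
    if method == "bonferroni":
        reject_sorted = sorted_p <= alpha / m
    elif method == "sidak_ss":
        reject_sorted = sorted_p <= 1 - (1 - alpha) ** (1.0 / m)
    elif method in {"holm", "sidak_sd"}:
        if method == "holm":
            crit = alpha / (m - i + 1)
        else:
            crit = 1 - (1 - alpha) ** (1.0 / (m - i + 1))
        passing = sorted_p <= crit
        reject_sorted = np.zeros(r, dtype=bool)
        for k in range(r):          # stop at first acceptance
            if not passing[k]:
                break
            reject_sorted[k] = True
    else:
        if method == "hochberg":
            crit = alpha / (m - i + 1)
        elif method == "bh":
            crit = i * alpha / m
        else:  # by
            crit = i * alpha / (m * harmonic_number(m))
        passing = np.nonzero(sorted_p <= crit)[0]
        reject_sorted = np.zeros(r, dtype=bool)
        if passing.size:            # reject all at or below the largest pass
            reject_sorted[: passing[-1] + 1] = True
    out = np.zeros(r, dtype=bool)
    out[order] = reject_sorted
    return out


def _grid_inverted_adjusted(ps: np.ndarray, m: int, method: str,
                            grid: np.ndarray) -> np.ndarray:
    """Smallest grid alpha at which each hypothesis is rejected (1 if never)."""
    adjusted = np.ones(ps.size)
    decided = np.zeros(ps.size, dtype=bool)
    for alpha in grid:
        rej = _sequential_rejections(ps, m, method, alpha)
        newly = rej & ~decided
        adjusted[newly] = alpha
        decided |= newly
        if decided.all():
            break
    return adjusted


# ---------------------------------------------------------------------------
# published-table reproduction


def _half_ulp(printed: str) -> float:
    """Relative half-ulp of a printed decimal string, e.g. '1.3E-08' -> 0.05/1.3."""
    mantissa = printed.upper().split("E")[0].replace("-", "").replace(".", "")
    digits = len(mantissa.lstrip("0"))
    lead = float(printed.upper().split("E")[0].lstrip("-"))
    return 0.5 * 10.0 ** (1 - digits) / lead


# (comparison, rank0, method, printed raw, printed adjusted): top-ranked rows
# whose printed raw precision suffices to reconstruct the adjusted value.
PUBLISHED_ROWS = [
    ("Pre", 0, "bonferroni", "1.3E-08", "7.93E-07"),
    ("Pre", 0, "holm", "1.3E-08", "7.93E-07"),
    ("Pre", 0, "by", "1.3E-08", "3.72E-06"),
    ("Pre", 1, "bonferroni", "4.81E-07", "2.93E-05"),
    ("Pre", 1, "holm", "4.81E-07", "2.89E-05"),
    ("Pre", 1, "by", "4.81E-07", "6.89E-05"),
    ("Pre", 2, "bonferroni", "1.2E-05", "0.00073"),
    ("Pre", 2, "holm", "1.2E-05", "0.00071"),
    ("Pre", 2, "by", "1.2E-05", "0.00114"),
    ("d3", 1, "bonferroni", "8.72E-13", "5.14E-11"),
    ("d3", 1, "holm", "8.72E-13", "5.06E-11"),
    ("d3", 1, "by", "8.72E-13", "9.49E-11"),
    ("d3", 2, "bonferroni", "1.03E-12", "6.10E-11"),
    ("d3", 2, "holm", "1.03E-12", "5.90E-11"),
    ("d8", 0, "bonferroni", "1.36E-13", "8.04E-12"),
    ("d8", 0, "holm", "1.36E-13", "8.04E-12"),
    ("d8", 0, "by", "1.36E-13", "3.75E-11"),
    ("d26", 0, "bonferroni", "2.14E-26", "1.31E-24"),
    ("d26", 0, "holm", "2.14E-26", "1.31E-24"),
    ("d26", 0, "by", "2.14E-26", "6.14E-24"),
    ("d26", 1, "bonferroni", "4.54E-17", "2.77E-15"),
    ("d26", 1, "holm", "4.54E-17", "2.72E-15"),
]


class TestPublishedTable:
    @pytest.mark.parametrize("comparison,rank,method,raw_str,adj_str",
                             PUBLISHED_ROWS)
    def test_adjusted_values_at_printed_precision(self, comparison, rank,
                                                  method, raw_str, adj_str):
        raw = [p for _, p in COMPARISONS[comparison]]
        assert raw[rank] == float(raw_str)
        adj = adjust_pvalues(raw, m=FAMILY_SIZES[comparison], method=method)
        tol = _half_ulp(raw_str) + _half_ulp(adj_str)
        assert adj[rank] == pytest.approx(float(adj_str), rel=tol)

    @pytest.mark.parametrize("comparison,bh_count,bonf_count", [
        ("Pre", 10, 6), ("d3", 16, 10), ("d8", 13, 8), ("d26", 21, 15),
    ])
    def test_rejection_counts_match_report(self, comparison, bh_count,
                                           bonf_count):
        raw = [p for _, p in COMPARISONS[comparison]]
        m = FAMILY_SIZES[comparison]
        assert rejection_count(raw, m, "bh", 0.05) == bh_count
        assert rejection_count(raw, m, "bonferroni", 0.05) == bonf_count

    @pytest.mark.parametrize("comparison,count", [
        ("Pre", 17), ("d3", 24), ("d8", 19), ("d26", 27),
    ])
    def test_all_printed_raw_values_significant_unadjusted(self, comparison,
                                                           count):
        raw = [p for _, p in COMPARISONS[comparison]]
        assert len(raw) == count and all(p < 0.05 for p in raw)

    def test_family_size_derivation(self):
        assert derive_family_size(1.3e-08, 7.93e-07) == 61
        assert derive_family_size(8.72e-13, 5.14e-11) == 59


class TestAdjustBasics:
    def test_single_test_identity(self):
        for method in METHODS:
            assert adjust_pvalues([0.031], m=1, method=method)[0] \
                == pytest.approx(0.031)

    def test_by_equals_bh_times_harmonic_penalty_at_top_rank(self):
        raw = [1e-6, 0.2, 0.4]
        bh = adjust_pvalues(raw, method="bh")
        by = adjust_pvalues(raw, method="by")
        assert by[0] == pytest.approx(bh[0] * harmonic_number(3))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], method="bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 0.2, 0.3], m=2, method="bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], method="fdr_storey")

    def test_statsmodels_cross_check(self, rng):
        from statsmodels.stats.multitest import multipletests

        pairing = {"bonferroni": "bonferroni", "sidak_ss": "sidak",
                   "holm": "holm", "sidak_sd": "holm-sidak",
                   "hochberg": "simes-hochberg", "bh": "fdr_bh",
                   "by": "fdr_by"}
        for _ in range(20):
            raw = rng.random(rng.integers(2, 40))
            for ours, theirs in pairing.items():
                mine = adjust_pvalues(raw, method=ours)
                ref = multipletests(raw, method=theirs)[1]
                np.testing.assert_allclose(mine, ref, rtol=1e-10,
                                           err_msg=ours)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
           st.permutations(range(8)))
    def test_permutation_invariance_and_bounds(self, raw, perm):
        raw = raw[:8] if len(raw) > 8 else raw
        perm = [p for p in perm if p < len(raw)]
        for method in METHODS:
            adj = adjust_pvalues(raw, method=method)
            assert np.all(adj >= np.asarray(raw) - 1e-12)
            assert np.all(adj <= 1.0 + 1e-12)
            shuffled = [raw[k] for k in perm]
            adj_shuffled = adjust_pvalues(shuffled, method=method)
            np.testing.assert_allclose(adj_shuffled, adj[perm], atol=1e-12)

    def test_monotone_in_rank(self, rng):
        raw = rng.random(50)
        order = np.argsort(raw)
        for method in METHODS:
            adj = adjust_pvalues(raw, method=method)
            assert np.all(np.diff(adj[order]) >= -1e-12), method

    def test_ties_share_adjusted_values(self):
        raw = [0.01, 0.04, 0.04, 0.9]
        for method in METHODS:
            adj = adjust_pvalues(raw, method=method)
            assert adj[1] == pytest.approx(adj[2]), method


class TestOracleEquivalence:
    def test_rejection_sets_match_sequential_definitions(self, rng):
        """Exhaustive check on random families <= 12 at random alpha levels."""
        for _ in range(60):
            r = int(rng.integers(1, 13))
            ps = np.round(rng.random(r), 4)
            m = r + int(rng.integers(0, 4))
            alpha = float(rng.choice([0.01, 0.05, 0.1, 0.2, 0.5]))
            for method in METHODS:
                adj = adjust_pvalues(ps, m=m, method=method)
                np.testing.assert_array_equal(
                    adj <= alpha, _sequential_rejections(ps, m, method, alpha),
                    err_msg=f"{method} r={r} m={m} alpha={alpha}")

    def test_grid_inversion_recovers_adjusted_pvalues(self, rng):
        grid = np.linspace(0.0, 1.0, 2001)  # resolution 5e-4
        for _ in range(8):
            r = int(rng.integers(2, 11))
            ps = rng.random(r)
            for method in METHODS:
                adj = adjust_pvalues(ps, method=method)
                oracle = _grid_inverted_adjusted(ps, r, method, grid)
                assert np.all(np.abs(adj - oracle) <= 5.01e-4), method


class TestDominance:
    def test_dominance_chain(self, rng):
        for _ in range(50):
            raw = rng.random(int(rng.integers(1, 25)))
            adj = {m: adjust_pvalues(raw, method=m) for m in METHODS}
            eps = 1e-12
            assert np.all(adj["bonferroni"] >= adj["holm"] - eps)
            assert np.all(adj["holm"] >= adj["hochberg"] - eps)
            assert np.all(adj["hochberg"] >= adj["bh"] - eps)
            assert np.all(adj["sidak_ss"] <= adj["bonferroni"] + eps)
            assert np.all(adj["sidak_sd"] <= adj["holm"] + eps)
            assert np.all(adj["bh"] <= adj["by"] + eps)

    def test_rejection_sets_nest(self, rng):
        """Bonferroni ⊆ Holm ⊆ Hochberg ⊆ BH and BY ⊆ BH, at alpha=0.05."""
        for _ in range(200):
            raw = rng.random(int(rng.integers(1, 30))) ** 3  # push some small
            rej = {m: adjust_pvalues(raw, method=m) <= 0.05 for m in METHODS}
            assert not np.any(rej["bonferroni"] & ~rej["holm"])
            assert not np.any(rej["holm"] & ~rej["hochberg"])
            assert not np.any(rej["hochberg"] & ~rej["bh"])
            assert not np.any(rej["by"] & ~rej["bh"])
            assert not np.any(rej["bonferroni"] & ~rej["sidak_ss"])


class TestFamilyAndCurves:
    def _zt(self, gene, p, valid=True):
        return ZTestResult(gene=gene, pooled_p=0.1, pooled_sd=0.01,
                           z=1.0, raw_p=p, valid=valid,
                           invalid_reason="none" if valid else "expected_count")

    def test_build_family_excludes_invalid(self):
        results = [self._zt("A", 0.01), self._zt("B", 0.5),
                   self._zt("C", 0.2, valid=False)]
        raw, m = build_family(results)
        assert raw == {"A": 0.01, "B": 0.5} and m == 2

    def test_empty_family_is_an_error(self):
        with pytest.raises(ValueError, match="no valid tests"):
            build_family([self._zt("A", 0.1, valid=False)])

    def test_rejection_count_boundaries(self):
        raw = [p for _, p in COMPARISONS["Pre"]]
        assert rejection_count(raw, 61, "bh", 0.0) == 0
        assert rejection_count(raw, 61, "bonferroni", 1.0) == len(raw)

    def test_curves_monotone_and_anchor_rejection_count(self):
        raw = [p for _, p in COMPARISONS["Pre"]]
        grid = np.linspace(0, 1, 101)
        curves = rejections_vs_alpha(raw, 61, alpha_grid=grid)
        k_005 = int(np.argmin(np.abs(grid - 0.05)))
        assert curves["unadjusted"][k_005] == 17
        for method in METHODS:
            curve = curves[method]
            assert np.all(np.diff(curve) >= 0)
            assert curve[k_005] == rejection_count(raw, 61, method, 0.05)
            assert np.all(curves["unadjusted"] >= curve)
        assert curves["bonferroni"][-1] == len(raw)
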