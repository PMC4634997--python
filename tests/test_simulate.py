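"""Synthetic repertoire generator: determinism, moments, error rates."""

from __future__ import annotations

import numpy as np
import pytest

from clonostat import (SimulationSpec, coverage_study, estimate_error_rates,
                       generate_pair, paper_like_spec, shift_usage)
from clonostat.simulate import mc_standard_error


def small_spec(**overrides) -> SimulationSpec:
    """A light spec for unit tests: 8 V and 3 J genes, 300 clonotypes."""
    defaults = dict(
        genes={"V": [f"V{k}" for k in range(8)], "J": ["J0", "J1", "J2"]},
        usage_i={"V": np.full(8, 1 / 8), "J": np.array([0.5, 0.3, 0.2])},
        usage_j={"V": np.full(8, 1 / 8), "J": np.array([0.5, 0.3, 0.2])},
        n_i=300, n_j=300, seed=42,
    )
    defaults.update(overrides)
    return SimulationSpec(**defaults)


class TestGeneratePair:
    def test_same_seed_gives_identical_tables(self):
        spec = small_spec()
        assert generate_pair(spec) == generate_pair(spec)

    def test_requested_sizes_and_structure(self):
        rec_i, rec_j = generate_pair(small_spec(n_i=120, n_j=80))
        assert len(rec_i) == 120 and len(rec_j) == 80
        assert {r.set_id for r in rec_i} == {"sim_i"}
        assert all(r.v_gene.startswith("V") and r.j_gene.startswith("J")
                   for r in rec_i)

    def test_out_of_frame_fraction(self):
        all_in = generate_pair(small_spec(out_of_frame_fraction=0.0))[0]
        assert all(r.in_frame for r in all_in)
        half_out = generate_pair(small_spec(out_of_frame_fraction=0.5,
                                            n_i=2000))[0]
        frac = np.mean([not r.in_frame for r in half_out])
        assert frac == pytest.approx(0.5, abs=3 * mc_standard_error(0.5, 2000))

    def test_cdr3_outlier_masses(self):
        spec = small_spec(cdr3_short_outlier_mass=0.2,
                          cdr3_long_outlier_mass=0.1, n_i=3000)
        recs = generate_pair(spec)[0]
        lengths = np.array([len(r.cdr3_aa) for r in recs])
        assert np.mean(lengths < 4) == pytest.approx(0.2, abs=0.03)
        assert np.mean(lengths > 60) == pytest.approx(0.1, abs=0.02)
        assert lengths.min() >= 2 and lengths.max() <= 70

    def test_multinomial_marginals_are_binomial(self):
        """Empirical per-gene means across replicates match n * usage."""
        spec = small_spec(n_i=200, n_j=1)
        reps = 300
        counts = np.zeros(8)
        root = np.random.SeedSequence(5)
        for child in root.spawn(reps):
            rec_i, _ = generate_pair(spec, rng=np.random.default_rng(child))
            for r in rec_i:
                counts[int(r.v_gene[1:])] += 1
        mean = counts / reps
        expect = 200 / 8
        se = np.sqrt(200 * (1 / 8) * (7 / 8) / reps)
        assert np.all(np.abs(mean - expect) <= 4 * se)

    def test_binomial_per_gene_marginals(self):
        spec = small_spec(sampling_model="binomial_per_gene", n_i=500, n_j=1)
        reps = 200
        counts = np.zeros(8)
        for child in np.random.SeedSequence(9).spawn(reps):
            rec_i, _ = generate_pair(spec, rng=np.random.default_rng(child))
            for r in rec_i:
                counts[int(r.v_gene[1:])] += 1
        se = np.sqrt(500 * (1 / 8) * (7 / 8) / reps)
        assert np.all(np.abs(counts / reps - 500 / 8) <= 4 * se)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            small_spec(n_i=0)
        with pytest.raises(ValueError):
            small_spec(out_of_frame_fraction=1.0)
        with pytest.raises(ValueError):
            small_spec(usage_i={"V": np.full(8, 0.2), "J": np.array([1.0, 0, 0])})
        with pytest.raises(ValueError):
            small_spec(sampling_model="poisson")


class TestShiftUsage:
    def test_shift_moves_mass_and_renormalises(self):
        spec = paper_like_spec()
        shifted = shift_usage(spec, "V", "V01", 0.05)
        ui = np.asarray(spec.usage_i["V"])
        uj = np.asarray(shifted.usage_j["V"])
        assert uj[0] == pytest.approx(ui[0] + 0.05)
        assert uj.sum() == pytest.approx(1.0)
        assert spec.null_genes("V") == set(spec.genes["V"])
        assert shifted.null_genes("V") == set()  # renormalisation moves all

    def test_true_diff_reports_injected_effect(self):
        spec = shift_usage(paper_like_spec(), "V", "V01", 0.04)
        assert spec.true_diff("V")["V01"] == pytest.approx(-0.04)


class TestErrorRates:
    def test_global_null_fwer_controlled_smoke(self):
        """Bonferroni FWER under a small global null stays near alpha."""
        res = estimate_error_rates(small_spec(n_i=400, n_j=400),
                                   procedures=("bonferroni", "bh"),
                                   reps=200, seed=3)
        se = mc_standard_error(0.05, 200)
        assert res.fwer["bonferroni"] <= 0.05 + 3 * se
        # under a global null every rejection is false, so FDR == FWER
        assert res.fdr["bh"] == pytest.approx(res.fwer["bh"])

    def test_alpha_zero_rejects_nothing(self):
        res = estimate_error_rates(small_spec(n_i=200, n_j=200),
                                   procedures=("bh",), alpha=0.0,
                                   reps=100, seed=4)
        assert res.fwer["bh"] == 0.0 and np.all(res.rejection_counts["bh"] == 0)

    def test_power_reported_for_effect_genes_and_monotone(self):
        base = small_spec(n_i=500, n_j=500)
        powers = []
        for delta in (0.04, 0.10):
            spec = shift_usage(base, "V", "V0", delta)
            res = estimate_error_rates(spec, procedures=("bh",),
                                       reps=100, seed=6)
            assert "V0" in res.power["bh"]
            powers.append(res.power["bh"]["V0"])
        assert powers[0] < powers[1]  # power grows with effect size

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            estimate_error_rates(small_spec(), reps=10, seed=0)


class TestCoverage:
    def test_effect_gene_coverage_near_nominal(self):
        """n=2000/set, usage 0.10 vs 0.05: Wald CI covers the true
        difference at close to the nominal 95%."""
        spec = shift_usage(paper_like_spec(n_i=2000, n_j=2000),
                           "V", "V01", -0.035)
        cov = coverage_study(spec, reps=150, seed=8)
        row = cov[cov["gene"] == "V01"].iloc[0]
        assert row["n_valid"] == 150
        assert abs(row["coverage"] - 0.95) <= 5 * mc_standard_error(0.95, 150)

    def test_wider_interval_covers_at_least_as_often(self):
        spec = small_spec(n_i=800, n_j=800)
        cov95 = coverage_study(spec, ci_level=0.95, reps=100, seed=12)
        cov999 = coverage_study(spec, ci_level=0.999, reps=100, seed=12)
        merged = cov95.merge(cov999, on=["gene", "group"],
                             suffixes=("_95", "_999"))
        assert np.all(merged["coverage_999"] >= merged["coverage_95"])
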