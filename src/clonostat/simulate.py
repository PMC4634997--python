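"""Synthetic two-set clonotype repertoires with known gene-usage structure.

The generator emulates the sampling structure assumed by the per-gene test:
each clonotype independently carries one gene per group, so per-gene counts
in a set of size n are marginally Binomial(n, usage).  Two sampling models
are offered.  ``multinomial`` (default) draws one gene per clonotype per
group from the usage vector, as in real repertoires where a clonotype has
exactly one V gene; ``binomial_per_gene`` draws per-gene counts as
independent binomials, matching the test's independence assumption exactly
at the cost of a random set total.

CDR3 amino-acid sequences, junction frame flags and per-clonotype read
counts are generated so the tables pass through the same I/O and filtering
stages as real data.  What the generator does not emulate: clonal lineage
structure, shared (public) clonotypes, sequencing error, or any dependence
between a clonotype's gene usage and its CDR3 - passing tests therefore
validate the statistical procedure under its own assumptions, not the
upstream annotation of real reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .adjust import METHODS, adjust_pvalues
from .counts import count_by_gene, union_gene_inventory
from .io import AA_ALPHABET, ClonotypeRecord, FilterConfig, filter_clonotypes
from .stats import two_proportion_arrays

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "paper_like_spec",
    "shift_usage",
    "generate_pair",
    "estimate_error_rates",
    "coverage_study",
    "mc_standard_error",
]


def mc_standard_error(q: float, reps: int) -> float:
    """Monte-Carlo standard error of an estimated proportion q over reps."""
    return math.sqrt(max(q * (1 - q), 0.0) / reps)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one two-set repertoire simulation.

    ``genes`` maps a group label (ending in V, D or J) to its gene names;
    ``usage_i``/``usage_j`` give the per-group usage probability vectors of
    the two sets.  Defaults for the nuisance parameters: 5% out-of-frame
    junctions, CDR3 lengths 4 + Poisson(10) (mean 14 AA, the typical human
    TRB scale) with no outlier mass, and geometric read counts with mean 3.
    """

    genes: Mapping[str, Sequence[str]]
    usage_i: Mapping[str, np.ndarray]
    usage_j: Mapping[str, np.ndarray]
    n_i: int = 2000
    n_j: int = 2000
    out_of_frame_fraction: float = 0.05
    cdr3_length_mean: float = 14.0
    cdr3_short_outlier_mass: float = 0.0   # P(length in {2, 3})
    cdr3_long_outlier_mass: float = 0.0    # P(length in 61..70)
    expression_mean: float = 3.0
    sampling_model: str = "multinomial"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_i < 1 or self.n_j < 1:
            raise ValueError("set sizes must be >= 1")
        if not (0.0 <= self.out_of_frame_fraction < 1.0):
            raise ValueError("out_of_frame_fraction must lie in [0, 1)")
        outlier = self.cdr3_short_outlier_mass + self.cdr3_long_outlier_mass
        if not (0.0 <= outlier < 1.0):
            raise ValueError("outlier masses must be in [0, 1) and sum below 1")
        if self.sampling_model not in {"multinomial", "binomial_per_gene"}:
            raise ValueError(f"unknown sampling_model {self.sampling_model!r}")
        if self.expression_mean < 1.0:
            raise ValueError("expression_mean must be >= 1")
        for usage in (self.usage_i, self.usage_j):
            for grp, vec in usage.items():
                v = np.asarray(vec, dtype=float)
                if grp not in self.genes or v.size != len(self.genes[grp]):
                    raise ValueError(f"usage vector for {grp!r} does not match inventory")
                if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-12:
                    raise ValueError(f"usage for {grp!r} must be a probability vector")

    def null_genes(self, group: str) -> set[str]:
        """Genes whose usage is identical in both sets (true nulls)."""
        ui = np.asarray(self.usage_i[group], float)
        uj = np.asarray(self.usage_j[group], float)
        return {g for g, a, b in zip(self.genes[group], ui, uj) if a == b}

    def true_diff(self, group: str) -> dict[str, float]:
        ui = np.asarray(self.usage_i[group], float)
        uj = np.asarray(self.usage_j[group], float)
        return {g: float(a - b) for g, a, b in zip(self.genes[group], ui, uj)}


def _decaying_usage(k: int, strength: float = 9.0) -> np.ndarray:
    w = 1.0 / (np.arange(k) + strength)
    return w / w.sum()


def paper_like_spec(n_i: int = 2000, n_j: int = 2000,
                    seed: int | None = None) -> SimulationSpec:
    """A TRB-scale null spec: 48 V, 2 D and 13 J genes, ~2000 clonotypes/set.

    Gene names are synthetic (V01..V48, D1, D2, J01..J13) so the default
    pseudogene list never intersects them; usage decays smoothly across
    genes, mimicking the skewed usage of real repertoires.  Both sets share
    the same usage (a global null); use :func:`shift_usage` to inject
    effects.
    """
    genes = {
        "V": [f"V{i:02d}" for i in range(1, 49)],
        "D": ["D1", "D2"],
        "J": [f"J{i:02d}" for i in range(1, 14)],
    }
    usage = {
        "V": _decaying_usage(48),
        "D": np.array([0.55, 0.45]),
        "J": _decaying_usage(13),
    }
    return SimulationSpec(genes=genes, usage_i=usage, usage_j=dict(usage),
                          n_i=n_i, n_j=n_j, seed=seed)


def shift_usage(spec: SimulationSpec, group: str, gene: str, delta: float,
                which: str = "j") -> SimulationSpec:
    """Return a spec with one gene's usage shifted by ``delta`` in one set.

    The shift is absorbed proportionally by the other genes of the group so
    the vector stays a probability distribution.
    """
    usage = dict(spec.usage_j if which == "j" else spec.usage_i)
    vec = np.asarray(usage[group], dtype=float).copy()
    idx = list(spec.genes[group]).index(gene)
    new_val = vec[idx] + delta
    if not (0.0 <= new_val <= 1.0):
        raise ValueError("shift pushes usage outside [0, 1]")
    rest = 1.0 - vec[idx]
    vec[np.arange(vec.size) != idx] *= (1.0 - new_val) / rest
    vec[idx] = new_val
    usage[group] = vec / vec.sum()
    if which == "j":
        return replace(spec, usage_j=usage)
    return replace(spec, usage_i=usage)


_AA_ARRAY = np.array(list(AA_ALPHABET))


def _random_cdr3(spec: SimulationSpec, n: int, rng: np.random.Generator) -> list[str]:
    lengths = 4 + rng.poisson(max(spec.cdr3_length_mean - 4.0, 0.0), size=n)
    lengths = np.minimum(lengths, 60)
    u = rng.random(n)
    short = u < spec.cdr3_short_outlier_mass
    long_ = (~short) & (u < spec.cdr3_short_outlier_mass + spec.cdr3_long_outlier_mass)
    lengths[short] = rng.integers(2, 4, size=int(short.sum()))
    lengths[long_] = rng.integers(61, 71, size=int(long_.sum()))
    max_len = int(lengths.max(initial=1))
    letters = _AA_ARRAY[rng.integers(0, len(_AA_ARRAY), size=(n, max_len))]
    return ["".join(row[:ln]) for row, ln in zip(letters, lengths)]


def _generate_set(spec: SimulationSpec, usage: Mapping[str, np.ndarray],
                  n: int, set_id: str, rng: np.random.Generator) -> list[ClonotypeRecord]:
    groups = list(spec.genes)
    assignments: dict[str, np.ndarray] = {}
    if spec.sampling_model == "binomial_per_gene":
        # Independent Binomial(n, usage) counts for every group; the primary
        # (first) group fixes the record count, other groups are resampled
        # to that length from their usage vectors.
        primary = groups[0]
        counts = rng.binomial(n, np.asarray(usage[primary], float))
        total = int(counts.sum())
        assignments[primary] = np.repeat(np.arange(counts.size), counts)
        rng.shuffle(assignments[primary])
        for grp in groups[1:]:
            assignments[grp] = rng.choice(
                len(spec.genes[grp]), size=total, p=np.asarray(usage[grp], float))
        n = total
    else:
        for grp in groups:
            assignments[grp] = rng.choice(
                len(spec.genes[grp]), size=n, p=np.asarray(usage[grp], float))

    cdr3 = _random_cdr3(spec, n, rng)
    in_frame = rng.random(n) >= spec.out_of_frame_fraction
    if spec.expression_mean > 1.0:
        n_seq = rng.geometric(1.0 / spec.expression_mean, size=n)
    else:
        n_seq = np.ones(n, dtype=int)

    def gene_of(grp_role: str, idx: int) -> str | None:
        for grp in groups:
            if grp[-1].upper() == grp_role:
                return spec.genes[grp][assignments[grp][idx]]
        return None

    records = []
    for idx in range(n):
        records.append(ClonotypeRecord(
            v_gene=gene_of("V", idx) or "V-undefined",
            d_gene=gene_of("D", idx),
            j_gene=gene_of("J", idx) or "J-undefined",
            cdr3_aa=cdr3[idx],
            in_frame=bool(in_frame[idx]),
            n_sequences=int(n_seq[idx]),
            clonotype_id=f"{set_id}-{idx + 1}",
            set_id=set_id,
        ))
    return records


def generate_pair(
    spec: SimulationSpec, rng: np.random.Generator | None = None,
) -> tuple[list[ClonotypeRecord], list[ClonotypeRecord]]:
    """Draw the two clonotype tables described by the spec.

    Reproducible: a given ``spec.seed`` (or an explicitly passed generator
    state) always yields the same pair of tables.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    records_i = _generate_set(spec, spec.usage_i, spec.n_i, "sim_i", rng)
    records_j = _generate_set(spec, spec.usage_j, spec.n_j, "sim_j", rng)
    return records_i, records_j


@dataclass(frozen=True)
class SimulationResult:
    """Empirical error rates from replicated full-pipeline runs."""

    reps: int
    alpha: float
    procedures: tuple[str, ...]
    fwer: Mapping[str, float]
    fdr: Mapping[str, float]
    power: Mapping[str, Mapping[str, float]]  # method -> gene -> power
    rejection_counts: Mapping[str, np.ndarray] = field(repr=False, default_factory=dict)

    def fwer_se(self, method: str) -> float:
        return mc_standard_error(self.fwer[method], self.reps)

    def fdr_se(self, method: str) -> float:
        # SE of a mean of per-replicate FDP values, bounded by the proportion SE
        return mc_standard_error(self.fdr[method], self.reps)


_SIM_FILTER = FilterConfig(exclude_pseudogenes=False)


def _replicate_tests(spec: SimulationSpec, groups: Sequence[str],
                     rng: np.random.Generator, min_expected: float,
                     ci_level: float = 0.95):
    """One replicate: generate, filter, count, test.  Yields per-group
    (genes, stats-dict, true-diff map, null-gene set)."""
    rec_i, rec_j = generate_pair(spec, rng=rng)
    kept_i, _ = filter_clonotypes(rec_i, _SIM_FILTER)
    kept_j, _ = filter_clonotypes(rec_j, _SIM_FILTER)
    for grp in groups:
        t_i = count_by_gene(kept_i, grp)
        t_j = count_by_gene(kept_j, grp)
        genes = union_gene_inventory(t_i, t_j,
                                     reference_order=list(spec.genes[grp]))
        stats = two_proportion_arrays(
            np.array([t_i.count(g) for g in genes]), t_i.n_total,
            np.array([t_j.count(g) for g in genes]), t_j.n_total,
            ci_level=ci_level, min_expected=min_expected)
        yield grp, genes, stats, spec.true_diff(grp), spec.null_genes(grp)


def estimate_error_rates(
    spec: SimulationSpec,
    procedures: Sequence[str] = METHODS,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    groups: Sequence[str] = ("V",),
    min_expected: float = 5.0,
) -> SimulationResult:
    """Empirical FWER, FDR and per-gene power of the full pipeline.

    Each replicate runs generation -> filtering -> counting -> pooled
    z-tests -> family building -> adjustment, then scores rejections
    against the spec's true usage vectors.  FWER is the fraction of
    replicates with at least one false rejection; FDR the mean of
    (false rejections)/max(1, rejections).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for meaningful error rates")
    children = np.random.SeedSequence(seed).spawn(reps)
    false_any = {m: 0 for m in procedures}
    fdp_sum = {m: 0.0 for m in procedures}
    rej_counts = {m: np.zeros(reps, dtype=int) for m in procedures}
    power_hits: dict[str, dict[str, int]] = {m: {} for m in procedures}
    power_total: dict[str, int] = {}

    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        fam_genes: list[str] = []
        fam_raw: list[float] = []
        fam_null: set[str] = set()
        effect_genes: set[str] = set()
        for grp, genes, stats, _true, nulls in _replicate_tests(
                spec, groups, rng, min_expected):
            valid = stats["valid"]
            for g, ok, p in zip(genes, valid, stats["raw_p"]):
                if ok:
                    fam_genes.append(g)
                    fam_raw.append(float(p))
            fam_null |= nulls
            effect_genes |= set(spec.genes[grp]) - nulls
        for g in effect_genes:
            power_total[g] = power_total.get(g, 0) + 1
        if not fam_raw:
            continue
        raw_arr = np.asarray(fam_raw)
        for method in procedures:
            adj = adjust_pvalues(raw_arr, method=method)
            rejected = adj <= alpha
            n_rej = int(rejected.sum())
            rej_counts[method][rep] = n_rej
            false_rej = sum(1 for g, r in zip(fam_genes, rejected)
                            if r and g in fam_null)
            if false_rej:
                false_any[method] += 1
            fdp_sum[method] += false_rej / max(1, n_rej)
            for g, r in zip(fam_genes, rejected):
                if r and g in effect_genes:
                    power_hits[method][g] = power_hits[method].get(g, 0) + 1

    power = {
        m: {g: power_hits[m].get(g, 0) / power_total[g] for g in power_total}
        for m in procedures
    }
    return SimulationResult(
        reps=reps, alpha=alpha, procedures=tuple(procedures),
        fwer={m: false_any[m] / reps for m in procedures},
        fdr={m: fdp_sum[m] / reps for m in procedures},
        power=power, rejection_counts=rej_counts,
    )


def coverage_study(
    spec: SimulationSpec,
    ci_level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
    groups: Sequence[str] = ("V",),
    min_expected: float = 5.0,
):
    """Per-gene empirical coverage of the Wald CI for the usage difference.

    Returns a DataFrame (gene, group, true_diff, coverage, n_valid, mc_se)
    where coverage is the fraction of replicates with adequate expected
    counts whose interval contains the true difference.  Genes never
    adequately counted are omitted.
    """
    import pandas as pd

    if reps < 100:
        raise ValueError("reps must be >= 100")
    children = np.random.SeedSequence(seed).spawn(reps)
    hits: dict[tuple[str, str], int] = {}
    valid_n: dict[tuple[str, str], int] = {}
    truth: dict[tuple[str, str], float] = {}

    for child in children:
        rng = np.random.default_rng(child)
        for grp, genes, stats, true, _nulls in _replicate_tests(
                spec, groups, rng, min_expected, ci_level=ci_level):
            for g, ok, lo, hi in zip(genes, stats["valid"],
                                     stats["ci_low"], stats["ci_high"]):
                if not ok:
                    continue
                key = (grp, g)
                truth[key] = true[g]
                valid_n[key] = valid_n.get(key, 0) + 1
                if lo <= true[g] <= hi:
                    hits[key] = hits.get(key, 0) + 1

    rows = []
    for (grp, g), n in sorted(valid_n.items()):
        cov = hits.get((grp, g), 0) / n
        rows.append({"gene": g, "group": grp, "true_diff": truth[(grp, g)],
                     "coverage": cov, "n_valid": n,
                     "mc_se": mc_standard_error(cov, n)})
    return pd.DataFrame(rows)
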