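# Methods

## Model and assumptions

A clonotype summary table lists, for one sequencing set, every distinct
amino-acid clonotype (a unique V-(D)-J rearrangement with its CDR3
amino-acid junction) together with its gene assignments and read count.
For a fixed gene group (e.g. the V genes of a locus) and gene *k*, carrying
gene *k* is modelled as a Bernoulli indicator per clonotype, i.i.d. within
a set: the count $c_{ik}$ among the $n_i$ clonotypes of set *i* is then
Binomial($n_i$, $p_{ik}$).  Sets are assumed independent of each other.

In reality a clonotype carries exactly one gene per group, so the vector of
per-gene counts in a set is multinomial and mildly negatively dependent
across genes; the per-gene marginals are still exactly binomial, which is
the property the test uses.  The Monte-Carlo harness exercises both
sampling models (see below).

Diversity mode counts each clonotype once; expression mode weights it by
its read count.  Expression counts are not independent Bernoulli draws
(reads cluster within clones), so expression-mode p-values should be read
as descriptive unless clone sizes are small; this caveat is inherited from
the procedure itself.

## Estimation and testing

Per gene: difference $\hat p_{ik} - \hat p_{jk}$, unpooled standard
deviation, and Wald CI with the exact standard-normal quantile by default.
Significance uses the pooled z statistic with the size-weighted pooled
proportion; the two-tailed p-value is computed with the complementary
normal CDF (`scipy.stats.norm.sf`), which remains accurate far beyond
|z| = 5 where naive `1 − Φ(z)` loses all precision.

The large-sample approximation is only reported as a test when all four
expected counts — $c$, $n-c$ in both sets — reach a threshold (default 5).
Genes failing the rule (including genes absent from one set) keep their row
in the output, flagged with a reason, but contribute neither a p-value nor
a unit to the family size *m*.  Genes absent from *both* sets carry no
information and are dropped from the inventory altogether.

### The CI critical value

The worked reference report computes its 95% interval with the conventional
two-decimal critical value 1.96; the exact quantile is 1.959964.  The two
choices differ in the sixth decimal place of a bound.  `compare_proportions`
defaults to the exact quantile and takes an explicit `z_crit` for
reproducing reports that used the rounded convention.

## Multiple testing

The seven procedures are implemented in adjusted-p-value form (the smallest
level at which the sequential rule rejects), so `adjusted ≤ α` is exactly
the step-down/step-up decision.  Formulas are documented in
`clonostat.adjust`; the Šidák terms use `expm1`/`log1p` so that p-values of
order 1e-26 survive, and the BY penalty $c(m)=H_m$ is computed by direct
summation (families are at most a few hundred).  Ties share adjusted values
through the cumulative max/min formulations over a stable sort.  Rejection
at level α uses `adjusted ≤ α`; the strict/non-strict boundary is
unobservable at any printed precision.

**Family composition.**  One comparison forms one family pooled across the
requested gene groups (V, D and J rows adjusted together), with a
`per-group` option.  The family contains exactly the valid tests; the
expected-count-invalid genes are excluded from *m*.  For the bundled
reference comparisons this yields m = 61, 59, 59, 61 (Pre, d3, d8, d26),
recovered from the ratio of a printed Bonferroni-adjusted to unadjusted
p-value (the rank-2 row for d3, whose rank-1 raw value is
display-truncated).

**Truncated families.**  `adjust_pvalues` accepts m larger than the number
of supplied p-values, treating the supplied values as the smallest of the
family.  Bonferroni, single-step Šidák, Holm and step-down Šidák are then
exact.  Hochberg, BH and BY start their backward cumulative minimum at the
largest supplied rank, which assumes every unsupplied value yields a larger
step term; rejection counts at α are exact whenever all unsupplied raw
p-values exceed α — the situation of the bundled tables, which print every
value below 0.05.

## Synthetic repertoires

`SimulationSpec` fixes a gene inventory per group, usage vectors for both
sets, set sizes, and nuisance parameters chosen to mimic a human TRB
experiment at the scale of roughly two thousand clonotypes per set:

* `out_of_frame_fraction` = 0.05 — a small fraction of junctions carry a
  frameshift and are removed by the in-frame filter;
* CDR3 length = 4 + Poisson(10), i.e. mean 14 AA, truncated at 60, with
  configurable outlier mass below 4 and above 60 (default 0);
* read counts per clonotype geometric with mean 3;
* usage decaying smoothly across genes in the default 48 V / 2 D / 13 J
  inventory (`paper_like_spec`), uniform vectors available for calibration.

Frame status, CDR3 length and read count are drawn independently of the
gene assignment, so filtering leaves the per-gene usage probabilities
unchanged and the spec's usage vectors remain the ground truth after the
pipeline's filter stage.  `shift_usage` injects an effect on one gene and
renormalises the remaining genes proportionally — note that renormalisation
makes every gene's usage differ slightly between sets, so a shifted spec
has no exact nulls.

What passing simulation tests shows: the pooled z-test and the adjustment
procedures control their error rates under the sampling structure the
method itself assumes.  What it does not show: robustness to clonotype
mis-assignment, clone-size dependence between gene and expression, or any
other feature of real sequencing data that violates the i.i.d. Bernoulli
model.

`estimate_error_rates` runs the full pipeline per replicate (generate →
filter → count → test → adjust) and reports empirical FWER (fraction of
replicates with ≥ 1 false rejection), FDR (mean false discovery
proportion), and per-gene power, each with Monte-Carlo standard errors
$\sqrt{q(1-q)/\text{reps}}$.  `coverage_study` reports per-gene CI coverage
among replicates where the gene passed the validity rule.

### Problem sizes

Calibration runs use the prescribed scale — 60 genes, 2000 clonotypes per
set, 1000 replicates — for the headline FWER/FDR and coverage checks
(about a minute each); module-level smoke tests use 8–48 genes, 200–800
clonotypes and 100–300 replicates with correspondingly wide Monte-Carlo
tolerances.

## Filtering and gene names

Records are dropped, in this order of reasons, when out-of-frame, when the
CDR3 length falls outside the inclusive keep-range [4, 60] (the bound is
applied to the `cdr3_aa` field as given), or when the V gene is a listed
pseudogene.  The shipped default list holds the six human TRBV pseudogenes
that cannot produce a receptor chain; ORF genes are kept, and genes with
unknown functionality are kept with a warning.  Gene labels are normalised
by stripping a species prefix, an allele suffix (`*NN`) and trailing
functionality tokens, so counting is per gene, never per allele; a
comma-separated multi-gene assignment is rejected at parse time because the
clonotype definition fixes a unique rearrangement.

## Design choices on open points

* Display order of genes defaults to natural (numeric-aware) name order,
  with an optional locus reference order; the forest plot can instead sort
  by effect size.
* Clonotypes without a D assignment are omitted from the D group's counts
  and total (D totals are therefore smaller than V/J totals, as in real
  TRB data where short D segments often cannot be called).
* Significance classes for the forest plot partition the valid genes with
  precedence all-seven > two-or-more > BH-only > raw-only > none; invalid
  genes are drawn greyed-out rather than omitted.
* Continuity corrections, exact (Fisher) tests and score/Wilson intervals
  are out of scope: the procedure standardises on the plain Wald/pooled-z
  forms.

## Known limitations

* The Wald interval undercovers for very small expected counts; the
  validity rule guards the test but the CI is still reported for flagged
  genes and should be read qualitatively there.
* Truncated-family adjustments of step-up procedures are assumption-bound
  as described above.
* The generator does not model public clonotypes, sequencing error or
  clone-size/gene dependence; calibration results transfer to real data
  only insofar as the i.i.d. Bernoulli model holds.
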