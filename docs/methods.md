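# Methods

This note documents the statistical conventions, the synthetic data
model, and the design choices behind `lifespankit`. No empirical claim
here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Survival estimation and testing

**Kaplan–Meier.** The product-limit estimator is computed over the
distinct event times; censored records leave the risk set at their time
without contributing an event. With no censoring S(t) reduces exactly to
the empirical survival function (asserted as a property test). Lifespans
are whole days (the data model rejects fractional days), so ties are
common and handled through the risk-set bookkeeping.

**Median.** The median is the smallest event time with S(t) ≤ 0.5. When
the curve sits *exactly* at 0.5, the midpoint between that time and the
next event time is reported; this plateau convention makes the
all-events, even-n case (e.g. lifespans 1, 2, 3, 4 → median 2.5) behave
like the familiar sample median. A curve that never reaches 0.5 (heavy
censoring) raises an explicit undefined-median error rather than
returning a sentinel.

**Log-rank.** Standard two-group form: at each distinct event time the
observed events in group 1 are compared with the hypergeometric
expectation d·n₁/n, with variance d(n₁/n)(n₂/n)(n−d)/(n−1); the squared
standardised sum is χ² on 1 df. Implementation is cross-checked against
exact-rational hand tables on small examples and against `lifelines` on
random censored data.

**Fisher's exact test.** Two-sided p by the minimum-likelihood rule: the
sum of hypergeometric point probabilities (computed from integer
binomial coefficients) not exceeding the observed table's probability,
with a 1e−7 relative slack so that floating-point representation cannot
split exact ties. This convention reproduces the published decile
p = 0.0157 on the symmetric 50/50 design and matches the dominant
software convention. An exhaustive-enumeration oracle over all tables
with row sums ≤ 12 backs the implementation.

**Student's t.** Pooled-variance by default ("Student's"), Welch behind a
flag. Zero pooled variance is handled explicitly: p = 1 for equal means,
p = 0 (infinite statistic) otherwise.

**Maximum-lifespan decile test.** k = ⌊q·N⌋ of the pooled cohorts
(q = 0.10 by default). Ties at the cutoff are broken deterministically —
descending lifespan, then ascending mouse id, then group — and flagged
with a warning; with duplicated cohorts the symmetric 5/5 split follows
from the pairing of tied values regardless of the within-tie order. The
genotype-by-membership table goes to Fisher's test. The companion
comparison averages the top ⌊q·n⌋ lifespans *within* each cohort
(mean ± SEM) and applies the pooled t-test; the percent difference of
those means is reported. Censored records make the test undefined and
are rejected.

**Daily chi-square scan.** For each day from the first to the last death
over both groups, the (died ≤ d vs alive > d) × group table is tested by
Pearson's χ² without continuity correction (a corrected variant is
exposed by flag); days with a zero margin get p = 1 by convention and
are counted. Windows are maximal runs of consecutive days with p < α;
each window records the total deaths (both groups) inside it. No
multiplicity adjustment is applied across days — the scan reports the
number of days tested so users can correct as they see fit.

## Tumour metrics

Incidence uses necropsied mice only as the denominator and is reported
to one decimal. Occurrence is the age at death of each tumour-bearing
mouse. Load is the number of distinct tumour types in a mouse. Spread is
implemented as the number of distinct (organ, type) pairs: this counts
one type in two organs as 2 and also rates two different types in the
same organ as 2, which is the only reading consistent with both clauses
of the field definition ("number of different organs ... irrespective of
the type, except that different types in the same organ each count").
Because of the multi-organ single-type case, load ≤ spread is *not* an
invariant; only load ≥ 1 and spread ≥ 1 per bearing mouse are. Type
frequencies count mice, not findings. Tumour-stratified survival splits
each cohort into bearing/free among necropsied mice and runs the
log-rank within each stratum; empty strata are marked not computable.

## Expression variability

FPM is depth-only normalisation (10⁶·count/library size); no gene-length
term enters, and the CV is length-invariant anyway. The expression
filter keeps genes with overall mean ≥ 1 FPM (the boundary gene is
retained; only genes below the threshold are excluded) and is
idempotent. CV uses the n−1 sample SD — the per-group n of 6 makes the
small-sample convention matter — and is configurable. Genes with a zero
within-group mean have undefined CV, are dropped from ratio selection
and counted. The comparison line is OLS of group-2 CV on group-1 CV with
intercept; the selections use the plain CV-ratio > 2 rule with no
absolute-CV floor (a floor can be supplied). Over-representation is the
one-sided hypergeometric upper tail against a user-supplied universe and
GMT collection, with Benjamini–Hochberg FDR across the tested terms
(terms disjoint from the universe are skipped). `differential_count` is
a deliberately simple stand-in for a dedicated count-model engine: a
per-gene pooled t-test on log2(FPM + 1) with BH correction; its method
string is carried in the output.

## Synthetic data model

The generator mirrors the design of a two-genotype, two-sex, 50-per-arm
lifespan study:

* **Mortality** follows the Gompertz law h(t) = a·e^{bt}, sampled by the
  inverse CDF t = (1/b)·ln(1 + (b/a)(−ln U)) and rounded to whole days
  (minimum 1). Defaults a = 4.71e−6/day, b = 0.012/day put the wild-type
  median at ≈ 623 days — the anchor value for C57BL/6J females in this
  setting — and the genotype effect is a proportional scaling of `a`
  (hazard ratio 0.214 by default, chosen so the closed-form medians
  separate by ≈ 20.6%, the study-scale effect). Scaling `a` rather than
  `b` is the simplest one-parameter longevity effect and keeps the
  closed-form quantile available for recovery tests.
* **Ulcerative dermatitis** flags are Bernoulli at the per-stratum
  incidences 38/52/30/20 percent; UD and background mortality are
  independent by default, with a rank-correlation knob for sensitivity
  analyses. Necropsy dropout counts default to 0/2/3/5 across the four
  strata, matching the study's exclusion pattern (denominators
  50/48/47/45).
* **Tumours**: P(bearing | age at death) is logistic with intercept −3
  and slope 0.006/day, giving ≈ 68% at the wild-type female median and a
  positive age-selection effect (tumour-bearing mice die older than the
  cohort average, a property the tests assert). Bearing mice receive 1–3
  distinct findings from a fixed type/organ table dominated by lymphoma,
  hepatocellular carcinoma and histiocytic sarcoma.
* **Counts** are negative binomial parameterised by mean and dispersion
  φ with Var = m + φm², making CV² ≈ 1/m + φ explicit for test design.
  Gene means are log-uniform over (1, 5000); φ = 0.1 for "young" groups
  and 0.6 (6×) on a planted 100-gene subset in "old" groups. Library
  sizes are column totals, and the planted truth is returned.

What the generator does **not** emulate: correlated gene-gene
expression, batch or library-preparation effects, sex- or
genotype-specific tumour incidence, cause-of-death dependence between UD
and malignancy, and any mechanistic link between the genotype and the
expression program. Passing recovery tests therefore demonstrate the
correctness and calibration of the statistics under the stated
generative model, not performance on real tissue data.

## Calibration and the discreteness of exact tests

Type-I calibration is checked under the null simulator (two identical
Gompertz arms, n = 50 each, 2000 replicates). The log-rank statistic is
asymptotically χ²₁ and its measured size sits near the nominal 0.05. The
two discrete tests cannot reject at the nominal rate: the
decile-membership Fisher test has exact size 0.0157 at α = 0.05
(enumerable over the hypergeometric support — Fisher is conservative by
construction), and the median-day Pearson χ² has exact size ≈ 0.057
(enumerable over the two binomial death counts). The calibration checks
therefore compare the Monte-Carlo rejection rate of each discrete test
with its *enumerated exact size* (binomial 99% CI), which is the
statistically meaningful statement of correctness; both enumerations are
independent of the Monte-Carlo pipeline.

## Limits of the CV-ratio rule at n = 6

With 6× dispersion inflation the true CV ratio is bounded by
√6 ≈ 2.449 (from CV² ≈ 1/m + φ), and the sampling noise of a CV estimate
at n = 6 is roughly CV/√(2(n−1)) ≈ 0.32·CV per group. The probability
that an estimated ratio clears the 2× threshold is therefore ≈ 0.6 for
any baseline dispersion and mean range ≥ 50 — a majority of planted
genes, but not a high-sensitivity detector. The recovery experiments
report sensitivity and the false-discovery proportion of the selection
(kept below 0.3 at the default 100-planted-in-300 design) rather than
overstating the rule's power.

## Problem sizes and numerical choices

Simulation-based tests use 100–2000 replicates and cohort sizes of
50–5000; the Kaplan–Meier/Gompertz median recovery uses 10⁵ draws (well
inside a 1% relative-error target, since the median's sampling error
scales like 1/√n). Exact-rational oracles (Python fractions and integer
binomials) back Fisher, the hypergeometric tail, BH and the log-rank
hand tables, so oracle comparisons carry no floating-point slack beyond
1e−9 relative. All randomness flows through `numpy.random.Generator`
seeded per run; every generator is byte-reproducible under a fixed seed.

## Known limitations

* The log-rank is the only weighting offered (no Gehan–Breslow–Wilcoxon,
  no Cox model) — matching the analyses this package reproduces.
* `differential_count` is not a substitute for a negative-binomial GLM
  engine at small n; it exists so the pipeline's counting contract
  (up/down/total at an FDR threshold) is exercised end to end.
* The daily scan's windows inherit the per-day test's anticonservatism
  at small risk sets; interpret window edges, not single days.
* Tumour spread follows the pair-count reading documented above; if
  three types share one organ it rates 3, a case the verbal definition
  leaves ambiguous.
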