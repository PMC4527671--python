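# Methods

## Gompertz mortality model

Deaths are modelled with the Gompertz hazard mu(x) = R0·exp(alpha·x), where
alpha (1/day) is the demographic rate of ageing and R0 (1/day) the baseline
mortality. The survivorship is S(x) = exp(−(R0/alpha)(e^{alpha·x} − 1)) and,
for fully observed death ages, the log-likelihood is

    l(alpha, R0) = sum_i [ ln R0 + alpha·x_i − (R0/alpha)(e^{alpha·x_i} − 1) ].

The likelihood treats the recorded census day as the exact death time. With
a daily census and MRDT = ln(2)/alpha around 7–9 days, the discretisation
error is far below sampling noise, and the convention matches the standard
demographic ML tools for fly data. No censoring machinery enters the fit:
cohorts are followed to death (the record format still carries an event
flag, and the Kaplan–Meier and rank-test code honours it).

Optimisation runs in (ln alpha, ln R0) with analytic gradients (L-BFGS-B,
objective tolerance 1e-12, followed by a Nelder–Mead polish), initialised
from an OLS regression of the binned log-hazard on age. The fit is
deterministic; a `converged` flag is reported honestly and downstream
likelihood-ratio tests refuse to run on non-converged fits.

**Goodness of fit.** Reported lifespan summaries of this kind quote a
"determination coefficient of the Gompertz approximation" without defining
it. Ours is a documented stand-in: a life-table hazard on fixed 5-day age bins,
mu_k = d_k/(n_k·5) with n_k the number alive at the bin start, and R² of the
OLS of ln mu_k on bin midpoints over bins with at least one death. Bin
width is configurable; fewer than 3 informative bins yields a sentinel
(None), never a fabricated number.

**Likelihood-ratio test.** Mortality-intensity differences between two
groups are tested by 2(l_full − l_constrained) ~ chi², where the full model
gives each group its own (alpha, R0) and the constraint shares alpha, R0,
or both (df = number of shared parameters). Null calibration is verified by
simulation in the test suite.

## Lifespan quantiles and two-sample tests

Median lifespan is the smallest observed death age with S ≤ 0.5; the age of
90% mortality uses S ≤ 0.1. Both follow the Kaplan–Meier step-function
convention, which yields the integer day values a daily census produces; an
unreached threshold returns an explicit sentinel.

The log-rank and Gehan–Breslow–Wilcoxon statistics are the weighted
log-rank Z = Σ w(O−E)/sqrt(Σ w²V) with w ≡ 1 and w = pooled number at risk
respectively, hypergeometric variance V with standard tie handling, and a
two-sided normal p-value. The statistic is signed (positive = first group
dies earlier), so label swaps flip the sign and preserve p. Both tests also
offer an exact permutation mode (full enumeration of group assignments) for
small samples; tests verify it against an independent brute-force oracle
and the asymptotic p against lifelines.

The modified KS test computes D = sup|S_a − S_b| over the two Kaplan–Meier
curves — with censoring, the curves themselves carry the correction; for
uncensored data D is exactly the classical two-sample KS statistic, which
is the binding contract the tests assert. The p-value uses the asymptotic
Kolmogorov distribution with effective size n_a·n_b/(n_a+n_b) and Stephens'
small-sample factor.

The Wang–Allison test thresholds at the smallest age by which ≥90% of the
pooled sample has died (ties: deaths exactly at the threshold count as
died-at-or-before), builds the 2×2 group × died/survived table, and applies
the two-sided Fisher exact test by probability-mass summation (not
doubling), making results bit-reproducible. scipy's implementation uses
exactly this rule and is verified in the tests against direct
hypergeometric enumeration.

## Strehler–Mildvan regression

Across populations, ln R0 = gamma − beta·alpha is fitted by OLS of ln R0 on
alpha (slope = −beta). Beta (days) equals the common abscissa at which the
log-hazard lines intersect — checked exactly in the tests via the
closed-form pairwise intersection (ln R0_1 − ln R0_2)/(alpha_2 − alpha_1).
Deviation of a single population from the line is tested with the
externally studentized residual against t(n−3). The regression is run on
per-replicate fits (three cohorts per dose group), matching how the
correlation is examined in practice; pooled-group fits populate the summary
table.

## Synthetic lifespan data

Cohorts are drawn by inverse-CDF sampling,
x = (1/alpha)·ln(1 − alpha·ln U/R0), then discretised by rounding **up** to
the census grid: a fly found dead during day k is recorded at day k. The
ceiling convention is our choice (the census protocol does not fix it); it
never decreases an age, and at integer ages the discretised survival equals
the continuous law exactly, which is why the simulated median (58 d) and
90%-mortality age (71 d) at the male-control parameters alpha = 0.092,
R0 = 0.00031 match the closed forms. Defaults mirror the study design:
3 replicates × 150–170 flies per group, two control groups per sex
(short- and long-exposure sessions) with optional merging, dose rate
36 mGy/h with exposure durations giving 5/10/20/40 cGy. No censoring is
generated. Random streams are per-cohort substreams of the master seed
(SeedSequence spawn keys), so adding a group leaves other groups'
draws untouched.

What the generator does **not** emulate: vial effects and other
within-replicate dependence, age-dependent frailty heterogeneity,
non-Gompertzian late-life mortality plateaus, or any dose-response linkage
between alpha and dose (group parameters are set independently). Passing
tests therefore demonstrate statistical correctness of the estimators under
the stated model, not robustness to those real-data features.

## qPCR simulation and analysis

Ct values follow Ct = baseline − c·ln2/ln(E) + technical noise, where c is
the true log2 concentration (planted group effect + biological noise) and E
the per-gene efficiency, so E = 2 means one cycle per doubling. Defaults:
sigma_bio = 0.25 (log2 units), sigma_tech = 0.15 cycles — typical bench
values — with an extra sigma = 1.5 per-sample instability for planted
unstable genes; 3 biological × 3 technical replicates; efficiencies in
(1.9, 2.2].

Technical triplicates are collapsed by the arithmetic mean; triplicates
with SD > 0.5 cycles and missing reactions are flagged, never silently
imputed. Stability methods run on the collapsed matrix:

- **delta-Ct**: mean over partners of the SD of pairwise Ct differences.
- **BestKeeper**: SD of Ct as the primary score (the original tool's MAD is
  deliberately not used; SD keeps the score consistent with the other
  methods), plus CV% and the correlation with the per-sample candidate
  index.
- **NormFinder**: on log2 expression (−Ct·log2 E) with per-sample means
  across candidates removed, within-group variances s²_g and group means
  are combined as stability = sqrt(max(0, var(group means) − mean(s²_g/n_g))
  + mean(s²_g)) — a documented simplification of the model-based
  intra/inter-group decomposition. With one group it reduces to the SD of
  the centred log2 expression.
- **geNorm**: M = mean SD of pairwise log-ratios of relative quantities
  Q = E^(minCt−Ct), with stepwise exclusion of the highest-M gene; the
  final pair ties for the top rank.

The consensus is the arithmetic mean of the four per-method ranks (average
ranks on ties, alphabetical tie-break), and the top two genes become the
reference set unless overridden.

Relative expression uses the efficiency-corrected, geometric-mean-of-
references formula given in the README; the implementation works in log
space for numerical stability and the hand identities hold to 1e-10.
Fold changes pair replicates by index (replicate b vs replicate b) by
default, with an all-pairs mode available. The significance test on log2
relative expression is a two-sided Welch t-test by default (the choice is
recorded in every report; Mann–Whitney is available) — no specific test is
mandated by the source methodology, so the default is the field-standard
small-sample choice. No multiple-testing correction is applied by default;
a Benjamini–Hochberg flag exists.

**Variability filter.** The DE rule excludes contrasts whose
SD(log2FC)/|mean log2FC| exceeds a threshold. The literal reading of the
"SD more than 5% of mean" exclusion (threshold 0.05) is implausibly strict
for 3-replicate qPCR — with sigma_bio = 0.25 the SD of a paired log2FC is
~0.35, so virtually every true 2-fold change would be excluded — so the
threshold is a first-class config parameter: the default stays at the
literal 0.05, and the analysis drivers use 0.5 as the working value.

## Problem sizes and numerical choices

Simulation studies in the test suite use the sizes at which their
statistical claims are sharp: 100,000 ages for distributional fidelity of
the simulator, 3,000-fly cohorts × 200 seeds for ML parameter recovery
(median |alpha error| < 5%), 200-seed ensembles for Strehler–Mildvan CI
coverage, 2,000 null simulations for Wang–Allison conservativeness, 500 for
rank-test calibration, and 100–200 seeds for the planted-truth qPCR
recoveries. The grid-search oracle uses a 200×200 grid in
(alpha, ln R0). Fisher p-values and permutation p-values are exact;
asymptotic normal/chi² p-values are used where the source analyses used
them. All simulations are seeded and deterministic.

## Known limitations

- The modified KS p-value is asymptotic; for very small cohorts it is
  approximate (the statistic itself is exact).
- The NormFinder score is a simplified variance decomposition, not a
  re-implementation of the original tool's shrinkage estimator; rankings
  agree on planted designs, exact stability values may differ.
- The binned-hazard R² depends on the bin width (default 5 days) and is not
  comparable across bin-width choices.
- One reported summary row (females, 40 cGy) prints an MRDT inconsistent
  with its own alpha at printed precision; the consistency checks
  explicitly except it.
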