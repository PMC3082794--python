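# Methods

## Three-source capture–recapture

### Data and model family

The observable data are the 7 cells of the 2×2×2 source-incidence table;
the all-absent cell is structurally unobservable. Cell counts are treated
as independent Poisson with log-linear mean. All 8 hierarchical models
contain the intercept and the three source main effects; they differ in
which pairwise interactions {AB, AC, BC} are included. A pairwise term is
the log odds-ratio of joint capture and absorbs positive or negative
dependence between two sources. The three-way interaction is excluded: with
7 observations it would saturate the table and leave the missing cell
unidentified. Residual degrees of freedom are df = 3 − (#interactions).

The missing-study count is the model's extrapolation to the all-absent
pattern, X̂ = exp(intercept), and N̂ = n_obs + X̂. Key assumptions: the
population of eligible studies is closed (fixed during the search window),
studies are homogeneous in capture probability within a source (no
study-level heterogeneity model), and any source dependence is captured by
the included pairwise terms. Dependence not represented in the fitted model
biases N̂ — positively dependent sources overlap more than independence
predicts and pull the estimate down; negative dependence pulls it up. The
simulation tests assert this direction.

### Fitting and identifiability

Fitting uses iteratively reweighted least squares for the Poisson log link
on the 7 cells, deviance-change tolerance 1e-10, at most 100 iterations.
Zero cells are handled by the likelihood itself (0·ln 0 = 0); no continuity
correction is added. Goodness of fit is G² = 2·Σ obs·ln(obs/fitted) over
the 7 cells, with upper-tail chi-square p; at df = 0 (saturated) a zero
deviance is reported as p = 1 by convention.

Some models have no finite maximum: the likelihood drives the intercept to
+∞ (e.g. when a needed overlap cell is empty — in the worked example
n_AC = 0 makes the saturated extrapolation X̂ = n_ABC·n_A·n_B·n_C /
(n_AB·n_AC·n_BC) infinite). A fit is declared non-identifiable when
X̂ > 1000·n_obs or the intercept's standard error is non-finite; such fits
report X̂ = N̂ = ∞ and are excluded from model selection. The threshold
1000·n_obs is far above any plausible completeness scenario and far below
where IRLS iterates actually land for divergent fits (~1e12), so the flag
is insensitive to its exact value.

### Model selection and criteria

AIC = G² − 2·df and BIC = G² − ln(n_obs/2π)·df, with n_obs the number of
observed studies; smallest value wins among identifiable fits, ties broken
toward fewer interaction terms, then canonical order. Both criteria are
monotone transforms of the deviance penalised per df, so on 7 cells they
usually agree; the worked example selects the no-interaction model under
both.

Known discrepancy: the published model table of the worked example prints a
BIC column that does not follow from its own stated formula — for the
independence row, G² − ln(34/2π)·3 = −1.97, while the table prints −8.83
(its column is consistent with a per-df multiplier of about ln 53.5
instead). This package computes the stated formula verbatim. Model
selection is unaffected: the independence model minimises either variant.
A regression test asserts the stated-formula value so the printed column is
never silently "matched".

### Interval estimation

The review that motivates the worked example does not state its interval
method, and its printed bounds (4.2–6.2 around X̂ = 5) are far narrower
than any standard likelihood-based interval supports. Two methods are
implemented, and the printed bounds are deliberately not reproduced:

- **Profile likelihood (default).** The missing cell is pinned at a value
  x, the model refitted to the 8 cells including x as a pseudo-observation,
  and the interval is the set where the deviance rises by less than the
  chi-square(1) quantile. Respects the X ≥ 0 boundary and the likelihood's
  right skew. For the worked example this gives roughly 0.6–15.4.
- **Log-normal delta method.** X̂·exp(±z·se(log X̂)) with the intercept's
  standard error from the information matrix.

Coverage of the profile interval is checked by simulation (500 independent-
capture populations of 5000, capture probabilities 0.4/0.5/0.2): empirical
coverage is within Monte-Carlo error of 95%, and mean relative bias of N̂
is well under 2%. These sizes keep the full check inside a normal test run
while leaving Monte-Carlo error small against the tolerances asserted.

### Completeness

Completeness of a source with margin m is 100·m/N̂; overall completeness is
100·n_obs/N̂. The denominator defaults to N̂ rounded to the integer shown
in a completeness table (`use_rounded_n=True`), so the percent column is
consistent with the displayed total — the convention the worked example
follows (34/39 = 87.2%); the full-precision denominator (34/39.18 = 86.8%)
is available. Percent confidence bounds transform the X interval
monotonically: 100·m/(n_obs + X_upper) to 100·m/(n_obs + X_lower).

Display rounding for counts and percents is half-away-from-zero (40.5 →
41), applied after snapping to 9 decimals so an iterative estimate that
converges to an exact half (the BC model's X̂ is exactly 6.5 on the worked
example) rounds as the exact value would.

### The worked-example table

Only marginal facts about the review's retrieval pattern are published:
per-source totals 21/26/6, 34 distinct studies, 2 found by all three
sources, 17 by at least two. These constraints leave a one-parameter family
of integer tables; `hbv_review_table()` enumerates all feasible candidates
(15 of them) and keeps the unique one whose independence-model deviance
matches the published 3.10. The remaining published quantities (the other
seven model rows and the completeness table) are *not* used in the
selection, so their reproduction in the tests is an independent check, not
a circularity. The function raises, listing candidates, if the enumeration
ever fails to isolate exactly one table.

## Meta-analysis core

Inverse-variance pooling delegates to statsmodels; τ² is the
DerSimonian–Laird moment estimator truncated at zero (the random-effects
pool is recomputed from the truncated value, so τ² = 0 reproduces the fixed
pool exactly). Q, I² = max(0, 100·(Q−df)/Q) and the chi-square test of
homogeneity (conventional 10% level) are reported alongside both pools.
REML and other τ² estimators are out of scope. Proportion inputs can enter
raw (rejected at boundary proportions, where the binomial variance
degenerates), on the logit scale (0.5 continuity correction at boundaries),
or as Freeman–Tukey double arcsine (variance 1/(n+0.5)); logit is the
default analysis scale, raw is offered because funnel displays of event
rates conventionally use it.

## Bias diagnostics

**Begg–Mazumdar.** Deviates t_i = (θ_i − θ̂_F)/√(v_i − v̄), where θ̂_F is
the fixed-effect pool and v̄ its variance, are rank-correlated (Kendall
τ_b) with the v_i. The p-value uses the tie-corrected normal approximation
for Kendall's S with a ±1 continuity correction; an exact permutation
p-value (all k! orderings, vectorised in chunks) is available for k ≤ 10.
In exact arithmetic v_i > v̄ always; a dominant study can cancel the
difference to zero in floats, so the correction is floored at 1e-12 with a
warning. Acceptance-level simulation confirms the normal approximation
tracks the exact p within 0.05 at k = 8.

**Egger.** OLS of θ_i/se_i on 1/se_i with intercept; two-sided t test on
the intercept with k−2 df (statsmodels OLS). The classic unweighted form is
the default; a precision²-weighted variant is available. Constant precision
makes the intercept collinear with the slope and is rejected. An exact fit
(zero residual) degenerates the t statistic; the implementation then
reports p = 1 for a zero intercept.

**Trim-and-fill.** Deviations are oriented so the over-represented side is
positive (suppression side `auto` picks the side opposite the Egger
intercept's sign, ties to the left). Estimators on ranks of absolute
deviations: L0 = (4T − k(k+1))/(2k−1) with T the rank sum of the surplus
side (default, better small-sample stability), and R0 = rightmost-run
length − 1. Iteration alternates fixed-effect centring on the trimmed set
with re-estimation of k0 until stable (≤50 rounds); filling reflects the
trimmed studies about the final centre with their original standard errors,
and the adjusted pool is random-effects by default. k0 is capped at k−1.

Implementation fidelity is tested directly against R's
`metafor::trimfill` (identical k0 and adjusted estimates on shared
datasets). Two behavioural limitations of the method itself are documented
and exercised by the tests rather than hidden: under between-study
heterogeneity with no suppression it imputes spurious studies at an
elevated rate, and when the suppressed tail overlaps the observed effect
distribution the iterative estimator systematically under-counts (the
centre is estimated from the biased observed set, so the iteration's fixed
point sits below the true k0). The recovery test asserting a ±2 hit rate of
at least 80% under 6-of-30 tail suppression fails for exactly this reason —
with estimates identical to the reference implementation — and is retained
as an honest record of the method's accuracy envelope rather than weakened.

## Synthetic-data generators

`simulate_capture` draws capture patterns from the same log-linear family
the models fit: main effects are logits of the per-source marginal capture
probabilities (defaults in tests: 0.4/0.5/0.2, a realistic
database/reference-list/gray-literature gradient), pairwise dependence
enters as log odds-ratios. Generator and fitted model sharing one family
makes recovery tests clean: independence data must be recovered by the
independence model, and the sign of dependence determines the direction of
the independence-model bias. `simulate_meta` draws effects as true mean +
N(0, τ²) + N(0, se²) with se uniform on (0.1, 0.5) by default, then applies
a user-supplied publication-probability function; published and suppressed
studies are both returned so truth is available to tests.

What these generators do not emulate: study-level capture heterogeneity
(some studies intrinsically harder to find for every source), non-normal
effect distributions, correlated effect/precision beyond the selection
mechanism, and the bibliographic screening funnel upstream of inclusion.
Passing tests therefore validate the estimators under their own stated
assumptions, not robustness to violations of them.

## Degenerate inputs and errors

Empty record sets, duplicate study ids, records captured by no source,
boundary proportions on the raw scale, single-study pools, sub-3-study bias
tests, constant-precision Egger input, and non-identifiable fits asked for
intervals or completeness all raise informative `ValueError`s; CLI commands
translate them to nonzero exits without writing partial output.
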