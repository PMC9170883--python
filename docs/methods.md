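# Methods

## Response classification

A patient's imaging response is computed from matched baseline/follow-up
measurements of the selected target lesions. Target selection keeps baseline
lesions with longest diameter ≥ 10 mm, largest first, at most two per organ
and five in total (ties broken by organ label, then lesion id, so selection
is deterministic). Greedy selection by diameter is optimal here: the
constraint set (per-organ cap intersected with a total cap) is a matroid
truncation, and the test suite checks the greedy pick against brute-force
enumeration of all admissible subsets.

Two sums are tracked per timepoint: the sum of longest diameters (SLD) of
the target lesions and the SLD of their arterially enhancing (viable)
portions. Changes are signed fractions of the baseline sum; with a single
follow-up the nadir reference for progression reduces to the baseline. If
more timepoints are ever supplied, the progression reference is the minimum
sum over all timepoints before the evaluated one.

The RECIST 1.1 cascade is evaluated in the order PD → CR → PR → SD. PD
requires both the ≥ 20 % increase over the nadir and an absolute increase of
at least 5 mm, or new lesions, or non-target progression. The mRECIST
cascade runs on the viable sums; its PD row carries only the percentage
condition (no absolute-mm clause), and CR is the disappearance of all
arterial enhancement. A patient with no enhancing tissue at baseline and
some at follow-up has an undefined viable change and is conservatively
binned SD.

All thresholds are inclusive and applied to exact fractions — a change of
exactly −0.30 is PR, an AFP change of exactly −0.76 satisfies the biomarker
rule, +0.20 with exactly 5.0 mm growth is PD. Rounding to one-decimal
percentages happens only at display time.

### Composite criteria

The composite rules are binary responder/non-responder decisions layered on
a base criterion, because their CR/SD/PD semantics are not separately
defined: base PD (including new lesions) vetoes response; otherwise
`responder = size_ok OP afp_ok` where `size_ok` is the base CR/PR flag,
`afp_ok` is either AFP_Δ ≤ −0.76 or AFP_BL ≥ 54.4 ng/ml, and OP is OR or
AND. Responders are labeled PR (CR is preserved when the base reached CR
and, under AND, the AFP condition also holds); non-responders are labeled
SD. This matches cohorts in which no CR or PD occurs while keeping the rule
total.

Two deliberate design points:

* **Baseline-AFP direction.** The αBL rules count a *high* baseline AFP
  (≥ 54.4 ng/ml) toward response, exactly as the rule is stated, even though
  high AFP is prognostically adverse. The direction is surprising but is
  implemented verbatim; the orientation is an explicit parameter of the
  cutpoint search and is never inferred from data.
* **Missing AFP.** A patient without an AFP pair is *non-evaluable* under an
  AFP composite (`None` in the API, `NE` in tables) rather than silently SD,
  so responder denominators are not biased by missingness.

Useful algebra, used as invariants: among patients not progressing under the
base criterion, responders(AND) ⊆ responders(base) ⊆ responders(OR), and
|OR| + |AND| = |base responders| + |AFP-rule satisfiers| (inclusion–
exclusion on two sets).

## Cutoff discovery

`optimal_cutpoint` performs an exhaustive maximally selected log-rank scan:
candidate cutoffs are midpoints between consecutive distinct marker values,
restricted so each induced group keeps at least ⌊min_frac·n⌋ patients
(default 10 %); every candidate split is scored by the two-group log-rank
chi-square, and the argmax is returned. Ties break toward the more balanced
split, then the smaller cutoff. Because the statistic is maximized over many
correlated splits, the naive chi-square p-value is anti-conservative; the
Miller–Siegmund approximation corrects for the scanned quantile range
(clamped to [naive p, 1], and reported as 1 when the statistic is below 1,
where the asymptotic formula is unreliable). The scan is invariant to
strictly monotone transformations of the marker up to the transformed
cutoff, and, for small n, is verified in tests against an independent
re-computation of the log-rank statistic at every split.

## Survival statistics

Kaplan–Meier estimation and Cox partial-likelihood fitting delegate to
lifelines; the log-rank observed-minus-expected statistic with
hypergeometric variance is implemented directly because the scan needs it
vectorized (one O(n log n) precomputation, then O(n) per candidate) and the
result exposes per-group observed/expected counts. Conventions: events
precede censorings at tied times; Cox uses Efron's tie correction and Wald
intervals on the log-hazard scale; if one level of the indicator has no
events (monotone likelihood) the fit warns and adds a small L2 penalty
(0.1) as a divergence guard. Median follow-up uses the reverse Kaplan–Meier
estimate (event/censor roles swapped); it is undefined without censored
observations and `None` is returned. Survival queried beyond the last
observed time returns the last estimate with an extrapolation warning.

## Agreement and concordance

Weighted Cohen's kappa uses similarity weights over the fixed order
CR < PR < SD < PD: linear `1 − |i−j|/3` by default, quadratic optional.
When only two categories occur the weighted and unweighted kappas coincide
for every scheme (both the numerator and denominator scale by the
complement of the single off-diagonal weight), so two-category agreement
values are scheme-independent; this identity is asserted numerically. The
confidence interval uses the Fleiss–Cohen–Everitt large-sample standard
error; the upper bound is not truncated at 1 by default, mirroring how such
intervals are printed in radiology agreement tables (a `truncate` flag
exists). Note that agreement tables published without the underlying
per-case ratings can be reconstructed only when the margins force the
matrix; where they do, recomputed kappas may differ slightly from printed
ones (one published two-category table reproduces 0.874 where 0.89 was
printed — the reconstruction is exact, so the difference lies upstream).

Pathologic response bins the residual-viable-tumor fraction: complete = 0,
major < 0.5, minor ≥ 0.5. Fractions strictly between 0 and 1 % are binned
major (the conventional 1–49 % description leaves them unassigned).
Response–pathology concordance uses mid-rank Spearman correlation; for
binary–binary inputs this equals the phi coefficient (tested identity). Its
interval is Fisher-z with se = 1/√(n−3) — an approximation; only the point
estimate should be compared across software.

## Synthetic cohort generator

The generator emulates the data structure of a conversion-therapy HCC
cohort so every pipeline stage is testable without patient data. Per
patient: a latent responder flag (p = 0.5); total-size change drawn from a
responder/non-responder normal mixture (means −0.35 / −0.05, sds
0.12 / 0.10); AFP change from a second mixture (means −0.85 / −0.30, sds
0.10 / 0.25); baseline AFP lognormal(μ = 5.25, σ = 1.5), calibrated so about
48.7 % of patients have AFP ≥ 200 ng/ml; baseline tumor burden
lognormal(ln 70, 0.45) mm (median 70 mm, IQR ≈ 52–95 mm), a single target
lesion for 95 % of patients. Viable diameters shrink slightly faster than
total size in responders. Change draws are clipped at −1 (nothing can lose
more than all of itself), leaving a small atom at −1.

Survival is exponential with uniform censoring over 12–60 months, chosen
for the analytic tractability of the recovery tests. The non-responder
median recurrence-free survival is 20 months (1-year non-responder survival
e^(−0.416) ≈ 0.66); responders' hazard is multiplied by 0.31. In
`step-hazard` mode the hazard reduction instead applies to patients with
AFP change ≤ −0.76 — the planted structure the cutpoint search is expected
to recover. Overall survival adds an exponential increment of mean 12
months to the recurrence time, so RFS ≤ OS always holds. Pathology fraction
is uniform(0.05, 0.95), independent of response, reflecting the near-zero
response–pathology correlation such cohorts show; no simulated patient has
a pathologic complete response. Reader pairs are simulated as truth plus
adjacent-category flips at a small probability (default 0.025).

What the generator does *not* emulate: tumor-growth kinetics, measurement
noise in diameters, informative censoring, correlation between pathology
and survival, and multi-organ lesion structure. Passing recovery tests
therefore show the estimators work under the stated generative model, not
that the clinical findings generalize.

## Problem sizes and determinism

Recovery checks run at sizes where Monte-Carlo error is small relative to
the tolerances: cutpoint recovery uses 20 cohorts of n = 600 (median
recovered cutoff within ±0.05 of −0.76), hazard-ratio recovery one cohort
of n = 2000 (±0.05 around 0.31; the per-seed sampling sd of the estimate is
≈ 0.018) plus 200 replicates of n = 300 for interval coverage. Every random
draw flows through an explicit `numpy.random.default_rng(seed)`; there is
no global random state, and identical seeds reproduce cohorts and CSV
outputs byte-for-byte.

## Known limitations

* Best-overall-response adjudication across many follow-ups is out of
  scope; criteria operate on (baseline, designated follow-up) pairs with a
  nadir reference.
* The kappa and Spearman intervals are large-sample approximations; they
  are unreliable for very small or very sparse tables.
* The Miller–Siegmund correction is asymptotic; for tiny cohorts a
  permutation approach would be preferable.
* Only two readers are supported (no Fleiss kappa), and only exponential /
  uniform-censoring survival is generated.
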