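# Methods

## The estimand

A reliability study of a hormone panel measures each of n participants at
two assessments (baseline BL, follow-up FU). Writing y_it for participant
i's value at assessment t, the working model behind both estimators is a
two-way decomposition

    y_it = μ + r_i + c_t + e_it,

with participant effects r_i ~ N(0, σ²_r), a fixed (or random) assessment
effect c_t, and residuals e_it ~ N(0, σ²_e). Test–retest reliability is the
fraction of total variance attributable to stable between-participant
differences.

### ICC(A,1)

The single-measurement, absolute-agreement intraclass correlation of
McGraw & Wong is computed from the two-way mean squares (MSR between
participants, MSC between assessments, MSE residual):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)).

"Absolute agreement" is the operative choice: a systematic shift between
assessments (MSC > MSE) counts against reliability, which is what matters
when a biomarker is to be compared across visits. The 95% interval is the
F-based procedure with Satterthwaite degrees of freedom for the
a·MSC + b·MSE mixture, evaluated at the point estimate; the p-value tests
H₀: ICC = 0 with F = MSR/MSE on (n−1, (n−1)(k−1)) df. The implementation was
verified against an independent sums-of-squares oracle (1e-10 agreement) and
against pingouin's ICC(A,1) row (estimate and p to 1e-10, interval to the
reference's printed rounding) before the tests were frozen.

Estimates are interpreted with the Koo & Li bands: poor < 0.5,
moderate [0.5, 0.75), good [0.75, 0.90], excellent > 0.90. The published
bands overlap at their edges; this package uses left-closed intervals with
0.90 still "good" because the excellent band is quoted strictly as
"> 0.90". Negative estimates — possible for this estimator — are reported
as computed (useful in simulation studies) and classified as poor.

Degenerate inputs (zero total variance) return a flagged non-numeric
estimate rather than a number; a matrix with identical columns but distinct
rows is genuine perfect agreement and returns exactly 1.0 with a [1, 1]
interval.

### Covariate-adjusted ICC

To ask how much reliability survives conditioning on lifestyle and
glycaemic state, a linear mixed model is fitted with fixed effects (fasting
glucose mmol/L, HbA1c %, total physical activity h/week, dietary habits
index points), a participant random intercept, and REML estimation. The
adjusted ICC is σ²_between / (σ²_between + σ²_residual) from its variance
components.

The REML fit is a purpose-built profiled optimiser: for a random-intercept
model, V = σ²_e (I + λ ZZ') has a closed-form block inverse, so β and σ²_e
profile out exactly and only the variance ratio λ remains, optimised on a
log scale by bounded scalar search (tolerance 1e-10, bounds e⁻²⁵…e¹⁵), with
an explicit comparison against the λ = 0 boundary; a boundary solution is
truncated to σ²_between = 0 and flagged. The fit matches statsmodels'
MixedLM to ~1e-3 on variance components (cross-checked in the test suite)
and the closed-form one-way ANOVA REML solution exactly on balanced data
without covariates. Missing covariate cells fail loudly — the analysis is
complete-case by design, no imputation.

No analytic interval for this variance ratio is trustworthy at n = 17, so
the interval is a seeded parametric bootstrap: simulate responses from the
fitted model (fixed effects + Gaussian intercepts + Gaussian residuals),
refit, take the percentile interval (default 500 replicates). The bootstrap
interval is clipped to contain the point estimate and no p-value is
attached to the adjusted estimate.

### Paired permutation test

Baseline/follow-up mean differences are tested against the within-
participant exchangeability null: swapping a participant's two labels is
equivalent to flipping the sign of their paired difference, so the null
group is the 2ⁿ sign assignments. The statistic is the difference of
assessment means. The Monte Carlo version draws iid Bernoulli(½) swaps per
participant per iteration (default 100,000) and reports the two-sided
add-one p-value (1 + #{|T_perm| ≥ |T_obs|}) / (1 + m), which guarantees
p > 0 and exact validity of the level for any m. The add-one convention is
this package's choice; an exact full-enumeration implementation (n ≤ 22)
serves as its oracle and agrees within Monte Carlo error. Ties on |T| are
counted as extreme (≥), the conservative direction.

## The synthetic cohort generator

The generator emulates the data structure of a small longitudinal panel —
17 normal-weight adults, two assessments about six months apart, four
fasting hormones plus covariates — so every downstream stage is testable
without participant-level data, which such studies rarely publish.

* **Hormone marginals are log-normal.** Published summaries are medians
  with strongly asymmetric IQRs, indicating right skew; with only three
  quantiles available, log-median and log-SD come from the method of
  quantiles: logSD = (log Q3 − log Q1) / (2 · 0.6745). Presets (pg/mL):
  ghrelin 771.92 (662.63, 898.21), leptin 5056.90 (3704.31, 8132.15), GLP-1
  168.78 (203.21, 315.32), PP 37.29 (12.49, 289.28). The GLP-1 source row
  prints a first quartile above its median — evidently a typo — so only the
  quartile pair informs its spread. Log-normality is an assumption, not a
  published fact.
* **Reliability is embedded on the log scale**: per hormone, participant
  level b_i ~ N(0, σ²_b) and residual e_it ~ N(0, σ²_e) with
  σ²_b/(σ²_b+σ²_e) = true ICC and σ²_b+σ²_e = logSD². Preset true ICCs
  mirror the reported panel: ghrelin 0.99, leptin 0.51, GLP-1 0.79, PP 0.89.
* **Covariates** get a between/within split (participant mean + occasion
  deviation) matched to the cohort's printed summaries (glucose 4.9 ± 0.66
  mmol/L, HbA1c ~5.4 %, activity ~11.5 h/week log-normal, diet index ~83 of
  127 points, weight ~67 kg); the within-participant SDs are this package's
  choice of "mostly stable across six months". Covariate effects on the
  log-hormone scale default to zero so the generated reliability equals the
  configured ICC exactly; presets can switch them on (centred covariates,
  so the marginal median is preserved). `weight_drift_sd` adds a
  between-assessment weight change; combined with a weight→leptin effect it
  reproduces the mechanism by which small weight fluctuations degrade
  leptin reliability (a tested property).
* **Censoring pathway**: values are generated uncensored and then passed
  through the assay rules (below detection → 0; above the PP ceiling →
  2276.02), the same code path real input files take, rather than truncating
  the distribution.
* **Seeding**: one master seed; each hormone and covariate draws from a
  substream keyed by a stable hash of its name, so adding a hormone to a
  config leaves the others' values bit-identical.

What the generator does **not** emulate: assay measurement error as a
separate layer (it is folded into σ²_e), duplicate-well averaging,
non-fasting visits, participant dropout, and any dependence structure
between hormones (they are simulated independently given covariates).
Passing tests therefore demonstrate correctness of the statistics under the
stated model, not robustness to violations real cohorts may show.

## Scale conventions

The pipeline's default analyses raw pg/mL concentrations (as the reference
workflow did). Estimator-recovery checks in the test suite instead estimate
the ICC of log-concentrations, because the generator defines true ICC on
the log scale and the log-normal transform changes raw-scale correlations;
`log_transform` is an explicit analysis option. Raw zeros produced by
censoring make a log analysis impossible and raise an error rather than
being fudged.

## Lifestyle indices

The dietary habits score sums per-item points over a 37-item food-frequency
list (six frequency categories from "almost daily" to "never"), with 127
points the healthy-diet maximum. The original instrument's per-item weights
are not published, so the packaged scheme is an explicit modeling choice:
16 "healthy-frequent" items (fruit, vegetables, whole grains, fish,
unsaturated fats…) worth up to 4 points and 21 "healthy-rare" items (fatty,
cured, sugary, salty foods…) worth up to 3, maxima summing to exactly 127,
monotone within each item. Any user scheme with a consistent declared total
can replace it; the loader fails on an inconsistent total. Category tokens
match case-insensitively; unknown items or categories are errors, never
silently skipped.

The physical-activity index is total hours/week over daily, leisure and
athletic activities. The MET energy index is implemented in two modes
because the source description ("hours × MET, summed, divided by the square
of body weight") conflicts with the kcal/week units of the reported tables
(the standard convention is 1 MET = 1 kcal·kg⁻¹·h⁻¹, i.e. multiply by
weight): `paper_literal` (default) returns Σ(MET·h)/kg², `standard` returns
Σ(MET·h·kg) in kcal/week. Intent is not guessed; both are exposed.

## Validation problem sizes

The study-scale checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use: 2000 null cohorts of 17 pairs with 2000
permutation iterations each for type-I error; 10⁶-iteration Monte Carlo vs
2⁸ enumeration on 20 eight-pair datasets; 50 random matrices against the
sums-of-squares oracle; 10 replicate n = 500 cohorts per reliability preset
(averaging replicates targets the estimator's expectation — a single cohort
has sampling SE ≈ 0.05 at the lowest preset); 500 replicates at n = 17 for
95% CI coverage of a true ICC of 0.8; and 100 replicates at n = 100 for the
adjusted-vs-unadjusted ICC null equivalence. These sizes make each check's
own Monte Carlo error small relative to the tolerance it asserts.

## Known limitations

* The adjusted-ICC bootstrap assumes Gaussian components; at n = 17 its
  interval is approximate and can undercover for ICCs near 1.
* ICC(A,1) assumes the two-way model; heavy raw-scale skew at small n makes
  raw-scale estimates volatile (visible in the README example), which is a
  property of the estimator, not a bug.
* The weight-change subgroup threshold has no principled default; it is a
  required config parameter when splitting.
* The diet scheme's per-item weights are a documented stand-in for an
  unpublished instrument; absolute scores are comparable only within a
  scheme.
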