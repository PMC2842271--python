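# Methods

## Intake estimation model

Per-subject fructose intake is assembled from one recall day:

1. **Decomposition.** Each recall record (subject, food, grams) is expanded
   through the food→commodity composition table; commodity mass is
   `grams × fraction`, summed over foods. Per-food fractions may sum to
   less than 1 (water and non-commodity mass), so commodity mass never
   exceeds the grams consumed times the fraction total.
2. **Fructose resolution.** A commodity's fructose fraction comes from the
   nutrient reference directly, or — when the direct value is missing — by
   scaling its carbohydrate content with the fructose-to-carbohydrate
   ratio of an explicitly linked family member. Commodities with neither
   route contribute zero and are counted in the imputation audit; partial
   nutrient coverage is a fact of commodity references, and silently
   dropping mass would hide it.
3. **Added sugars.** Commodities flagged as added caloric sweeteners are
   split by sweetener class. Corn sweeteners are an aggregate commodity:
   their free fructose is the disappearance-share-weighted average of
   HFCS-55 / HFCS-42 / corn syrup fractions (defaults 0.55/0.42/0.00 of
   sugars; shares default to 0.5/0.4/0.1 and are plain parameters — no
   single authoritative split exists, so none is claimed). Other sweetener
   profiles (honey, maple, sorghum, molasses) contribute their direct free
   fructose. Bound fructose is 50% of the sucrose mass from added sugars.
   Commodity masses are treated as dry sugar-solids mass — the composition
   tables here are synthetic, so one convention suffices.
4. **Components.** `all_added = added_unbound + added_bound`;
   `total = all_added + natural_unbound`. Percent of energy uses 4 kcal/g
   (the standard carbohydrate factor). Subjects with zero or missing
   energy get flagged NaN percentages rather than infinities.

Naturally occurring bound fructose (the fructose half of natural sucrose)
cannot be computed from these inputs. Its ceiling is estimated from cohort
means: subtract added sugars and lactose from total sugars, multiply by the
supply-side sucrose-to-total-sugar ratio, halve. A negative remainder
clamps to zero — the quantity is a bound, not a mass balance.

## Cohort preparation

- Exclusions: age outside 20–80 y, any of diabetes/cancer/heart-disease
  flags, unreliable recall. Counts per reason are reported; reasons are
  not mutually exclusive.
- Hyperuricemia: strict `>` against sex-specific cut-offs. Default scheme
  8.4/7.5 mg/dL (upper limits of the clinical normal range); sensitivity
  scheme 7/6 mg/dL. Conversion to SI uses 59.48 μmol/L per mg/dL.
- Quartiles: cutpoints are the 25th/50th/75th percentiles by linear
  interpolation between order statistics (numpy's default estimator; the
  choice is logged with the cutpoints in the output sidecar). Intervals
  are half-open on the left and closed on the right, consistent with the
  alcohol-level notation ">0–15": a value equal to a cutpoint takes the
  lower label. Quartiles are computed on the analysis cohort after
  exclusions, unweighted by default; a survey-weighted option uses
  plotting positions `(cumw − w)/(W − w_last)`, which reduce exactly to the
  unweighted estimator under equal weights.
- Fixed codings: alcohol 0 / >0–15 / >15–30 / >30 g/d; BMI <25 / 25–<30 /
  ≥30; age groups 20–30 / 31–40 / 41–50 / >50 (integer-year semantics, so
  the groups close at 30, 40, 50). Fiber is converted to density
  (g/1000 kcal) before quartiling.

## Statistical layer

- **Descriptives** are survey-weighted. Weights are renormalised to mean 1
  within each stratum; the weighted SD uses `Σw(x−m)²/(Σw−1)`, and the
  weighted median interpolates the weighted CDF — all three reduce exactly
  to their unweighted forms under equal weights (tested).
- **Mean comparisons** fit OLS of uric acid on the group factor (plus
  categorical covariates for the adjusted model). Each non-reference group
  is compared to the lowest group with many-to-one multiplicity-adjusted
  p-values computed from the joint multivariate-t distribution of the
  contrast statistics (box probabilities via quasi-Monte-Carlo with a
  fixed seed, so results are reproducible to ~1e-4; this generalises the
  classical many-to-one procedure to covariate-adjusted and unbalanced
  designs and matches `scipy.stats.dunnett` in the unadjusted case, which
  the tests verify). Adjusted group means are G-computation averages.
- **Risk models** are maximum-likelihood logistic regressions, unweighted
  by default — weighting is applied to descriptive statistics, while the
  regression models condition on the design covariates; a
  frequency-weighted option exists. The crude model contains the exposure
  only; the adjusted model has 13 explanatory variables: the exposure plus
  sex, age group, race, education, BMI category, quartiles of energy,
  protein, fat (%E), vitamin C, fiber density and caffeine, and the
  alcohol level. Lowest levels are references. CIs are Wald on the
  log-odds scale (the standard for published OR tables); the model p is
  the likelihood-ratio test of the exposure. Non-converged, separated or
  singular fits are returned flagged `unstable` (empty or NaN intervals)
  rather than raised, so a pipeline run on a small cohort completes and
  the instability is visible in the output.
- **Goodness of fit** is Hosmer–Lemeshow with g = 10 risk-decile bins and
  χ² on g−2 df. Tied predicted probabilities collapse bins with a warning
  and reduce the df. For exposure-only models the fit is saturated and the
  statistic is degenerate (p ≈ 1); the test is informative for the
  adjusted models, which is where it is reported.
- **Power** uses the two-sided normal approximation for two proportions,
  with the comparison arm's probability obtained by scaling the reference
  odds by the odds ratio. At OR = 1 the power equals α by construction.
  The "extreme-group" contrast is an interpretation: the calculation is
  exposed transparently with its inputs rather than claiming to reproduce
  any particular published power figure.

## Synthetic scenario generator

The generator emulates the statistical structure the analysis assumes, not
any real survey's file formats or vocabularies.

- **Food/commodity universe.** Six added-sugar commodities covering the
  five sweetener classes (corn sweeteners appear twice, mirroring how
  composition vocabularies name them; their profiles carry 0 direct free
  fructose since their yield comes from the share partition). Natural
  commodities draw carbohydrate from U(5, 30) g/100 g; 70% bear fructose
  at 15–50% of carbohydrate. A configurable fraction of fructose-bearing
  commodities has the direct value withheld and a family link planted, so
  ratio imputation is exercised with known truth.
- **Recalls and components.** Each subject consumes 3–8 foods with
  log-normal gram amounts; a latent "sweet diet" factor scales sweetened
  foods and feeds total sugars, yielding a configurable fructose/total-
  sugar correlation (default 0.94). Ground-truth components are computed
  from per-gram fructose rates derived with the generator's own
  arithmetic, kept deliberately independent of the estimation module — the
  agreement of the two routes (to better than 1e-9 g, tested at n = 2,000)
  is itself a verified claim, not a tautology.
- **Outcome.** Hyperuricemia status is Bernoulli from a logistic model:
  baseline log-odds `logit(prevalence_target)` (default 2.5%) plus planted
  per-level increments for total-fructose quartile, alcohol level and
  fiber-density quartile. The serum concentration is then drawn from a
  sex-specific truncated normal on the matching side of the cut-off
  (men N(6.0, 1.1), women N(4.6, 1.0)), so status and concentration are
  consistent by construction.
- **Everything else** (demographics with roughly survey-like category
  frequencies, log-normal survey weights with mean 1, 2% unreliable
  recalls, 2% per-disease flags) exists to exercise the exclusion and
  adjustment paths without claiming to describe any real population; the
  covariate joint distribution is a convenience, not a claim.

**What passing tests show — and don't.** Parameter recovery, CI coverage
(~95% over 200 replicates at n = 5,000), type-I error ≈ α and calibration
of the goodness-of-fit p-values hold under this generator's assumptions:
independent subjects, correctly specified logistic link, no measurement
error in exposures, no survey design effects. Real recall data violate
several of these (day-to-day variation, misreporting, clustered sampling),
so passing here validates the estimator machinery, not any substantive
epidemiological conclusion.

## Numerical choices

- Quantile estimator: linear interpolation (type 7); degenerate all-equal
  vectors raise rather than silently producing one quartile.
- Many-to-one p-values: QMC box probabilities with a fixed internal seed;
  reproducible to ~1e-4, clipped to [0, 1].
- Instability detection in logistic fits: non-convergence flags, |β| > 15,
  or failed Hessian inversion → `unstable=True`.
- Determinism: every random draw descends from the scenario seed through
  named `SeedSequence` spawn keys (stream 0: food universe, stream 1:
  cohort); identical configuration gives byte-identical CSV/JSON outputs,
  which the test suite checks file-by-file.
- Problem sizes in the test suite (n = 2,000 self-consistency cohorts,
  200×5,000 replicate study, 60-seed calibration runs) were chosen to keep
  Monte-Carlo error well inside the asserted bands on a single CPU.

## Known limitations

- Single-day recalls only; no usual-intake (multi-day) modelling.
- Natural bound fructose is bounded, never estimated per subject.
- Survey weights enter descriptives and rate tables only; no
  design-based variance estimation (no strata/PSU structure exists in the
  synthetic weights).
- The corn-sweetener disappearance shares are scenario parameters, not
  estimates; results involving added unbound fructose scale with them.
- Family links for imputation must be provided explicitly in the nutrient
  reference; no taxonomy is guessed.
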