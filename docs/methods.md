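# Methods

This note documents the statistical procedures implemented in `macrohier`,
the synthetic-cohort generating model and its calibration, the numerical
choices, and the limits of what the test suite can establish.

## 1. Analysis procedure

### Contrasts and design

Two case/control contrasts are analysed, each discarding the opposite tail:

* macrosomia: birth weight > 4000 g vs controls 2500–4000 g (records
  < 2500 g excluded);
* LGA: birth weight > 90th reference percentile vs 10–90th (records < 10th
  excluded).

Predictors enter through explicit codings (`PredictorSpec`): continuous
columns unchanged; categorical/dichotomous codings as treatment (dummy)
contrasts against the documented reference category. The five
socio-demographic variables that may carry missing values (interpregnancy
interval, education, financial status, residence, marital status) receive an
extra `unknown` dummy rather than losing records; missing values anywhere
else are an error. The 26 candidate codings deliberately include the same
variable under several codings (BMI as continuous, 4-category and two
dichotomies; height as continuous and two dichotomies), because the
procedure ranks *codings*, not abstract variables.

### Logistic fitting

Maximum likelihood via IRLS (Newton) with step-halving, which makes the
log-likelihood non-decreasing by construction; convergence is declared when
every score-equation component satisfies |Xᵀ(y − p̂)| ≤ 1e-8, with at most
100 iterations. The coefficient covariance is the inverse observed
information at the optimum; Wald CIs use z = 1.959964 (the exact 97.5 %
normal quantile, not 1.96). Quasi-separation — any non-intercept |β| > 15 or
any fitted probability within 1e-10 of 0 or 1 — is flagged on the result and
carried into the reports as an annotation, never silently exponentiated. The
intercept is excluded from the |β| screen because its magnitude tracks the
scale of uncentered covariates. No penalization (Firth or otherwise) is
applied. Rank deficiency is detected by QR before fitting and reported with
the offending column names.

Adjusted odds ratios control for maternal age (continuous), parity
(0/1/2/≥3) and pre-pregnancy BMI (continuous). When the tested coding is
itself a function of weight or BMI, BMI is dropped from the adjuster set —
otherwise the design would be (near-)collinear. Whether the original
analysis retained or replaced BMI in that situation is not documented; drop
is this package's choice.

### Indicators

* **AUC**: Mann–Whitney estimator (ties count ½). Variance by DeLong's
  structural components: with events i and non-events j,
  V10ᵢ = meanⱼ ψ(xᵢ, yⱼ), V01ⱼ = meanᵢ ψ, and
  Var = s²(V10)/n₁ + s²(V01)/n₀. The AUC p-value tests AUC = 0.5. Paired
  differences between nested models use the components of the difference,
  which captures the covariance exactly.
* **IDI**: difference in discrimination slope; SE = √(s₁²/n₁ + s₀²/n₀) over
  the paired risk differences within events and non-events.
* **Continuous NRI**: category-free. A subject moves "up" when the extended
  model assigns a strictly larger probability; exact ties (possible only in
  degenerate fits) count as neither direction but stay in the denominators.
  Var = [u₁+d₁−(u₁−d₁)²]/n₁ + [u₀+d₀−(u₀−d₀)²]/n₀, the asymptotic
  multinomial form. This variance choice is validated in the test suite by
  reconstructing two published confidence intervals from their printed
  reclassification proportions to ±0.005. The categorical (threshold-based)
  NRI is deliberately not implemented: the published down/up decompositions
  sum to 100 % per group, which identifies the category-free variant.

All three p-values are two-sided normal. AUC CIs are truncated to [0, 1].

### Ranking

Within each indicator, rank 1 goes to the largest estimate; exact ties get
the average of the tied positions. The final hierarchy orders by the sum of
the three ranks. Rank-sum ties break by NRI rank, then IDI, then AUC, then
label — an arbitrary but documented and deterministic rule; the AUC ranking
uses the AUC *difference* column, which orders identically to raw AUC since
the base model is shared.

### Descriptives and auxiliary formulas

Continuous variables: mean (SD)/median per group, Shapiro–Wilk normality p,
Mann–Whitney U two-sided p. Categorical: n (%) with Pearson χ² (no
continuity correction), switching to Fisher's exact test when any expected
cell is below 5 (Cochran's rule; exact test only for 2×2 — larger sparse
tables keep χ² with a log note). The minimum-sample-size helper implements
n = Z²·p(1−p)/d², truncated. With p = 0.10, d = 0.02 and the exact
z = 1.95996 this gives 864; note that a rounded Z = 1.962 would give 866 —
the quantile is therefore exposed as an overridable parameter.

## 2. Synthetic cohort generator

The generator's purpose is to emulate the statistical structure of the study
population closely enough that every pipeline stage — encoding, fitting,
indices, ranking — is exercised under realistic conditions with a known
ground truth.

### Covariates

| Covariate | Model | Default | Rationale |
|---|---|---|---|
| Maternal age (y) | normal, clipped 18–48 | mean 35, SD 4.7 | population median 35, SD from group summaries |
| Height (cm) | normal, clipped 145–195 | mean 166.7, SD 6.1 | group means/SDs |
| Pre-pregnancy BMI (kg/m²) | 3-component normal mixture | weights .750/.132/.118, means 21.9/27.5/32.5, SDs 2.2/2.0/3.0 | solved against median 22.8, P(≥25) = .297, P(≥30) = .108 — no single lognormal satisfies both tail constraints simultaneously |
| Pre-pregnancy weight (kg) | BMI·height(m)² | — | keeps weight, height and BMI mutually consistent |
| GWG (kg) | left-skewed reflected-gamma residual, location by BMI class | class medians 15.0/14.15/12.7/10.5, scale 5.6, shape 1 | heavier women gain less; calibrated to the ≈37 % above-IOM rate and a ≈59 % rate among BMI ≥ 25 |
| Gestational age (completed wk) | term normal (39.35, 1.0) + preterm gamma tail, clipped 25–42 | preterm prob .072 | P(< 37 wk) ≈ 7 %, median 39 |
| Categorical covariates | independent categorical draws | documented in `CovariateParams` | only marginals are reported; obstetric-history fields are gated on parity > 0 |

The GWG targets are mutually incompatible in a strict sense: a median of
13.8 kg, an SD near 5.7 kg and an above-IOM rate of 36.8 % cannot all hold
under any one location-scale family. The left-skewed compromise lands at
median ≈ 13.4 kg with the above rate ≈ 0.37; the above-rate was prioritised
because the GWG coding, not the raw kilograms, is what the analysis ranks.

### Birthweight model and outcomes

Birthweight is Gaussian-linear in centered covariates:

    BW = β₀ + 10·(weight−66.5) + 11·(GWG−13) + 3·(height−166.7) + 110·son
         + 130·(GA−39) − 360·max(37−GA, 0) + 60·GDM₁ + 120·GDM₂
         + 220·prior_macrosomia + 3·(age−34.8) + parity offsets + ε,
    ε ~ N(0, 310²)  (grams)

The hinge term below 37 weeks mirrors the steeper preterm fetal growth
curve and is what makes the < 2500 g fraction (~6 %) attainable by a model
that is otherwise linear. The intercept β₀ is not a free constant: it is
root-found at configuration time so that P(BW > 4000) equals the configured
target (0.106 by default), using the empirical quantile of a fixed-seed
1.5-million-draw covariate sample — deterministic, cached, and accurate to
about ±0.0005 in the realised prevalence. Macrosomia and the weight bands
are deterministic thresholds of BW, so the generator carries an explicit
ground truth for recovery experiments: the default model is dominated by
pre-pregnancy weight, matching the hierarchy the analysis is expected to
find, and `dominant_weight_config()` sharpens that dominance (weight
coefficient 20 g/kg, GWG 4, height 0, residual SD 250) for the recovery
experiment proper.

### Reference growth grid

True national percentile references are proprietary; the built-in
`ReferenceGrowthGrid` is synthetic. For each (sex, completed week) the
reference mean is the birthweight model's conditional expectation given sex
and week (other covariates marginalised via the calibration sample) and the
SD is the pooled conditional SD; LGA is BW above the normal 90th percentile
of that cell. By construction ≈10 % of generated newborns are LGA (the
study population had 10.9 %). Any grid with columns
`fetal_sex, week, mean_g, sd_g` can be supplied via CSV instead; means must
increase with week and SDs be positive.

### Missingness

Missing-at-random blanking is applied only to variables whose codings carry
an `unknown` category, default rate 0.05 on the five socio-demographic
variables (the study reports the existence of missing-data categories but
not their rates; 5 % is a conventional choice). Outcomes and the base-model
variables (age, parity) can never be blanked.

### What the generator does not emulate

Covariate correlations beyond the weight–height–BMI identity and the
GWG/obstetric-history dependencies (everything else is independent);
recruitment attrition; pregnancy-induced hypertension and preeclampsia;
longitudinal weight trajectories; gestational age in days (completed weeks
only — the source data's resolution is not documented). Passing tests on
synthetic cohorts therefore demonstrate the *procedure's* correctness and
its ability to recover a known generating structure at the study's sample
size — not the clinical validity of any particular hierarchy on real data.

## 3. Numerical and degenerate-input choices

* Exact probability ties in the NRI count as neither up nor down but remain
  in denominators; identical base and extended risks give NRI = 0.
* Zero-variance index SEs report p = 1 at estimate 0 (p = 0 otherwise)
  instead of dividing by zero.
* Empty dummy columns (unobserved categories) are dropped before fitting,
  so subset-level category absence does not create rank deficiency.
* CSV dialect: comma-separated, UTF-8, `.` decimal, empty string = missing;
  floats round-trip exactly through `str()`.
* Problem sizes in the test suite: calibration checks use 40–200 cohort
  replicates of n = 912; the hierarchy-recovery experiment uses 100
  replicates; oracle-equivalence sweeps use 200–500 random instances.
  These sizes put Monte-Carlo error well below the tested tolerances while
  keeping the whole suite around a minute.

## 4. Known limitations

* DeLong is one of several defensible AUC CI constructions; published AUC
  intervals were not reproducible from printed quantities, so only point
  estimates and the NRI intervals anchor the implementation.
* The Wald intervals degrade under sparse cells (the separation flag marks
  these rows); profile-likelihood or Firth alternatives are out of scope.
* The rank-sum aggregation weights the three indicators equally and attaches
  no uncertainty to the final positions; no test comparing ranks is
  provided.
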