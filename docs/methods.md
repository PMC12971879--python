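# Methods

`diet2gut` implements an analysis chain linking maternal gestational diet
quality to the infant gut microbiota through the maternal gut microbiota:
dietary-index scoring, compositional preprocessing of genus count tables,
univariate association screening with false-discovery-rate control, and
two-model causal mediation analysis with bootstrap inference — together with
a synthetic mother–infant cohort generator that plants a known mediation
chain so every stage can be validated end to end.

## Dietary indices

All scoring standards are externalized as editable config tables under
`diet2gut/data`; the code asserts only structural constraints (35 DII
parameters; 13 HEI components whose maxima sum to 100; a DQI rubric summing
to 100; an MMDS maximum of 10).

**DII (dietary inflammatory index).** For each of 35 dietary parameters the
intake x is standardized, z = (x − µ)/σ, mapped to a standard-normal
percentile Φ(z), centered to [−1, 1] as 2Φ(z) − 1, and weighted by the
parameter's literature-style inflammatory effect score; the DII is the sum.
Two standardization modes exist: `cohort` (default; µ, σ from the analysed
sample, population SD) and `global` (the packaged reference means/SDs, the
mode under which the published −8.87…+7.98 range arises; that range is
documented, not asserted). The packaged 35-parameter subset and reference
moments are a reconstruction: published instruments vary in which of the 45
candidate parameters an FFQ supports, so the table is labelled as such and is
fully replaceable. The percentile step uses Φ of the standard normal;
empirical-rank percentiles can be had by passing a pre-ranked table.

**MMDS (modified Mediterranean diet score, 0–10).** Six beneficial
components (vegetables, legumes, fruit/nuts, fish/seafood, cereals, and the
fat ratio (MUFA+PUFA)/SFA) score 1 strictly above the cohort median; three
reverse-coded components (meat, meat products, dairy) score 1 strictly below
it; values equal to the median score 0 in both directions — a deterministic,
conservative tie rule. Alcohol scores 1 inside a recommended range,
inclusive; the range is not standardized anywhere, so the default [5, 25]
g/day is a package convention and fully configurable. A zero-SFA subject
makes the fat ratio undefined and raises an error naming the subject.

**HEI-2015 (0–100).** Thirteen components scored on densities — amount per
1,000 kcal, a fatty-acid ratio, or percent of energy. Adequacy components
rise linearly from 0 at the minimum standard to full points at/above the
maximum standard; moderation components earn full points at/below their best
standard and 0 at/above their worst, linear between. The component standards
follow the published HEI-2015 scoring table; the mapping from foods to
component groups is config, not code, since food-group divisions are
instrument-specific.

**DQI (0–100).** A rubric of variety, adequacy, moderation and balance
components on 0–3 / 0–5 / 0–6 point scales: one point per threshold reached
(at-or-above for adequacy-like components, at-or-below for moderation-like;
balance components score the deviation from an ideal macronutrient split or
fatty-acid ratio). The packaged cut-points are a reconstruction in the
spirit of serving/nutrient-based 100-point diet-quality rubrics and are
editable CSV.

Index z-scoring uses the population SD (divisor n), documented here because
either convention appears in the literature.

## Compositional preprocessing

Counts are row-normalized to relative abundances; the **core microbiota** is
defined by abundance-occurrence: a genus is core when its relative abundance
strictly exceeds the detection threshold (default 10⁻⁵, i.e. 0.001%) in at
least the prevalence fraction of samples (default 50%). The **centered
log-ratio (CLR)** transform is applied after core filtering, over the core
genera only: y_g = log(p_g + δ) − mean over core genera of log(p + δ), with
pseudocount δ = 10⁻⁶ added to relative abundances (configurable; the
screening sign pattern on synthetic data is insensitive to δ/10 and δ×10).
No depth filter is applied before prevalence computation.

**Alpha diversity** (Observed, Chao1, Shannon, Simpson, InvSimpson, Fisher's
α) is computed on raw integer counts via scikit-bio, natural logs
throughout. Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)),
which is defined when there are no doubletons. Fisher's α solves
S = α·ln(1 + N/α) numerically.

## Association screening

Each (diet index, outcome) pair gets a univariate OLS fit
`outcome ~ 1 + index` on complete cases (exposures and diversity outcomes
z-scored, taxa CLR-transformed), with classical t-based p-values and 95%
CIs. Benjamini–Hochberg q-values are computed across one joint family of all
tests by default (a per-exposure family is available as a sensitivity
option). Screening models are unadjusted by default; a covariate argument
exists. Rows are ordered deterministically by (exposure, outcome), and both
raw (p < 0.05) and FDR (q < 0.05) significance flags are reported — the
report notes explicitly when only raw-level hits exist.

## Causal mediation analysis

For exposure X (standardized diet score), candidate mediator M (CLR maternal
taxon or maternal diversity), outcome Y (CLR infant taxon or infant
diversity) and covariates C (delivery mode, coded 0 = vaginal,
1 = caesarean):

    M = α₁ + a·X + β₂·C + ε₁
    Y = α₂ + c′·X + b·M + β₄·C + ε₂

both fit by OLS on the same complete-case rows. The indirect effect is a·b,
and the total effect c′ + a·b equals the slope of the reduced model
Y ~ 1 + X + C exactly (an algebraic identity the tests verify to 10⁻⁹).
Candidate mediators are those maternal outcomes raw-significant (p < 0.05)
for the exposure in the screen — raw rather than FDR-adjusted, since the
screen is a filter, not a confirmatory family. Each mediator is fit in its
own two-model system; multiple mediators are never entered jointly, and the
"mean direct effect across models" is the arithmetic mean of the
per-mediator c′. Mediators are ranked by |unadjusted a·b| descending, ties
broken by mediator name.

**Bootstrap inference.** Dyads (rows) are resampled jointly with replacement
(B = 1000 by default), both models refit per replicate via batched
normal-equation solves (numerically cross-checked against statsmodels in the
tests), and the indirect effect summarized by the percentile CI and the
two-tailed pseudo p-value 2·min(fraction of draws ≤ 0, fraction ≥ 0),
floored at 1/B — the standard percentile-bootstrap convention. Near-singular
resamples (e.g. a rare covariate level vanishing) are skipped and counted;
more than 10% degenerate replicates aborts with diagnostics. The exposure is
standardized once on the full sample, not re-standardized per replicate. A
constant covariate is dropped (it is collinear with the intercept), making
adjusted and unadjusted fits coincide exactly. The delta-method (Sobel)
standard error b²SE_a² + a²SE_b² is provided as an internal cross-check and
agrees with the bootstrap SD within 15% on Gaussian data at n = 1000.

Counterfactual estimands allowing exposure–mediator interaction, joint
multiple-mediator decompositions, and unmeasured-confounding sensitivity
analyses are out of scope.

## Dietary patterns

PCA runs on the z-scored index table (sample SD, so component variances sum
to the number of indices); the sign convention makes each component's
largest-magnitude loading positive, so results are reproducible. K-means
(k-means++ seeding, best of 10 starts, fixed seed) clusters the PCA scores;
the elbow k maximizes the WSS second difference WSS(k−1) − 2·WSS(k) +
WSS(k+1) over a scanned range (default 1–10), ties resolving to the smaller
k. The pipeline reports the elbow k but clusters with a configurable
override defaulting to k = 3, mirroring the common presentation of three
dietary patterns. A per-index table of the eight most positively correlated
food items supports biplot-style interpretation.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the motivating cohort: 104 dyads and a 26% caesarean fraction
by default.

* **Diet.** A standard-normal healthy-diet driver X per dyad, plus an
  inflammatory driver correlated with X at `diet_corr_target` (default
  −0.61). Intakes are lognormal around parameter-specific baselines (the
  packaged DII reference means); healthy parameters and food groups load on
  X, pro-inflammatory ones on the inflammatory driver. With
  `intake_noise_sd = 0` the intake generator is deterministic given the
  driver (the all-zero driver reproduces the baselines exactly), which the
  tests exploit. The resulting index correlations reproduce the sign
  pattern (DII negative against MMDS/HEI/DQI); only signs are asserted.
* **Microbiota.** Two-tier logistic-normal compositions: a common tier of
  abundant genera (which the core filter retains) and a rare tier near the
  detection floor (which it drops). Counts are multinomial at lognormally
  varying depths (mean 10,000 reads, a convention — real library depths are
  not emulated from any dataset). Extra structural zeros are Bernoulli
  masks whose per-genus rates concentrate on rare taxa while averaging the
  configured `zero_inflation` (default 5%): structural zeros in real genus
  tables sit overwhelmingly on rare taxa, and uniform masking would plant
  implausible hard zeros in dominant genera. `generate_taxa_counts` itself
  accepts either a scalar (uniform) rate or a per-genus vector.
* **Planted chain.** The mediator (a maternal genus, default *Coprococcus*)
  and outcome (an infant genus, default *Veillonella*) latents are solved so
  that their CLR values over the common-tier genus set equal
  α₁ + a·X + β₂·C + ε₁ and α₂ + c′·X + b·M + β₄·C + ε₂ exactly
  (unit-variance Gaussian residuals). Because the common tier is what the
  core filter recovers, fitted path coefficients are directly comparable to
  the planted truth; the only attenuation left is multinomial count noise,
  which is negligible at the default depth. Default planted values
  a = −0.66, b = −0.23, c′ = −0.67 put the indirect effect at 0.1518.

What the generator does **not** emulate: taxon–taxon ecological
interactions, longitudinal dynamics, batch effects, variable-region or
taxonomy-assignment artifacts, and realistic genus-abundance distributions
beyond the two-tier logistic-normal. Passing tests therefore demonstrate
statistical correctness of the pipeline under its model assumptions, not
biological fidelity of any particular dataset.

## Validation design and problem sizes

Tests pin every operation to an independent oracle: step-by-step DII
arithmetic, exhaustive MMDS/DQI hand scoring, closed-form CLR and diversity
values, normal-equation OLS solves, a brute-force BH step-up implementation,
and an eigendecomposition PCA oracle. Calibration suites use Monte-Carlo
replication: 200 replicate cohorts (n = 300, B = 1000 bootstrap) verify that
the mean fitted indirect effect recovers 0.1518 within Monte-Carlo error and
that the 95% percentile CI covers the truth at close to nominal rate;
500 single-path-null replicates (a = 0, b ≠ 0, n = 104) verify the pseudo-p
rejects near the nominal 5% — the single-path null is used because under the
complete null (a = b = 0) the product test is well known to be conservative,
so nominal behaviour there is not the right calibration target. The all-null
screen (25 cohorts × 244 tests) checks the raw type-I fraction against
0.05. These replicate counts keep the full validation suite around a minute
of compute while leaving Monte-Carlo error well below the tolerances tested.

## Known limitations

* Cross-sectional linear mediation: no exposure–mediator interaction, no
  causal identification beyond the model's own assumptions.
* The DII subset, DQI rubric and HEI food-group mapping are reconstructions;
  absolute index values are comparable only within a fixed configuration.
* The CLR pseudocount and core thresholds are conventions; conclusions
  should be checked for sensitivity when porting to real data.
* Percentile bootstrap CIs can undercover for strongly skewed indirect
  effects at small n; BCa intervals are not implemented.
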