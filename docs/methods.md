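# Methods

## Setting and model

The package analyses time from blood sampling to a rare hematopoietic
malignancy in a cohort of twin pairs with blood DNA methylation
(beta-values in [0,1]) measured on an array. Death before malignancy is a
competing risk; follow-up ends administratively. Two regression scales are
carried in parallel throughout:

- the **cause-specific hazard** `λ1(t|x) = λ01(t) exp(βx)` (marginal Cox,
  competing deaths censored), reported as hazard ratios `HR = exp(β)`; and
- the **subdistribution hazard** of Fine and Gray, the hazard attached to
  the cumulative incidence `F1(t|x) = 1 − exp(−Λ01(t) exp(γx))`, reported as
  `sHR = exp(γ)`.

Twins within a pair are correlated, so every marginal fit uses a
cluster-sandwich variance with the pair as cluster ("Cox frailty" in the
marginal-model-plus-robust-variance reading; no multiplicative frailty term
is estimated). All p-values in the screen are two-sided Wald tests on the
robust z.

## Synthetic cohorts

The generator produces the statistical structure the estimators assume, so
every stage is testable without registry data.

- **Pairing.** `n_pairs` complete pairs, a fraction `frac_mz` monozygotic.
  Sex is shared within MZ pairs; age at entry and data-set label are shared
  within every pair; pairs share an array plate (as in the real design),
  positions are individual.
- **Methylation.** Per CpG, a latent standard-normal trait
  `z = √icc · shared + √(1−icc) · individual` with `icc` equal to `icc_mz`
  or `icc_dz` by pair type (the A+C vs ½A+C mixing collapsed to the ICCs,
  which are what the analysis interprets). Beta-values are a clamped affine
  map `clip(μ + 0.04·z + plate + cells, 0.05, 0.95)` plus per-plate and
  per-cell-type effects; the affine scale keeps clamping rare so planted
  correlations survive. Missingness is MCAR at `missing_rate`.
- **Outcomes.** Event times follow the indirect mixture construction that
  is exactly proportional on the subdistribution scale:
  `F1(t|η) = 1 − [1 − p(1 − e^{−ρt})]^{exp(η)}`, with `η` the linear
  predictor over causal CpG latents, `p` the baseline lifetime cause-1
  probability implied by `base_rate_cause1` over the administrative window
  and `ρ` set so ~95% of the mass falls inside it. Cause-2 (death) times
  are independent exponentials; administrative censoring truncates both.
  Because the law is closed-form, counterfactual cumulative incidences at
  any horizon are available exactly, giving the ATE estimator a known
  truth. A cause-specific generator is deliberately not the default: the
  mixture law is the one under which the Fine-Gray recovery targets are
  exact. An optional pair-level outcome frailty (`pair_frailty_sd`,
  default 0) exists because the real within-pair outcome correlation is
  unknown.

Defaults mirror the motivating study's scale: 540 pairs (~1,080 twins), 93%
MZ, ~3% cause-1 events over a 15-year window, 2.7% missingness, MZ/DZ ICCs
0.34/0.17, eight plates. What the generator does **not** emulate: array
chemistry and probe types, QC failures, non-random ascertainment,
cell-composition estimation error, genomic correlation between nearby CpGs.
Passing tests therefore demonstrate estimator correctness under the assumed
dependence structure, not robustness to real-array artefacts.

## Preprocessing

Imputation (per CpG, OLS on sex, age, zygosity, data set, three cell
fractions; fitted on observed samples, imputed values clamped to [0,1])
precedes covariate adjustment, and both the screen and the predictor share
this single missing-data policy. Adjustment is a per-CpG linear mixed model
with the same fixed effects and crossed random intercepts for plate and
position, fitted by REML. Because the model is refit for hundreds of
thousands of CpGs, the solver profiles out the residual variance and
optimises the two variance ratios with Woodbury/low-rank algebra (only
m×m factorisations, m = #plates + #positions); statsmodels' MixedLM is the
cross-check oracle in the tests. Non-convergent CpGs fall back to
fixed-effects OLS with a logged warning. Residuals are divided by their
n−1 sample SD; dichotomisation maps residual ≥ 0 to "high" (the boundary
had to be fixed somewhere; zero counts as high).

"Age at entry" and "age at blood sampling" are treated as the same
quantity (study entry is defined by blood sampling).

## The screen

One CpG at a time, methylation-only models on both scales (the
residualization already removed the shared covariates), BH-FDR per scale
across CpGs, and the dual rule: FDR < 0.05 on both scales **and**
unadjusted p below a threshold on both scales. The 1e-7 default is
calibrated to genome-scale multiplicity; simulations and examples at tens
to hundreds of CpGs use a proportionally weaker threshold (1e-3 to 1e-4)
through the same configuration field. Proportional hazards is checked only
for significant CpGs (scaled Schoenfeld residuals, Grambsch-Therneau score
test, Kaplan-Meier time transform), which bounds runtime and matches how
the rule is applied in practice.

## Fine-Gray estimation

No installed Python package fits Fine-Gray, so the solver is part of the
package: subjects failing from the competing cause stay in the cause-1 risk
set with time-varying weights `G(t−)/G(T_i−)` from the overall (not
covariate-stratified) Kaplan-Meier of the censoring distribution; the
weighted Breslow partial likelihood is maximised by Newton iterations with
step-halving (tolerance 1e-10 on the step). The cluster-sandwich variance
aggregates weighted score residuals by pair and treats the estimated
censoring weights as fixed — the weight-estimation contribution of the full
Fine-Gray variance is ignored, which is slightly conservative-to-neutral at
the event counts involved and is the standard practical simplification.
With zero competing events and untied data the fit reduces to the Cox
partial likelihood exactly (tested to 1e-8 against lifelines). The Breslow
baseline cumulative subdistribution hazard feeds G-computation.

## Causal and twin analyses

**ATE risk ratios.** The fitted exposure-only Fine-Gray model supplies each
subject's counterfactual `F1(h | do(high))` and `F1(h | do(low))` at
horizon `h` (default 5 years); standardization averages these and the ratio
is reported. With an exposure-only design the averaged risks coincide with
the two model CIFs, and label-swapping maps the ratio to its reciprocal
exactly. CIs and p-values come from a percentile bootstrap resampling
**pairs** (default 500 replicates, seeded); resampling individuals would
understate the variance under twin dependence. The wording "G-estimation"
in parts of the causal-inference literature is realized here as
G-computation/standardization; structural-nested-model G-estimation is out
of scope.

**ICCs.** Double-entry Pearson correlation per zygosity (the standard in
twin methylation work; an ANOVA ICC differs negligibly at these pair
counts), Fisher-z CIs with the number of pairs (not doubled entries) as
effective n. The MZ ICC is reported as the heritability upper bound under
the polygenic variance-components model; no ACE decomposition is fitted.

**Matched case-cotwin analysis.** Pair-stratified Cox. For two-member
strata the stratified partial likelihood reduces to a closed-form softmax
over the pair at its first failure, so the package solves that small exact
problem directly (a generic stratified solver is ~4 orders of magnitude
slower at thousands of pairs and is kept only as the fallback for larger
strata; the two agree to 1e-6 in tests). The joint multi-CpG "predictor"
variant reports a global likelihood-ratio p-value, asymptotically
equivalent to the score test and exact to compute from the conditional
likelihood.

## Predictor

Candidates are the CpGs passing the dual p-rule. The LASSO-Cox path
(coordinate descent via scikit-survival's coxnet, Breslow ties) carries
zero penalty on sex and age, which are always in the model. The penalty is
chosen by 10-fold cross-validated partial-likelihood deviance
(Verweij-van Houwelingen form), folds assigned by **pair**; the default
rule takes the largest penalty within half a standard error of the
minimising deviance ("min + half SE" read as a one-sided relaxation of the
minimum — the literal reading, minimiser plus half the SE as a number on
the penalty scale, is available as `literal_min_plus_half_se`). Stability
selection repeats the whole procedure on 1,000 random half-samples drawn by
pair (replicates without events are redrawn and logged) and keeps CpGs
selected in strictly more than 80% of replicates. The final model is an
unpenalised Cox refit (selected CpGs + sex + age, pair-robust SEs) whose
linear predictor is the risk score.

Validation: pair-blocked 5-fold cross-validation pools out-of-fold risk
scores and computes Harrell's C (score ties 0.5; comparable pairs under
censoring) and the cumulative/dynamic time-varying AUC with IPCW. The AUC
convention for competing risks: subjects with a competing event before the
horizon are **controls** (they are known never to develop the event of
interest); cases weight `1/G(T−)`, event-free controls `1/G(t)`. The AUC
CI is a Hanley-McNeil normal approximation on IPCW-effective case/control
counts — adequate for curve display; the bootstrap is the fallback when a
precise interval matters. External validation refits the selected
CpGs + sex + age on the external cohort (the selection is never
re-estimated), drops model CpGs missing from the external matrix with a
logged list, and ridge-stabilises the combined refit only when the external
event count is below the parameter count (logged).

## Numerical and design choices

- Ties: Efron for marginal Cox (lifelines), Breslow inside the weighted
  Fine-Gray and penalised fits; simulated times are continuous so the
  distinction is immaterial in the tests.
- Monotone likelihoods (perfect separation) yield a flagged fit carrying
  the score-sign at zero as an infinite-coefficient marker rather than an
  exception; cross-validation replaces such coefficients by ±10 to keep the
  ranking information.
- All estimation is deterministic given inputs; every stochastic procedure
  (generator, bootstrap, folds, subsampling) takes a seed, and the pipeline
  derives per-stage seeds from one root seed. Pipeline reruns are
  byte-identical (gzip mtime pinned to zero).
- Degenerate inputs raise early with the offending CpG/row named: constant
  CpGs, fully-missing CpGs, one-armed exposures, horizons beyond follow-up,
  event codes outside {0,1,2}, misaligned sample ids.

## Problem sizes in the shipped runs

The test suite and the reproduction script run at "desk scale", chosen as
the sizes at which each statistical claim is sharp: oracle equivalences on
2–200 subjects; calibration at 500 replicates (n = 50–300); parameter
recovery at 2,500 pairs (sHR bias), n = 5,000 (ATE), 200 replicates of 120
pairs (ICC coverage); stability selection at 2,000 pairs × 20 CpGs × 100
replicates; the end-to-end pipeline at 540 pairs × 300 CpGs. The
genome-scale thresholds and the 1,000-replicate stability default remain
the package defaults.

## Known limitations

- The Fine-Gray sandwich ignores the censoring-weight estimation term.
- The AUC confidence band is approximate (see above).
- The generator's marginal subdistribution law is not simultaneously a
  conditional-per-pair proportional hazards law; matched-analysis recovery
  is therefore tested under a cause-specific conditional generator built in
  the tests.
- No left truncation, time-varying covariates or effects; malignancies
  diagnosed before sampling are simply non-cases, by design.
- Heritability statements are bounds from ICCs, not variance-component
  estimates.
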