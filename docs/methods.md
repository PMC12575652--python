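# Methods

`multipgs` implements a three-step workflow for testing whether a
composite of many published polygenic scores (a *multiple polygenic
score*, MPS) improves colorectal-cancer (CRC) risk discrimination beyond
CRC-specific scores. This note records the statistical model, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
to know.

## The workflow

**Step 1 — selection.** Candidate scores come as PGS-Catalog-dialect
weight files. An exclusion cascade removes, in order: scores with zero
variant overlap with the genotype panel; scores with more than 20% of
their variants unavailable (strictly: overlap < 0.80 — a score with
exactly 80% present is kept); scores for CRC, colon or rectal cancer; and
scores for two broader traits (gastrointestinal cancer, rectal/anal
cancer) whose case sets subsume many CRC cases. Scores for precursor
lesions (benign colon neoplasms, rectal polyps) are deliberately
retained. Each surviving score is computed as the weighted sum of
effect-allele dosages over its matched variants and standardized to mean
0, SD 1 on the full selection cohort. An elastic-net-penalized logistic
regression of case status (CRC or advanced adenoma) on all scores — with
age, sex and genotyping platform unpenalized — is tuned over an
(α, λ) grid by stratified 10-fold cross-validation maximizing the
confounder-adjusted AUC of the held-out *score-only* linear predictor.
The nonzero coefficients of the full-data refit define the composite:
MPS = Σₖ βₖ · PRSₖ, standardized.

**Step 2 — risk models.** On an independent evaluation cohort, split
50/50 into training and validation halves, six logistic models are fit on
the training half: each subset of the two CRC scores (known-loci and
genome-wide), with and without the MPS, always adjusted for age and sex.
Odds ratios are per SD of the training-standardized score, with Wald 95%
intervals.

**Step 3 — validation.** On the validation half, each model's score-only
linear predictor is evaluated by confounder-adjusted AUC with bootstrap
SE and percentile 95% CI (1,000 replicates by default), and the three
nested pairs (model 4 vs 1, 5 vs 2, 6 vs 3) are compared by a *paired*
bootstrap: the same resample feeds both models in every replicate, the
replicate SD estimates the SE of the AUC difference, and z = Δ/SE gives a
two-sided normal p-value.

## The confounder-adjusted AUC

The adjusted AUC is a weighted Mann–Whitney statistic in which each case
receives a weight that matches the case confounder distribution to the
control distribution, so the score is credited only for discrimination
beyond age, sex and platform:

    AUC_w = Σ_{i∈cases} Σ_{j∈controls} w_i (1[s_i > s_j] + ½·1[s_i = s_j])
            / (Σ w_i · n_controls)

Two weight engines exist. The `strata` engine uses exact frequency
ratios, w_i = (control share of i's stratum) / (case share of i's
stratum), and requires categorical confounders (age is binned by decade);
cases in strata with no controls get weight 0 with a warning. The
`model` engine fits a main-effects logistic of the label on the
confounders and uses inverse-odds weights, allowing continuous age. Both
normalize the weights to mean 1 over cases. `strata` is exactly testable
by brute force and is the default throughout; `model` is preferable when
continuous confounders should not be binned. Ties contribute ½ (standard
Mann–Whitney convention). The weighted statistic is computed by binary
search against the sorted control scores, which is contract-equal to the
O(n₁·n₀) double loop (asserted to 1e-12 in the tests).

Bootstrap resampling is unstratified over individuals; a replicate that
loses a class is redrawn (the count is logged). Adjustment weights are
recomputed inside every replicate. CIs are percentile CIs; the z-test
uses the bootstrap SE. Everything is deterministic given (seed, n_boot,
data order).

## The penalized solver

The selection objective is

    (1/n) Σ_i [log(1 + e^{η_i}) − y_i η_i]
      + λ Σ_{j∈scores} [α|β_j| + (1−α) β_j²/2]

with the intercept and covariates carrying zero penalty. The solver is
cyclic coordinate descent on the IRLS quadratic approximation
(glmnet-style), with IRLS weights floored at 1e-5, warm starts along a
descending λ path, and convergence declared when the objective changes by
≤1e-10 (relative); non-convergence raises with the objective trace, and
|β| > 30 on the standardized scale triggers a separation warning. The
contract is the objective, not the algorithm: the tests pin the solution
against independent BFGS minimization of the same objective at λ=0
(tolerance 1e-5), at a ridge point (1e-5), and against the covariate-only
maximum-likelihood fit at λ=10⁶ (1e-6).

The default grid is α ∈ {0, 0.25, 0.5, 0.75, 1} and 50 log-spaced λ from
λ_max down to 10⁻⁴·λ_max, where λ_max = max_j |(1/n)·x_jᵀ(y − p̂)| at the
covariate-only fit — the smallest λ that zeroes every score coefficient
at α = 1 (for α < 1 the same path is reused, so fully-sparse solutions
are only guaranteed at the lasso end). Ties in mean CV AUC prefer larger
λ, then larger α (sparser models).

**Known behaviour: CV-argmax overselects.** Because the mean CV adjusted
AUC is nearly flat in λ once the informative scores have entered, the
strict argmax often lands at λ values that admit small-coefficient noise
scores. At the default simulation scale, truly pleiotropic trait scores
are selected essentially always, but pure-noise trait scores enter
roughly 20–50% of runs (with coefficients near zero). This is the
well-known overselection of CV-minimum tuning that motivates 1-SE rules;
the package keeps the plain argmax (with the sparsity tie-break) as its
contract, and the guarantee established by the tests is the *contrast*
between signal and noise selection rates, not a hard noise-exclusion
rate.

## Cross-validation scoring

Held-out folds are scored with the score-only linear predictor
Σ_j β_j·PRS_j; age, sex and platform enter the adjusted AUC as
confounders rather than the score. Rationale: the adjusted AUC exists
precisely to attribute performance to the scores alone — adding covariate
effects to the score would re-introduce them. Folds are label-stratified
with a seeded shuffle, so no fold can lose a class as long as each class
has at least n_folds members.

## Standardization and leakage

Scores are standardized per cohort ("based on the overall sample mean" of
that cohort); within the evaluation cohort, moments estimated on the
training half are applied unchanged to the validation half, and the
MPS combination is likewise standardized with training-half moments. No
validation-split quantity flows into fitting. The SD convention is the
sample SD (n−1 denominator) throughout; recorded moments travel with the
`ScoreMatrix` so the identical affine transform can be replayed.

## Variant matching

The matching key is chromosome:position plus the alphabetically sorted
allele pair, so a scoring file written in the opposite ref/alt
orientation still matches; orientation is resolved at scoring time
(effect allele = panel alt → dosage used as-is; effect allele = panel
ref → dosage reflected to 2−d). A position carrying a different allele
pair is unmatched and logged. Strand-ambiguous pairs (A/T, C/G) are
scored as matched by default — the simulator never creates strand flips —
with a `drop_ambiguous` option for real data. Individual-level missing
dosages at matched variants are imputed with the variant's sample-mean
dosage, the standard scoring convention (it preserves score means; with
no missingness it is a no-op).

## The synthetic cohort generator

The generator produces the statistical structure the workflow assumes,
at desk scale, with exact bookkeeping:

- **Genotypes**: independent biallelic variants in Hardy–Weinberg
  equilibrium, MAF ~ Uniform(0.05, 0.5), dosage ~ Binomial(2, MAF).
  There is deliberately **no linkage disequilibrium**: LD is irrelevant
  to the pipeline's contracts and its absence keeps the oracles exact.
- **Liability**: a sparse causal architecture (100 causal variants of
  1,000) with Gaussian effects scaled so the centred genetic value has
  variance h² = 0.3 — within published common-variant heritability
  estimates for CRC — plus standardized-age and sex effects (0.3 and 0.2
  on the liability scale) and N(0, 1−h²) noise. Status is assigned by
  empirical liability quantiles: top 5% CRC, next 10% advanced adenoma,
  rest controls. Advanced adenoma is thus modelled as a lower band of the
  *same* liability — consistent with treating it as a precursor lesion on
  one risk axis; no separate adenoma biology is modelled.
- **Pleiotropy**: each secondary trait's causal set overlaps the CRC
  causal set by a configurable fraction (default: 3 of 10 traits share
  50%), reusing the CRC effect sizes on the shared variants. This — not
  any direct trait-outcome effect — is what makes non-CRC scores
  informative.
- **Published weights**: true causal weights plus N(0, (2·SD(weights))²)
  noise. The noise level was calibrated once, at design time, so the
  noisy published CRC score attains a confounder-adjusted AUC near 0.60 —
  the operating point reported for known-loci CRC scores in the
  literature this package's workflow targets; the noiseless true weights
  stand in for a stronger genome-wide score (reported around 0.63). Ages
  are N(65, 10²) truncated to [40, 90]; sex is balanced; platform has
  three uniform categories.

What a green test therefore establishes: that the pipeline recovers
pleiotropic signal and that its inference is calibrated *under linkage
equilibrium, correct liability-threshold structure, and additive weight
noise*. It says nothing about LD leakage between scores, ancestry
structure, genotyping batch effects, or non-additive disease biology.

All generators are bit-reproducible from (config, seed), with independent
RNG substreams per stage; a `replicate` index draws independent cohorts
(e.g. selection vs evaluation) from the same variant universe and causal
truth.

The 2,724-entry catalog fixture used for the filter worked example has
five mutually exclusive strata by construction — 9 entries with zero
overlap, 485 with overlap in [0.5, 0.8), 40 full-overlap entries with
CRC-type trait labels, 3 with the broader labels, 2,187 passing — so the
cascade's counts are structural, not statistical; a variant with
overlapping strata exists to exercise the first-applicable-reason rule.

## Numerical and design choices

- Weighted AUC via sorted-control binary search, O((n₀+n₁) log n₀).
- Percentile bootstrap CIs; z-test on bootstrap SE; SE = 0 with Δ = 0
  gives p = 1, SE = 0 with Δ ≠ 0 gives p = 0 plus a degeneracy warning.
- Wald (not profile-likelihood) CIs in the risk models; sex coded as a
  male indicator, age centred at the sample mean (affects covariate rows
  only, never the per-SD score odds ratios); platform is a step-1
  covariate but not a step-2 covariate.
- `split_cohort`: seeded permutation, first ⌊fraction·n⌋ to training.
- Zero-variance score columns are an error naming the score; a fully
  missing dosage column is imputed as dosage 0.
- The pipeline's selection step always uses the broad endpoint (CRC or
  advanced adenoma); the endpoint setting governs steps 2–3.
- The catalog filter takes a single variant index; to reproduce a
  multi-panel rule (overlap against several datasets at once), intersect
  the panels' indexes before calling.

## Known limitations

- No LD-aware scoring, no genome-build liftover, no imputation of
  untyped variants, no ancestry structure.
- The strata weight engine needs pre-binned confounders and drops cases
  in control-free strata; with many strata and few controls this can
  discard information (the model engine avoids this).
- Elastic-net tuning targets discrimination, not support recovery; see
  the overselection note above.
- Desk-scale validation halves (thousands of individuals) make AUC gains
  below ~0.01 hard to distinguish from zero; the simulator's default
  effect sizes are chosen so true gains are detectable at that scale.
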