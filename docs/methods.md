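# Methods

This note documents the statistical models implemented in `woundage`, the
design of the synthetic-data generator, the numerical conventions, and the
limitations of what the test suite can demonstrate.

## Problem setting

Skeletal-muscle contusion triggers inflammation, tissue degradation and
repair, each with its own metabolic signature. Sampling contused muscle at
4-hour intervals from 4 h to 48 h post-injury (plus uninjured controls,
n = 9 per group, 117 study samples) yields peak-area profiles whose temporal
structure falls into three phases — early (4–12 h), intermediate (16–32 h)
and late (36–48 h) — with weaker sub-structure inside each phase. The
analysis screens differential metabolites against control, then trains a
two-level classifier that first assigns the phase and then one of seven
wound-age windows: 4, 8, 12, 16–20, 24–32, 36–40, 44–48 h.

## Reference panel and mass arithmetic

The packaged panel lists 43 differential metabolites with molecular formula,
measured neutral monoisotopic mass, mass error (ppm), retention time and
database identifiers (40 of 43 carry HMDB IDs). The tabulated mass column is
the **neutral monoisotopic mass** — it matches the formula masses (e.g.
valine C5H11NO2 at 117.0789 Da), not a protonated-ion m/z — and the fixture
documentation records this. Theoretical masses are computed from IUPAC 2021
monoisotopic atomic masses hard-coded at ≥ 6 decimal places; the formula
grammar is element symbol + optional integer count (no parentheses, isotopes
or charges — none occur in the panel). Two m/z values appear twice in the
panel (320.2354 for two HETE isomers; 392.2933 for two bile acids); the rows
are kept verbatim, without deduplication. All 43 entries agree with their
formula masses within 1.7 ppm; the tests allow 5 ppm to absorb the 4-decimal
rounding of the printed masses.

## Synthetic-data generator

Peak areas are **log-normal**: area = exp(μ(metabolite, group) + ε),
ε ~ N(0, `within_sd`). Peak areas are positive and heavy-tailed, and
multiplicative noise is the standard assumption; the generator makes it
explicit.

The group mean μ decomposes as

```
μ = baseline + effect_scale · (phase_gap · L[archetype][phase] + within-phase offset)
```

- Each panel metabolite follows one of four **trajectory archetypes** —
  early-peak, mid-peak, late-rise, monotone-fall — cycled by panel position,
  so every phase contrast has informative features in both directions.
  Archetype phase levels are fixed constants with a minimum between-phase gap
  of 0.35; the maximum within-phase spread is 0.5, so between-phase contrasts
  dominate whenever `phase_gap` > ≈1.4 (default 3).
- The **within-phase offset** ramps linearly across a phase with amplitude
  0.5 and archetype-dependent sign, and each metabolite carries it in **one
  phase only** (cycled by panel position). This is a deliberate design
  choice: fine temporal detail for different phases lives in different
  metabolites, so a phase-specific second-level panel and projection genuinely
  add information over one global 2-D reduction — the regime in which a
  tandem architecture is the right tool. With the within-phase ramp present
  in all metabolites at once, a single 2-D supervised projection separates
  all seven windows and flat models match the tandem.
- **Background features** (default 500) are label-independent log-normal
  draws around per-feature baselines fixed by the seed; they give the
  VIP+FDR screen a true-negative set.
- **QC rows** are the study grand-mean area vector with multiplicative noise
  of SD `within_sd`/4 (corrected by exp(σ²/2) so the expectation is exact),
  emulating pooled quality-control injections.
- **External samples** draw their time labels uniformly over the configured
  time points (the emulated test animals' time distribution is unknown);
  labels are returned only in an answer key.

Defaults: `effect_scale = 1.0`, `within_sd = 0.25` (log units),
`phase_gap = 3.0`, `n_background = 500`, `qc_count = 12`, baseline log-area
10 (areas ≈ 2×10⁴). `effect_scale` and `within_sd` were chosen once so that
the control/contused OPLS-DA is clearly separated but cross-validated Q² is
far from 1 — qualitatively the regime of real contusion data — and are not
tuned per experiment. All randomness flows from the config seed through
independent named streams (study noise, QC noise, external draws, feature
baselines), so tables are bit-reproducible and study/QC/external tables from
one config share feature-level parameters.

What the generator does **not** emulate: retention-time drift, batch effects,
missing values, heteroscedastic (intensity-dependent) noise, correlated
metabolite modules, or any real biochemical pathway structure. Passing tests
therefore demonstrate the pipeline's statistical behaviour under its own
assumptions, not performance on real instrument data.

## Preprocessing and PLS-DR

Pipeline order is fixed and leakage-safe: optional total-area normalization
(whole cohort, before any split) → train/validation split → Z-score fitted on
training rows → PLS-DR fitted on training rows → held-out rows transformed
with training parameters. Normalization rescales each sample to the cohort
median total area (the most common metabolomics convention); it is off by
default for synthetic data, which has no injection-loading artefact. Z-scores
use the population (1/n) SD. The ML pipeline operates on natural-log areas,
consistent with the log-normal noise model and with the Welch tests in the
screen. PLS-DR is the first two x-scores of a NIPALS PLS2 fit to the one-hot
class matrix; whether the original analysis fitted it before or after
splitting is not documented, so this implementation fits on the training
rows only (the leakage-safe reading) and records the choice here.

## Chemometrics

- **NIPALS PLS2** with X-deflation; convergence tolerance 1e-12, ≤ 1000
  iterations per component; the score starting vector is the Y column with
  the largest remaining variance. With A = rank(X) the fitted values equal
  the least-squares fit; this is an oracle test.
- **OPLS-DA**: per orthogonal component, the first predictive loading is
  stripped of its projection onto the (orthonormalized) PLS weight space,
  normalized to an orthogonal weight w_o, and the component t_o p_oᵀ is
  deflated from X; the predictive PLS model is then refitted on the filtered
  matrix. With `a_orth = 0` this reduces exactly to NIPALS PLS (tested to
  1e-8 on random matrices). Defaults: `a_pred` = n_classes − 1,
  `a_orth` = 1; columns are unit-variance scaled (population SD) unless
  `scale=False`. Predictive scores are mutually orthogonal and orthogonal to
  the filtered components (structural property of the deflation).
- **VIP** is computed over the predictive components only
  (VIP_j = √(p·Σ_a SS_a w_ja²/Σ_a SS_a), SS_a = (t_aᵀt_a)(c_aᵀc_a));
  mean(VIP²) = 1 exactly because weight vectors are unit-norm.
- **Q²** uses stratified 7-fold cross-validation (seeded); each fold refits
  the OPLS model, including its scaling, from the training part. A class
  smaller than the fold count is an error suggesting fewer folds.
- **CV-ANOVA**: F = ((SS_tot − PRESS)/df_model)/(PRESS/df_resid) with
  df_model = number of model components (predictive + orthogonal) and
  df_resid = N − 1 − df_model, pooled over the one-hot columns; p = 1 when
  cross-validation does not beat the mean. This is one rendering of the
  CV-ANOVA construction; published variants differ in df bookkeeping, and
  only the resulting p-value is used downstream.
- **Permutation test**: labels shuffled n_perm times; each permutation refits
  the model and its cross-validated Q², recording the correlation between
  permuted and original one-hot matrices.

## Screening

P-values come from two-sided **Welch t-tests on log areas** (the univariate
test in the original workflow is unstated; Welch on log intensities is the
default for continuous metabolomics data, and the choice is a config
switch). Zero-variance features with equal means get p = 1 (a copied-rows
comparison should not be significant). Benjamini–Hochberg adjustment is
applied across all features **within one comparison**, via statsmodels. VIP
comes from a two-class OPLS-DA (pooled case group vs control). Selection is
the conjunction VIP > 1 ∧ q < 0.05. Panel assembly mirrors the two-level
architecture: the union of per-phase screens forms the level-1 panel; each
level-2 node re-screens its phase's samples against control restricted to
the union, so node panels are subsets of the union. Screens only ever see
study rows.

## Tandem classifier

Candidate learners and hyperparameters are fixed: LR (lbfgs), SVM (C = 1.5;
kernel unstated in the source workflow, RBF chosen as the scikit-learn
default, switchable to linear), RF (128 trees), MLP ((32, 32) hidden layers,
Adam, adaptive learning rate, ≤ 3000 iterations). Each node standardizes its
panel, reduces to 2-D with PLS-DR, trains all four candidates on the same
coordinates and keeps the best by validation accuracy on a stratified 70/30
split (per class, round(0.7·n) training rows, at least 1 and never all).
Ties go to the later learner in LR < SVM < RF < MLP order, favouring the
deeper model. Control samples inform screening only and are excluded from
classifier training and validation. Each level-2 node splits **its own**
samples 70/30 (whether the original workflow re-split within groups is
undocumented; splitting within each node keeps validation honest at both
levels). A coarse group with a single leaf becomes a passthrough node, as
does level 1 under a single-group scheme. Routing consistency — the
predicted window always lies in the predicted phase — is structural: each
level-2 node only knows its own leaves.

Model selection uses validation accuracy only; macro one-vs-rest AUC (from
predicted probabilities, or decision values for the SVM) is computed
descriptively. Flat baselines train the same four learners as single-stage
seven-class models on the union panel with the same split seed, so
tandem-vs-flat comparisons isolate the architecture.

## Evaluation conventions

Internal validation re-predicts all 108 contused study samples (the
procedure the original workflow reports; note that 70% of them were training
samples, so internal accuracy is an optimistic estimate — under a
no-signal generator it sits well above chance because flexible learners
memorize noise, which is why the null-calibration tests use held-out
accuracy instead). External validation predicts freshly generated samples
against the answer key. Chance level for the 7 windows is not 1/7: the
windows are unbalanced (9, 9, 9, 18, 27, 18, 18 of 108), so the ceiling for
a label-independent classifier is the majority-window prior 0.25; null tests
use 0.25 + 3·√(0.25·0.75/n). Multiclass AUC is macro-averaged one-vs-rest
(the averaging method behind the source workflow's single AUC per algorithm
is unstated). Decision regions and predicted-vs-actual counts are exported
as CSV rather than rendered figures.

## Problem sizes and determinism

Default experiments use 543 features (43 panel + 500 background) × 117
study samples; tests use 60–150 background features where the statistical
structure is unchanged. The tandem-vs-flat benchmark uses 10 seeds with
shared panels and splits. Every stochastic step (generator, splits, fold
assignment, permutations, classifier seeds) derives from explicit seeds;
fixed seeds reproduce tables, models and predictions exactly.

## Known limitations

- OPLS component counts are fixed defaults, not auto-selected; R²Y/Q² values
  are therefore not comparable to software that chooses component counts by
  cross-validation.
- The CV-ANOVA degrees of freedom are one defensible convention among
  several; treat its p-value as a screening diagnostic.
- The generator's independence assumptions (no feature correlation beyond
  group structure) make screening easier than on real data, where correlated
  features inflate VIP ties.
- The external-validation difficulty is a generator choice
  (`sd_multiplier`), so external accuracies characterize the pipeline, not
  any real assay.
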