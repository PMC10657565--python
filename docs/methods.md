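# Methods

## Overview

`kinostate` implements an end-to-end analysis linking single-dose kinome
profiling of kinase inhibitors to cancer cell line drug sensitivity. The
pipeline (i) integrates two profiling assay dialects into a dense drug ×
kinase "kinome inhibition state" matrix, (ii) summarizes raw plate viability
titrations into dose-response AUC and IC50 via a four-parameter log-logistic
fit, (iii) ranks every candidate feature (kinome states + baseline gene
expression) by bivariate correlation with sensitivity, (iv) compares LASSO,
random-forest and gradient-boosting regressors over incremental feature-count
cutoffs under random 10-fold cross-validation, and (v) explains the winning
model with exact tree-Shapley attributions. A synthetic-data module generates
format-identical inputs with a planted causal signal so the whole chain can be
validated for signal recovery.

## Assay integration

Kinobead-style competition/MS profiling reports relative intensity (fraction
of control, non-negative, occasionally above 1 through quantification
artifacts); KINOMEscan-style profiling reports "Percent Control" on a 0–100
scale. The integration order is fixed:

1. drop assays of recombinantly mutated kinase constructs;
2. divide Percent Control by 100;
3. truncate kinobead outliers at the 99.99th percentile of kinobead values
   (linear-interpolation percentile between order statistics — the convention
   matters at this extreme quantile, so it is fixed and tested against a
   sort-and-interpolate oracle);
4. merge: within-dialect replicate measurements are mean-merged, then
   overlapping drug–kinase pairs across dialects are mean-merged;
5. impute every unmeasured pair with the no-interaction value 1.

Truncation precedes merging because the cap must reflect only kinobead
relative intensities, and imputation follows matrix assembly so the imputed
value never enters the percentile. Re-truncating already-truncated data is
the identity whenever the percentile position lands on an order statistic;
at generic positions it can only tighten the cap within the top
order-statistic gap (documented limitation of the interpolated-percentile
convention).

Cross-assay concordance is quantified on drug–kinase pairs measured by both
dialects, two ways: raw-value Pearson correlation, and agreement of binary
"strong hit" calls at ≥80% inhibition (value ≤ 0.2). Because most shared
pairs are non-interactions in both assays, hit-call agreement is structurally
much higher than the raw-value correlation.

## Dose-response summarization

Per (drug, cell line) plate row, replicate readings are averaged per dose and
normalized to the mean DMSO-only control reading; rows where any normalized
viability reaches 120% of DMSO are excluded (quality-control rule for
growth-stimulation or normalization artifacts).

The four-parameter log-logistic model

    v(d) = lower + (upper − lower) / (1 + 10^{hill·(log10 d − log10 IC50)})

is fitted by bounded least squares (`scipy.optimize.least_squares`, TRF) with
five deterministic starts placing the initial IC50 at the log-dose-range
quantiles {0, 0.25, 0.5, 0.75, 1}. Bounds: lower ∈ [−0.2, 1.2], upper ∈
[0.5, 1.3], hill ∈ [0.2, 10], log10 IC50 within ±2 decades of the tested
range. If no start converges the best-effort parameters are returned flagged.

Two summaries are extracted:

* **AUC** — the mean of v over log10-dose across the tested range, by
  adaptive quadrature; a flat curve at viability c scores exactly c, and
  normalizing by the log-range makes values comparable across dose grids.
* **IC50** — the *absolute* half-viability crossing (v = 0.5), in closed form
  from the fitted parameters. Curves never reaching half viability are capped
  at the highest tested dose; curves already below half viability at the
  lowest dose are capped at the lowest dose (reporting the highest dose for
  the most potent curves would invert the potency scale). Both caps carry an
  explicit flag rather than a sentinel value, and capped log10 IC50 values are
  retained in modeling with their flag. The relative (asymptote-midpoint)
  IC50 definition is a known alternative; the absolute definition matches the
  cap-at-range behavior needed for non-responsive curves.

## Feature ranking and selection

Each feature column — kinome states (`act_` prefix) and expression (`exp_`
prefix; the prefixes keep same-named kinases and genes distinct) — is
correlated with the outcome over all drug × cell-line rows (Pearson, with
Spearman reported alongside; two-sided p-values from the exact t reference
distribution). Features are ranked by decreasing |Pearson r|; zero-variance
features get r = 0 and rank last; ties break by ascending feature id for
cross-platform determinism. Note the deliberate sample-structure imbalance:
a drug's kinome state repeats across its cell lines and a cell line's
expression repeats across drugs, so these bivariate screens are descriptive,
not inferential — significance is reported but never used as a filter.  An
optional ``collapse_by_drug`` mode averages each drug's rows first, removing
the repetition at the cost of the cell-line axis; it is off by default to
match the standard full-table protocol.

By default the ranking is recomputed inside each CV fold on training rows
only, so held-out outcomes never influence feature selection; a
`rank_per_fold=False` mode reproduces the simpler protocol of ranking once on
the full table.

## Model comparison

One design-matrix row per screened (drug, cell line) pair: the drug's kinome
state block concatenated with the cell line's expression block. Outcomes
(AUC, log10 IC50) are modeled separately. Random 10-fold CV at the row level
(pairs sharing a drug or cell line may co-occur across folds, exactly as in a
random split of the screen); per fold, features are ranked and the top-k
selected, the model fitted, held-out rows scored by the coefficient of
determination R² = 1 − SSres/SStot (the squared-Pearson reading of
"R² between predicted and actual" is also available) and RMSE.

Hyperparameter search draws a fixed number of random configurations per
family within documented ranges: LASSO penalty ∈ [1e−10, 0.9] (log-uniform —
the range spans nine decades), random-forest trees ∈ [100, 2000], XGBoost
trees ∈ [100, 1000] and depth ∈ [4, 30] (uniform on integers). Engines:
scikit-learn `Lasso` on train-standardized features; LightGBM in
random-forest mode (bootstrap-style bagging fraction 0.632, per-tree feature
subsampling mtry = √p, minimum node size 5 — the conventions of the classical
RF engines); XGBoost with histogram trees (max_bin 64) and otherwise library
defaults. All fits are single-threaded and seeded, so the whole comparison is
deterministic. Because a random forest with t trees is exactly the average of
the first t trees of a longer forest, tree-count tuning fits one maximal
forest per fold and derives each configuration's predictions from its leading
trees — identical estimator, ~10× less compute.

The winning specification (maximal mean CV R²) is refitted on the full table
and used to predict every requested drug × cell-line pair; pairs lacking
features are returned in an exclusions report, and training pairs are flagged
in the prediction grid.

## Model explanation

Per-row, per-feature attributions use the exact TreeSHAP algorithm built into
XGBoost (`pred_contribs`) and LightGBM (`pred_contrib`), satisfying local
accuracy (base value + Σ attributions = prediction) by construction.
Attributions are computed on a seeded subsample of at most 2,000 rows;
importance is the mean |attribution| per feature, split by feature class,
with optional join against a user-supplied annotation table (understudied
"dark" kinase flags, kinase-interactor flags). For the linear LASSO
comparison model the importance analog is |standardized coefficient|.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at a
desk scale chosen to keep the full validation suite fast:

* **Scale** (defaults): 400 kinases, 2,000 genes, 40 cell lines; 35 drugs per
  assay dialect with 10 profiled in both (60 unique); kinase panels overlap by
  30% (matching the roughly one-third panel overlap of the real assay pair);
  62% of the drug × cell-line grid is screened (the real repurposing screen
  covers ~60% of its matched grid), leaving untested pairs for the prediction
  stage.
* **Profiles**: 35% of drugs are inert with respect to the planted drivers
  (inactive compounds anchor the potency axis, as in any real screen); active
  drugs receive 2–4 driver hits dealt from a reshuffled deck so every driver
  is covered by a comparable number of drugs without additively saturating
  the latent link, plus 1–3 strong off-targets and 8–16 weak partial
  engagements (values U(0.35, 0.9)) drawn from a shared promiscuity pool of
  ~n_kinases/4 kinases — conserved-ATP-pocket promiscuity means no single
  off-target uniquely fingerprints one compound.  Strong target inhibition
  states are ~U(0, 0.25); everything else sits at the no-interaction value 1.
  Reporting is sparse, as in real competition assays: engaged pairs are
  reported unless lost to the 25% per-dialect missingness; non-interacting
  pairs are reported only 10% of the time, *at the run's shared
  normalization bias* (control-level readings move together within a run and
  therefore cannot act as per-kinase drug fingerprints), and everything
  absent is later imputed to exactly 1.  Read noise is two-tier — sd 0.06 on
  strong engagement, sd 0.5 on weak engagement — because the two assay
  chemistries agree on strong binders and diverge on weak ones; this
  two-tier structure is what makes raw cross-assay correlation moderate
  (ensemble mean ≈ 0.55, wide seed scatter at ~30 shared pairs) while
  80%-inhibition hit calls agree far better (≈ 0.8–0.9), mechanistically
  reproducing the motivation for integrating the dialects at the hit level.
  The kinobead dialect adds rare heavy-tailed spikes (values ≫ 1) to
  exercise percentile truncation, and the KINOMEscan dialect emits a few
  flagged mutant-construct records to exercise filtering.
* **Expression**: log-normal TPM-like background; each driver's 3 context
  genes are bimodal (on ≈ 40–120 TPM, off ≈ 0.2–0.5 TPM, on-fraction
  U(0.3, 0.7) across cell lines), with "on" defined as > 10 TPM.
* **Latent sensitivity**: z = Σ_k w_k · max(0, 1 − x_k) · g_k over drivers,
  where w_k ~ U(0.7, 1.3), x_k is the drug's true inhibition state and g_k
  the context gate g_k = 0.5 + 0.5 · (fraction of the driver's context genes
  "on" in the cell line) — expression modulates a driver's effect rather
  than abolishing it, which keeps drivers marginally detectable from the
  drug axis while still giving expression features real predictive value.
  z maps through the decreasing logistic link AUC = 0.2 + 0.8 · 2/(1 + e^z),
  so an inert drug scores exactly 1 and a maximally effective one approaches
  0.2 (even potent cytotoxics leave near-full viability at the low end of an
  8-dose titration). Latent noise sd 0.04 is added to screened values.
  With only ~60 drugs, a driver's *marginal* correlation with the outcome
  carries drug-level sampling noise of order 1/√60 ≈ 0.13, so the structure
  above was chosen so the typical driver sits well above the non-driver
  background (median |r| ≈ 0.18 vs ≈ 0.10) while one or two of 20 drivers
  can still land low at a given seed — the recovery checks are therefore
  phrased over the driver population, not each driver individually.  For the
  same reason, any per-drug-unique measurement variation on non-interacting
  pairs would let tree models memorize drug identity from noise columns
  (correlation and split gain are scale-free, so even tiny noise wins a
  2,000-feature maximum-|r| lottery at n = 60 drugs); sparse reporting plus
  the shared run bias are what make the planted mechanism, not fingerprints,
  the models' best explanation.
* **Viability plates**: per screened pair, a 4PL curve (lower 0, upper 1,
  drug-specific Hill slope U(0.8, 2.5)) whose closed-form AUC over the
  default 8-dose grid (3 nM–30 µM, half-log-ish steps) equals the latent
  value; latent values outside the achievable window fall back to a flat
  curve and are flagged. Readings are viability × 1,000 counts + Gaussian
  viability noise (sd 0.05, a typical luminescence-assay replicate scatter;
  the real screens do not publish this number, so it is a free parameter) in
  3 replicate wells, plus 3 DMSO control wells per plate row. The generator's
  closed-form AUC and the analysis module's quadrature AUC are independent
  code paths, making generator→fit round-trips a genuine cross-check.

What the generator does **not** emulate: real compound chemistry or kinase
family structure, correlated assay batch effects, plate spatial bias, or the
pooled-barcode mechanics of multiplexed viability screens. Passing tests
therefore demonstrate that the pipeline recovers a planted signal under
realistic noise and missingness — not that any particular biological claim
holds on real data.

## Validation scale and determinism

The signal-recovery experiment uses the default study (≈1,500 screened pairs,
2,400 candidate features), cutoffs {100, 500}, all three families, 10 random
configurations each, under shared folds — small enough to run in minutes on
one core while leaving the planted-signal conclusions unambiguous (best CV R²
≈ 0.95 vs ≈ 0 for a permuted outcome; random row-level folds share drugs
across folds, so this measures within-screen interpolation, not chemistry
extrapolation). Every random choice in the
package flows from explicit integer seeds through numpy `default_rng`
seed-sequence spawning; the CLI derives per-stage seeds from a single master
seed, and rerunning any stage reproduces byte-identical CSVs.

## Known limitations

* Random row-level CV shares drugs and cell lines across folds, so CV R²
  measures interpolation within a screened grid rather than extrapolation to
  novel chemistry; grouped CV modes (`group_by="drug_id"` or
  `"cell_line_id"`) hold out whole drugs or cell lines for that question, and
  generalization to unscreened pairs is checked separately against the
  generator's latent truth.
* The bivariate feature screen inherits the kinome-vs-expression sample
  imbalance described above.
* The LASSO/RF engines differ from the R engines a practitioner might use
  (glmnet/ranger); penalty and mtry conventions were matched but small
  numerical differences are expected.
* IC50s capped at the range boundary are modeled as boundary values with a
  flag; no censored-regression treatment is attempted.
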