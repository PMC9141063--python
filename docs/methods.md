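# Methods

`txclass` implements a case/control classification workflow for bulk blood
RNA-seq counts: count preprocessing with control-anchored site-batch
removal, a univariate negative-binomial differential-expression baseline,
nested random-forest feature ranking feeding a gradient-boosted classifier
across a sweep of feature-set sizes, stability analysis of the selected
genes, and comparisons of predicted probabilities between clinically
defined case subgroups. A synthetic cohort generator with known ground
truth stands in for access-controlled patient data, so every stage is
testable end to end.

## Synthetic cohort model

Counts for gene *g* in sample *i* are negative binomial with

    log2 mu_gi = b_g + log2(s_i) + d_site(i) + beta_sex * male_i
                 + beta_rin * (RIN_i - 8) + lfc_g * case_i

and variance `mu + alpha * mu^2`, where the dispersion follows the trend
`alpha(mu) = a1/mu + a0` evaluated at the gene's baseline mean (the
standard parametric mean–dispersion convention for RNA-seq). Draws use the
gamma–Poisson mixture; `alpha = 0` degenerates to Poisson.

Defaults (the package's study conditions, chosen once):

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 200 / 100 | 2:1 case:control imbalance |
| n_genes | 2000 | desk-scale transcriptome |
| n_informative | 50 | planted signal genes |
| lfc_range | (0.1, 0.4) | planted log2 fold-change magnitudes (low-signal regime) |
| n_sites | 10 | clinical sites; `frac_zero_informative_sites = 0.15` of them get < 2 controls |
| batch_sd | 0.15 | sd of per-site log2 offsets (gene-shared scalar; gene-specific optional) |
| beta_sex / beta_rin | 0.2 / 0.05 | covariate effects, log2 per unit |
| libsize_log_sd | 0.5 | sd of log2 library-size factors |
| a0, a1 | 0.2 / 1.5 | dispersion trend (between-subject biological variability dominates) |
| baseline_mean_log_range | (3, 9) | log2 baseline expression range |

`SimConfig.ppmi_scale()` reproduces the published cohort structure
(390 cases, 189 controls, 25 sites, a fraction control-deficient) for
structural tests. RIN is truncated normal N(8, 1.7) on [1, 10]; age is
N(62, 10) for cases and N(61, 11) for controls; endophenotype fields
(cognitive impairment by MoCA ≤ 26, REM-sleep behaviour disorder, motor
subtype TD/PIGD, olfactory class, onset-age class) are sampled from
case/control marginal frequencies *independently of expression* by
default. Smell-class marginals are not published for this cohort
structure; we fixed normosmia at 35% of cases / 85% of controls once. The
optional `age_linked_signal` flag scales the planted effect by 1.4 for
late-onset (age ≥ 56) and 0.6 for early-onset cases, so the
age-endophenotype analysis has a generative truth to recover.

Two generator properties are deliberate design choices rather than
accidents:

- **Library size dominates sample-level technical structure.** The
  magnitudes above make column sums track the true size factors (rank
  correlation > 0.9), i.e. the batch/covariate offsets perturb, but do not
  drown, the library-size signal.
- **Site composition is label-neutral.** Cases and controls are allocated
  proportionally to site size within non-deficient sites
  (largest-remainder rounding); control-deficient sites are case-dominated
  with 0–1 controls and are excluded by preprocessing anyway. With
  multinomial assignment instead, per-site case fractions vary by chance,
  and since site identity is recoverable from the gene-shared offsets,
  site composition would leak label information into a null cohort —
  a finite-cohort confound, not a generative signal.

What the generator does **not** emulate: transcript-level structure,
splicing, GC and positional bias, cell-type composition shifts,
gene–gene correlation beyond the shared sample-level factors, and the
empirical expression distribution of any real cohort. Tests passing on
this generator therefore validate the pipeline's mechanics and its
statistical calibration under the stated model — not clinical performance
on real blood transcriptomes.

## Preprocessing cascade

Fixed order: biotype filter (protein-coding + lincRNA) → blacklist →
low-expression filter (strictly more than 5 counts in ≥ 10% of samples) →
median-of-ratios size factors (rescaled to geometric mean 1) → independent
filtering (mean normalized count below a quantile, default 0.4, ties
retained) → closed-form VST → exclusion of sites with < 2 controls →
control-anchored site-batch removal → sex/RIN residualization. Every stage
logs gene/sample counts into the run report.

The independent-filter quantile default (0.4) mirrors the roughly 40%
reduction the reference workflow reports (21,273 → 12,612 genes); the
underlying threshold is not published, so it is exposed as configuration.

**Dispersion trend.** Per-gene method-of-moments dispersions
`max(0, (var - mean)/mean^2)` on normalized counts are regressed on
1/mean with a robust (Huber) linear fit over genes with mean > 5.
Negative coefficients are clipped at zero; `a0 <= 0` triggers a
`log2(n+1)` fallback with a warning. This reproduces the parametric trend
shape without per-gene empirical-Bayes shrinkage.

**VST.** For trend `alpha(mu) = a1/mu + a0` the variance-stabilizing
transform of normalized counts n has the closed form

    v(n) = log2( (1 + a1 + 2 a0 n + 2 sqrt(a0 n (1 + a1 + a0 n))) / (4 a0) )

monotone in n and asymptotically `log2(n) + const`.

**Control-anchored batch removal.** Site offsets are estimated per gene
from control samples only (sum-to-zero site coding, so the offset is
relative to the mean control level) and subtracted from all samples of the
site. The naive version of this correction centers each site's controls
exactly while cases keep the offset-estimation noise — a systematic
case/control residual-variance asymmetry of order `1/n_controls(site)` per
gene. That asymmetry is invisible per gene but a multivariate classifier
aggregates it across a thousand genes into strong spurious discrimination
on null cohorts (the asymmetry itself is demonstrated directly in the test
suite). The default
correction is therefore **cross-fitted**: each control is corrected with
the leave-one-out offset from its site's other controls, scaled by
`sqrt(n^2 - 1)/n` so control and case residual variances match exactly
under within-site homoskedastic noise. Cases are corrected with the full
controls-only estimate, unchanged. `cross_fit=False` restores the literal
correction (per-site control means exactly equal afterwards). Anchoring on
controls is kept — estimating batches from both groups would absorb true
disease signal into the batch term; the exclusion of sites with fewer than
two controls exists precisely because the anchor needs replicates.

**Covariate removal.** Sex and RIN coefficients are fitted per gene by
least squares on all samples (the disease label is not in the model) and
subtracted; the intercept is retained. Constant covariates are skipped
with a warning. Sex/RIN are not confounded with the label by design, so
control-anchoring is unnecessary here.

## Differential-expression baseline

Each gene is fitted with an NB GLM (log link, offset `log s_i`,
dispersion fixed at the trend value for the gene's mean normalized count)
against intercept + standardized RIN + site (treatment coding) + sex +
label, label last. Fitting is IRLS, vectorized across genes (convergence
`max |Δbeta| < 1e-8`, ≤ 100 iterations); non-converged genes are flagged,
their p-values set missing, and they are excluded from the
Benjamini–Hochberg m. The Wald statistic is `beta_label / se` with se from
the inverse Fisher information; `lfc = beta_label / ln 2`; positive lfc
means higher expression in cases. The test suite checks coefficients and standard errors per gene against
statsmodels' NB GLM.

Deliberate simplifications relative to full empirical-Bayes DE machinery:
trend dispersions without per-gene shrinkage, no fold-change shrinkage, no
outlier refitting, no DE-coupled independent filtering. The module's role
here is a univariate baseline feature source, not a reimplementation of a
DE package. Null calibration is verified by simulation in the test suite (type-I
error within [0.03, 0.07] at nominal 0.05 over 1000 null genes).

## Nested feature selection and classification

Outer loop: stratified k-fold cross-validation (default k = 10), repeated
R times with different fold seeds. Inside each **training** fold, B
independently seeded random forests (default protocol: B = 100 forests of
1000 trees, √f features per split; desk-scale runs shrink B and the tree
count) produce impurity importances that are averaged and sorted
(ties broken by gene id) into the fold's ranking — validation samples
never touch the ranking, and an explicit guard raises on any
train/validation overlap. Permutation importance is available as an
alternative mode. For each feature-set size C on a geometric grid, an
XGBoost classifier (100 rounds, depth 6, learning rate 0.3, logloss — the
library defaults, no tuning) is trained on the top-C genes and scored on
the held-out fold.

Validation predictions are pooled across the k folds within each
repetition (more stable than averaging per-fold AUCs at small fold sizes;
switchable), giving one AUC-vs-C curve per repetition, linearly
interpolated between grid points. The summary curve is the pointwise
median with its mean absolute deviation about the median; `C*` is the grid
argmax of the median (smallest C on ties).

Per-repetition top-C sets for the stability analysis are obtained by
averaging each repetition's fold-level importance vectors; counting
membership across repetitions gives the selection-frequency table, and
genes selected in at least 70% of repetitions (inclusive; ≥ 14 of 20)
form the frequent-gene list. DE annotations are joined onto the table so
genes selected by the classifier but not differentially expressed are
visible.

The **DE baseline** trains the same boosted classifier on the DE gene set
using a single stratified 90/10 split. By default the DE screen runs on
the training portion only (leakage-safe); whether the reference analysis
derived its DE set inside or outside the split is not stated, so the
literal variant is available via `leakage_safe=False`.

## Evaluation

Threshold metrics (accuracy, sensitivity, specificity, balanced accuracy,
F1) come from the confusion counts at a fixed threshold of 0.5
(configurable; the reference protocol does not state one). AUC is
concordant-pair counting with half-credit for ties, computed via midranks.
Endophenotype comparisons use cases only: each subject's predicted
probability at C* is averaged over repetitions (arithmetic mean; the
aggregation rule is not published), groups are compared with a two-sided
Wilcoxon rank-sum test — exact null when the combined n ≤ 25 and tie-free,
tie-corrected normal approximation otherwise. Groups with fewer than two
subjects skip the test with a warning; missing endophenotype values are
dropped and counted.

## Numerical and reproducibility choices

- One master seed fans out to every stage by a stage-name-keyed hash
  (`_seeds.derive_seed`), so sub-pipelines are independently reproducible;
  all forest/boosting seeds derive from it (`rep_seed = base_seed + b`).
- IRLS: damped by clipping the linear predictor to ±30; ridge 1e-10 on the
  normal equations; singular fits flagged non-converged.
- BH adjustment follows the step-up definition with NaN-aware m.
- All tree learners run single-threaded for bit-reproducibility.
- Degenerate inputs fail loudly: single-class labels, empty DE sets,
  all-sites-removed, no all-positive reference gene, C outside 1..f.

## Problem sizes

Tests and the acceptance script run desk-scale configurations — cohorts of
~300 samples × 2,000 genes (≈ 1,100 after filtering), nested CV with 2–5
repetitions of 10 folds, 2 forest repetitions of 100 trees per fold — as
the package's validation scale. The full reference protocol
(R = 20, B = 100, T = 1000, ~12,600 genes, 548 samples) is a configuration
choice away and changes only runtime. Statistical conclusions from the
desk scale (null calibration, parameter recovery, ordering of the DE
baseline vs the nested selector) were chosen to be scale-robust
properties, not point reproductions of published numbers, which derive
from access-controlled data.

## Known limitations

- Dispersion handling is trend-only; genes with strong gene-specific
  overdispersion are mis-weighted relative to full empirical-Bayes DE.
- The cross-fitted batch correction equalizes residual variances under
  within-site homoskedasticity; heteroskedastic sites retain a
  second-order asymmetry.
- Selection-frequency analysis treats repetitions as exchangeable;
  fold-level selection variability within a repetition is averaged away.
- The generator's planted effects are gene-wise constant fold changes;
  correlated gene programs (the realistic case) would make ranking
  stability look better than a matched-power independent-gene truth.
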