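# Methods

`olfnet` implements an analysis chain linking odor-guided behavior in a
humanized-APOE mouse cohort to diffusion-MRI connectome features, AD risk
traits, and blood/brain transcriptomics. This note documents the models,
the synthetic-data generator that exercises them, and the numerical and
design choices a maintainer would want to know.

## Study design being modeled

Subjects are mice stratified by five risk factors: APOE genotype
(APOE2/APOE3/APOE4, protective → highest genetic AD risk), diet (control
vs. high-fat), sex, age group (12 vs. 18 months) and NOS2 immune
background (murine `mNOS2` vs. humanized `HN`). The bundled
"published-cohort" preset reproduces a 465-animal behavioral cohort with exact
per-cell margins for each (genotype, diet) cell. Downstream cohorts
(imaging, blood transcriptomics) are subsets in the original design;
synthetically they are simulated at whatever size a test requires.

## Behavioral indices

For a novel/familiar investigation pair (No, Fo):

* Recognition index `RI = No / (No + Fo)` in [0, 1]; > 0.5 indicates
  memory of the familiar odor.
* Dishabituation index `DI = (No − Fo) / (No + Fo)` in [−1, 1], computed
  from the trial-5 novel-odor time against the trial-4 familiar-odor
  time. The identity `RI = (DI + 1)/2` holds to machine precision and is
  property-tested.
* Preference ratio: each object's share of total object-investigation
  time.
* Anhedonia = (tracked − total odor exploration) / tracked. Immobility is
  retained deliberately — freezing may itself reflect diminished hedonic
  drive.
* Exploration AUC: trapezoidal area of response over the concentration
  series {0, 0.001, 0.01, 0.1 v/v}. The abscissa is the concentration
  rank 1..4 (equal spacing) because log-spacing is undefined at the
  vehicle concentration 0; `abscissa="value"` switches to raw
  concentrations.

A zero-total pair (No + Fo = 0) raises an error rather than returning 0;
silently coding undefined indices as 0 would bias group means downward.

## Factorial effect sizes

Outcomes are modeled as `outcome ~ APOE * Diet * Age * HN * Sex` with
sum-to-zero contrasts and Type III sums of squares (statsmodels OLS +
`anova_lm(typ=3)`). Per term we report F, p, partial
η² = SS_effect / (SS_effect + SS_error) and Cohen's f = sqrt(η² / (1−η²)).
Repeated measures (trials, concentrations) are aggregated to one value per
subject before fitting. This replaces a subject-level random intercept;
under balance the fixed-effect estimates coincide, and it keeps the model
an ordinary least-squares fit. Effect-size intervals are nonparametric
bootstrap (subject resampling, 1000 draws by default) rather than
noncentral-F inversion — simpler and consistent with the pipeline's other
resampling inference. Estimated marginal means are equal-weight averages
of model-predicted cell means over the non-focal factors with
normal-approximation CIs; on balanced designs they equal raw group means
(tested). Post hoc contrasts: Tukey HSD for all-pairwise, Šidák for
planned pairs, selected by flag.

Degenerate inputs: an all-equal outcome reports SS_effect = 0, F = 0,
p = 1 for every term (the 0/0 ratio is resolved by convention); a
rank-deficient design raises an error naming the aliased columns.

## Elastic net → SUMCOR MCCA

Connectomes are symmetric nonnegative streamline-count matrices over a
shared region list (332 atlas regions at full scale). Vectorization takes
upper-triangle (i < j) edges in row-major order, applies log(1 + count)
and a column z-score, and drops exactly-constant edges with a logged
report.

**Stage 1 (screening).** Edge features X are regressed on the behavioral
outcome matrix Y with the elastic-net loss

    (1/2n)·‖Y − Xβ‖² + λ·(α‖β‖₁ + (1−α)/2·‖β‖²),  α = 0.5,

one coordinate-descent fit per outcome column (scikit-learn's
`ElasticNetCV`, whose objective is exactly this loss with `alpha=λ`,
`l1_ratio=α`). λ* minimizes mean 10-fold CV MSE per outcome; the fold
assignment is seeded and recorded. The selected set is the union of
nonzero-coefficient edges across outcomes. A brute-force grid search of
the loss on 2-feature toys is the independent oracle in tests.

**Stage 2 (integration).** Three domains enter the multi-set CCA: the
selected edge columns, the standardized behavioral summary, and one-hot
sum-to-zero-centered risk traits. The SUMCOR criterion

    max Σ_{i<j} corr(X⁽ⁱ⁾w⁽ⁱ⁾, X⁽ʲ⁾w⁽ʲ⁾)  s.t. unit-variance variates

is solved by Horst block-coordinate ascent: each update solves a
ridge-stabilized (1e−8) normal system for one domain holding the others
fixed, which cannot decrease the objective; the iteration history is
asserted monotone within 1e−10 at every sweep. Initialization is the
leading right singular vector per domain (deterministic); convergence is
Δsumcor < 1e−8 or 500 sweeps, with non-convergence flagged on the model
rather than raised (permuted/bootstrapped data occasionally cycle slowly
near the optimum). The sign convention fixes the largest-|weight| entry of
the first domain positive via a global sign flip, which leaves all
pairwise correlations unchanged. Only the first canonical component is
computed — the analysis reports one weight per connection and one summed
correlation, so deflation is out of scope. A MAXVAR variant (generalized
eigenproblem on the block covariance) is available behind
`method="maxvar"`.

Oracles: the two-domain case agrees with classical CCA (generalized
eigenproblem) to 1e−6; 2-feature domains agree with exhaustive grid search
over unit vectors at 0.5° resolution to 1e−3.

**Inference.** Bootstrap: subjects resampled with replacement, MCCA refit
on the fixed EN-selected feature set, percentile 95% CI on the summed
correlation (re-running the elastic net per resample would change the
feature set across draws and is not what "retained features entered the
model" describes; it is also two orders of magnitude more expensive).
Permutation: rows of the behavior domain are shuffled, which breaks all of
that domain's pairwise couplings symmetrically;
p = (1 + #{perm ≥ obs}) / (P + 1).

**Back-projection.** The connectome-domain weight vector maps back to
region pairs on its natural scale (the canonical variate has unit sample
variance). Entries with |w| ≤ 1e−3 are counted as zeroed by the canonical
fit — the stage-count bookkeeping between "EN-selected" and
"post-threshold" uses this explicit, configurable rule — and the
remaining edges are thresholded at |w| ≥ 0.05 (default) into the reported
subnetwork.

## Eigengenes and the coupling grid

Expression counts are normalized by counts-per-million, log2(x+1), and
gene-wise centering. Published descriptions of such pipelines often say only "normalized"; this
dialect is explicit, configurable at the function boundary, and makes the
PCA capture co-variation rather than baseline abundance. Eigengenes are
SVD principal components of the subjects × genes matrix: 10 for blood, 4
per brain region by default; scores are standardized to unit variance with
the largest-|loading| gene of each component fixed positive. One blood PCA
is shared across all regions (recomputing per region subset would make
"eigengene k" mean different things in different rows of the grid).

The coupling grid fits one simple linear model per
(region, metric, eigengene) cell — 8 regions × 10 eigengenes × 7 metrics
= 560 cells at defaults — with both variables z-scored within region, so
the slope equals the Pearson r and R² = r². The eigengene is the response
and the metric the predictor; this is irrelevant to r but fixes the
reported β. BH-FDR runs over the whole grid as one family. Cells with
fewer than 4 overlapping subjects are emitted with a missing flag (never
silently dropped) and excluded from the BH family. Subject matching is by
inner join with a logged count — no imputation.

## Brain–blood coupling and enrichment

Tissue-pair PC correlations use both Pearson and Spearman tests over the
top 4 PCs per tissue; BH runs in one family per test type (a flag pools
them), and a pair is significant when min(FDR_P, FDR_S) < 0.05 — the
combination rule is explicit because running both tests requires one. For
each significant pair the top-200 |loading| gene lists are intersected;
intersections under 5 genes are skipped. Over-representation is the
upper-tail hypergeometric test against a GMT collection (one-sided, as is
standard for ORA), BH-corrected across sets — a separate family from the
PC-pair tests. Annotation comes from GMT files only; a toy collection
built from the generator's planted modules plus random decoys ships for
fixtures.

## The synthetic cohort generator

Every table is a pure function of a `SimulationSpec` (master seed; child
seeds by fixed stream offsets, recorded in the fixture manifest). Planted
structure, all zero by default (a null configuration):

* **Trial structure** — preference trials with investigation time rising
  in concentration rank; habituation with multiplicative decay 0.8/trial
  over trials 1–4 and a novelty rebound on the odor-switched object at
  trial 5; memory probes at 1 h/24 h/48 h with mean RI 0.65/0.60/0.55.
  Behavioral times are truncated Gaussians (base 10 s, sd = `noise_sd`);
  tracked time exceeds summed object time by construction so the
  anhedonia index is well defined.
* **Effect sizes** — mean shifts in SD units keyed by trait-level
  conditions (e.g. RI −0.5 SD for APOE4 × 18 mo × high-fat in the
  published-cohort preset). No within-group variances are published for the original cohort, so
  these magnitudes are free parameters chosen once at a realistic
  moderate-effect scale; all acceptance checks are recovery- or
  calibration-based, not value-matching.
* **Latent factor** — one standard-normal score per subject, injected
  linearly into designated connectome edges, the behavioral
  recognition/anhedonia outcomes, and tilted along an
  APOE4/high-fat/aged risk contrast in the traits. A single factor,
  because a single canonical dimension is what the integration stage
  estimates.
* **Connectomes** — per-edge log-normal baselines around 50 streamlines;
  planted edges are Gaussian mixtures of the latent score at the
  configured loading before rounding to nonnegative integers.
* **Expression** — negative-binomial counts (dispersion 0.3), log-normal
  library sizes (CV 20%, so the CPM step matters). Ten gene modules of 40
  genes load on shared module scores with geometrically decaying strength
  (factor 0.88 per module) so that module variances are distinct and the
  PCA does not rotate within a degenerate eigenspace — eigengene order
  then tracks module index. Within each module, half the genes load
  negatively: modules are within-library contrasts, as real expression
  PCs are, which keeps module activity from contaminating every gene
  through the library-size denominator. Brain tissues see the blood
  module scores mixed at correlation 0.7.
* **Imaging** — designated (region, metric) cells carry correlation
  `eigengene_metric_r` (default −0.5) with a designated module score;
  defaults mirror the strongest reported couplings (parasubiculum /
  hippocampus / postsubiculum diffusivities vs. module 2). FA is clipped
  to [0, 1]; other metrics use plausible location/scale per unit.

What the generator does **not** emulate: tract geometry, spatial
autocorrelation between regions, batch effects, cell-type composition,
count overdispersion heterogeneity, or realistic gene–gene correlation
beyond block modules. Passing recovery tests therefore demonstrates the
estimators work under the planted model, not that the biological effect
sizes are attainable in real data.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately desk-scale configurations: null
calibration uses 200 seeds × 199 permutations on 60-subject
three-domain toys and 50 replicates of the 560-cell grid; recovery suites
use n = 500; the end-to-end pipeline default is 120 subjects × 40 regions.
The statistical behavior being checked (uniform null p-values, FDR
calibration, weight-cosine recovery) is size-stable; tolerances follow the
binomial/KS Monte-Carlo error at those sizes.

Other numerics: BH adjustment is the standard step-up with monotone
enforcement, validated against an independent reference on random
p-vectors; hypergeometric tails come from `scipy.stats.hypergeom`,
validated by exhaustive enumeration on small universes; zero-variance
columns map to zero (not NaN) during standardization so degenerate
bootstrap resamples cannot poison a fit; ties in gene rankings break
alphabetically and in region rankings by region name, making every
reported ordering deterministic.

## Known limitations

* No mixed-model solver: repeated measures are aggregated, which loses
  within-subject df; between-subject effect estimates are unchanged under
  balance but the aggregated F statistics are not numerically comparable
  to subject-level mixed-model F statistics at unbalanced designs.
* The stage-2 reduction rule (|w| > 1e−3 after the canonical fit) is an
  explicit interpretation of an unstated step in the original analysis;
  the counts it produces are bookkeeping under this rule, not a claim
  about the original one.
* Bootstrap CIs condition on the EN-selected feature set; selection
  uncertainty is not propagated (a flag re-runs selection per resample at
  ~100× cost).
* The behavioral outcome matrix entering the elastic net is "all summary
  columns"; composites (e.g. a single memory score) are a caller choice.
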