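# Methods

`metaborank` implements a consensus machine-learning workflow for
prioritizing plasma metabolites by the strength and consistency of their
association with a binary clinical outcome (28-day mortality in sepsis) in
small, class-imbalanced cohorts. This note documents the statistical model
behind each stage, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## The analysis problem

The motivating setting is a cohort of 60 ICU patients with sepsis, profiled
for 411 plasma metabolites by GC/LC mass spectrometry, with a 42% 28-day
mortality rate. With hundreds of correlated, right-skewed, left-censored
features and only ~25 events, no single classifier's feature ranking is
trustworthy on its own. The workflow therefore fits a *panel* of classifier
families, lets each one nominate the metabolites its innate
feature-selection mechanism ranks highly, and scores every metabolite by
the fraction of families that nominated it — the **ensemble importance
score**. Metabolites at or above a score threshold (default 0.5) form the
prioritized set.

## Preprocessing

Fixed stage order: drug-metabolite exclusion → below-LOD filter → log10
transform → imputation.

* **Drug exclusion** removes metabolites annotated as drug metabolites
  (exogenous compounds reflect treatment, not physiology).
* **LOD filter**: a metabolite is removed iff the fraction of its cells
  flagged below the lower limit of detection is *strictly greater than*
  10% (`lod_exclusion_fraction`, default 0.10). The decision uses only the
  below-LOD mask, never the numeric values; a metabolite at exactly 10% is
  retained.
* **log10 transform** is applied to observed cells only; a scale tag on the
  table rejects accidental double transformation.
* **Imputation** fills each remaining below-LOD cell with a per-metabolite
  value computed from observed cells only, on the analysis (log10) scale.
  The default is half the minimum observed value (`half_min_per_metabolite`),
  the most common convention for left-censored metabolomics data;
  `min_per_metabolite` and `lod_over_sqrt2` are available because the
  choice is a judgment call and affects only the censored tail.

Inside cross-validation, imputation fill values and standardization
parameters are recomputed from the training folds of each split and applied
unchanged to the held-out fold, so no test-fold information leaks into
preprocessing. Standardization uses the sample SD (ddof = 1); training
columns that are constant within a fold are mapped to all-zeros rather than
dropped, keeping the metabolite index identical across folds.

## Model registry

Eight classifier families, each exposing a risk score in [0, 1] (larger =
higher predicted death risk) and a nonnegative innate importance vector:

| family | estimator | importance | selection |
| --- | --- | --- | --- |
| `pls_da` | PLS regression on the 0/1 outcome | VIP scores | top-N |
| `nearest_shrunken_centroids` | soft-thresholded class centroids (own implementation) | max shrunken centroid difference | native (surviving features) |
| `random_forest` | 500 trees | impurity importance | top-N |
| `svm` | linear-kernel SVC | absolute weight vector (permutation importance for nonlinear kernels) | top-N |
| `random_knn` | kNN ensemble on random sqrt(p)-feature subspaces (own implementation) | mean excess leave-one-out accuracy of subspaces containing the feature | top-N |
| `ada_boost_bag` | AdaBoost on stumps | impurity importance | top-N |
| `lasso_logistic` | L1 logistic regression | absolute coefficients | native (nonzero support) |
| `penalized_logistic` | elastic-net logistic regression, ridge-leaning mixing (l1_ratio = 0.1) | absolute coefficients | top-N |

Default hyperparameter grids are small and ordered from most regularized /
fewest components to least: penalty paths of 10 values (C from 0.01 to 10,
log-spaced) for the two logistic families, 1–5 PLS components, 10 shrinkage
thresholds for nearest shrunken centroids, 2 `max_features` settings for
the forest, C in {0.1, 1, 10} for the SVM, k in {5, 3} for random kNN, and
{50, 100} boosting rounds.

"Ranked highly" is undefined for families without an intrinsic sparse
solution, so those use **top-N** selection (default N = 20, a config knob
surfaced in all reports): the N largest importances, ties broken by fixed
metabolite order. Exact-zero importances are never selected — a model that
assigned zero weight did not rank the feature, and tie-breaking zeros by
column order would systematically favour early-indexed metabolites across
every dense family, biasing the consensus score.

PLS-DA risk scores are the predicted 0/1 response passed through a strictly
monotone sigmoid centred at 0.5: this preserves the ranking (hard clipping
would tie extreme predictions) while keeping scores on a probability-like
scale. The linear SVM score is the decision margin through a sigmoid —
a monotone pseudo-probability whose 0.5 point is the decision boundary,
not a calibrated probability.

## Cross-validation and tuning

Stratified k-fold cross-validation (default 5 folds), re-randomized across
repeats (default 50 repeats; the recovery experiment and worked examples
use 5 to keep runtimes in minutes — problem sizes are stated with each
result). The tuning objective is the area under the precision-recall curve
by the average-precision convention: no interpolation between operating
points, equal scores grouped into one threshold step. Under this convention
a constant (no-skill) classifier scores exactly the event prevalence —
0.4167 for 25 events in 60 — which anchors an interpretable baseline for
imbalanced cohorts; linear PR interpolation would break this identity and
is known to be optimistic.

Grid selection uses the **one-standard-error rule** by default: the most
regularized grid point whose mean test-fold PR-AUC lies within one standard
error of the best mean. Exact ties therefore resolve to the simpler model,
and on uninformative data — where every grid point ties statistically —
the sparsest configuration wins, keeping native selections small on noise.
Plain best-mean selection (`grid_rule="best"`) is available. Even with the
one-SE rule, winner's-curse bias of the maximum over a 10-point grid at 25
resamples means noise selections are *small*, not reliably empty; the
property tests assert a median of at most 20% of features on pure noise.

Reported per-split metrics: PR-AUC, ROC-AUC (the normalized Mann–Whitney
statistic, ties counted half), and sensitivity/specificity at a probability
threshold of 0.5. The operating point is a reporting convention only — no
published threshold exists for this design — and is configurable.

The final importance vector per family comes from a refit on all samples at
the tuned hyperparameters (the convention of caret-style workflows), with
full-data imputation and scaling.

## Ensemble importance score

With M configured families (default 8) and s_mj = 1 if family m selected
metabolite j:

    score_j = (1/M) * sum_m s_mj

Scores live on the lattice {0, 1/M, …, 1}. Families whose tuned fit
degenerates to an empty selection still count in the denominator.
Prioritization applies an inclusive threshold (score ≥ τ, default τ = 0.5).
Ranking is by descending score with alphabetical tie-breaking on the
display name; both conventions are deterministic. Cross-method agreement is
reported as pairwise intersection sizes and Jaccard indices (two empty
selections have Jaccard 1 by convention).

## Cohort statistics

* Wilcoxon rank-sum (midranks for ties) for continuous comparisons: exact
  enumeration when the combined sample is ≤ 12 without ties, otherwise the
  normal approximation with tie and continuity correction.
* Likelihood-ratio chi-squared (G = 2 Σ O ln(O/E), 1 df) for 2×2
  categorical comparisons; zero cells contribute 0, zero margins are an
  error.
* Group medians and IQRs use linear-interpolation quartiles (numpy's
  default), stated because quartile conventions differ between packages.
* Univariate p-values are descriptive companions to the ensemble score and
  are reported unadjusted; a Benjamini–Hochberg column is emitted alongside
  for reference but never used for ranking.
* PCA variance fractions come from the singular values of the centered,
  per-metabolite standardized matrix.
* Heatmap layout uses agglomerative clustering (Euclidean distance,
  complete linkage — a display choice) of per-metabolite standardized log10
  values, with scipy's deterministic merge order as the tie-break.

## Synthetic cohort generator

Real cohort data are not publicly deposited, so the generator is the
package's test bed. Defaults encode the study conditions: 60 samples, 411
metabolites in 8 super-pathways, 42% event rate (exact event counts by
default: round(n × rate)), 13 effect metabolites at a standardized mean
difference of 1.0 on the log10 scale, all higher among non-survivors.

* **Abundances**: log10 values are mu_j + sigma_j Z_ij with mu_j ~ N(5.2,
  0.8) and sigma_j ~ U(0.25, 0.6), i.e. log-normal ion counts around 10^5
  with right-skewed raw scale. Latents Z are standard normal with a single
  exchangeable correlation (default 0.4) within super-pathway blocks —
  the simplest structure producing pathway-level covariation without
  inventing pathway biology.
* **Outcome**: the binary outcome is drawn first and the planted
  metabolites' latents are shifted by `effect_size` standard deviations in
  the non-survivor group. For equal-covariance Gaussian latents this
  location-shift model induces an exactly logistic-linear conditional
  P(died | latents), so the outcome follows a logistic model on the planted
  latents while each planted metabolite's SMD equals `effect_size` by
  construction. (A prospective logistic model on the *sum* of 13
  quasi-independent latents cannot reach a per-metabolite SMD of 1.0 at
  this event rate — the separation information would have to be shared
  across all 13 — which is why the generator uses the retrospective
  formulation.) The induced intercept is recorded in the ground-truth
  manifest via bisection calibration.
* **Censoring**: each metabolite gets a detection-limit quantile q drawn
  uniformly from `lod_quantile_range` (default (0, 0.29)); the floor(q·n)
  smallest values are flagged below-LOD. With the strict >10% filter this
  removes ~60% of metabolites at n = 60, emulating the 411 → ~158
  attrition of the motivating study. Planted metabolites draw q from
  (0, 0.08) so they always pass the filter — mirroring that reported top
  metabolites had, by construction, survived quality control — so recovery
  experiments exercise the selection machinery rather than filter
  attrition. Censoring is applied after the outcome is generated from the
  uncensored latents: it acts as measurement degradation, not confounding.
* **Drug metabolites**: a 5% random subset, never overlapping the planted
  set.
* **Seeding**: one master seed, deterministic per-stage substreams;
  identical config gives bit-identical cohorts.

What the generator does **not** emulate: instrument-level artifacts (peaks,
retention times, batch drift), heavy-tailed or multimodal abundance
distributions, missingness mechanisms other than left-censoring at the
detection limit, correlation between censoring severity and outcome, and
real pathway topology (blocks are exchangeable). Passing recovery tests
therefore show that the pipeline finds location-shifted, block-correlated
log-normal signals at the study's dimensions — not that it would rank any
particular real metabolite highly.

## Recovery experiment

`run_recovery_experiment` generates a default cohort per seed, runs the
full 8-family pipeline (5 repeats of fivefold CV; the full 50-repeat mode
is a longer optional run), and reports per seed: the mean ensemble score of
planted vs. null metabolites and the overlap between the planted set and
the ensemble top-13. Under defaults the planted mean exceeds the null mean
on every tested seed and the median top-13 overlap is ~10 of 13.

## Known limitations

* Importances are not comparable in magnitude across families; only the
  selection indicator enters the consensus, which is the point of the
  design but discards within-model ranking detail beyond the top-N cut.
* The top-N size (20) and the score threshold (0.5) are conventions; the
  prioritized set's size is sensitive to both, so both are surfaced in all
  reports.
* With 25 resamples, hyperparameter selection retains winner's-curse bias;
  sparse families select a small but nonzero number of features on pure
  noise.
* Sensitivity/specificity at threshold 0.5 are not calibrated probabilities
  for margin-based families (SVM, PLS-DA).
* The random-kNN support weights use leave-one-out training accuracy, which
  is optimistic relative to held-out accuracy; weights are used only
  relatively, within one fitted ensemble.
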