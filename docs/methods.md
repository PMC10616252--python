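# Methods

This note documents the models and procedures implemented in `sehybrid`,
the parameter choices that matter, what the synthetic cohorts do and do
not emulate, and the numerical conventions.

## Problem setting

Subjects undergo a fixed selenium-supplementation period; hair selenium
content is measured before and after. The absorption rate is defined as

    rate = (Se_after − Se_before) / Se_before × 100 %

and subjects are labeled high-efficiency (HE) when rate ≥ 10 %, else
low-efficiency (LE). The boundary is inclusive; the comparison carries a
1e-9 absolute tolerance so that decimal inputs such as 0.40 → 0.44
(exactly 10 %) classify HE despite binary floating-point representation.
Subjects missing either measurement are excluded with a warning. The
prediction task is binary classification of this label from the
*pre-intervention* genus-level microbiome profile plus host metadata.

## Classifier and feature pipeline

The classifier is a gradient-boosted decision-tree ensemble (XGBoost,
histogram method, single-threaded for bit reproducibility) wrapped as a
scikit-learn estimator. Tuned hyperparameters and their default search
grid: tree depth {2, 3, 4}, learning rate {0.1, 0.3}, boosting rounds
{100}, L2 leaf penalty λ {1, 10}. Selection maximizes mean 5-fold
stratified CV AUC; the grid order is fixed and ties keep the first
configuration, so tuning is deterministic given the seed. Folds are
reduced with a warning when a class has fewer members than folds.

Feature refinement ranks genera by "weight" importance — the number of
tree splits that use the genus (gain-based importance is available
behind a flag) — descending, ties broken lexicographically so rankings
are reproducible. The learning curve retrains on top-k prefixes under
the same CV; the biomarker set is the top k = 10 (explicit, no automatic
knee detection).

Two caveats are worth knowing:

* The protocol ranks features on the full training batch and then
  cross-validates on that same batch, so small-k points of the learning
  curve carry feature-selection optimism; under a pure null this can
  reach ~0.6–0.7 CV AUC at small k. The package keeps the protocol as
  stated; the null behaviour of the curve is therefore tested with a
  ranking taken from an independent cohort.
* On the synthetic cohorts the curve stabilizes at k ≈ 10 and declines
  again once the many noise genera enter — the stabilization point, not
  a monotone plateau, is the tested property.

Host variables are discretized — age: Young ≤ 35, Middle 36–59, Old
≥ 60; BMI: Low < 18.5, Middle [18.5, 24), High ≥ 24 (the bins read as a
gapless partition of the real line, so BMI 23.95 is Middle) — and
one-hot encoded with a fixed column order: 2 gender + 3 age + 3 BMI + 2
probiotics + 2 health-status columns = 12 by default; the health-status
category list is configurable and can be extended from data. Encoded
columns are concatenated after the genus columns and each row is
L2-normalized to unit norm (all-zero rows are left as zeros and
flagged). "L2 regularization" thus enters twice, deliberately: per-row
normalization of the fused matrix and the classifier's λ penalty.

A fitted model is stored as a `ModelBundle`: booster + *feature recipe*
(exact genus list, encoding spec, normalization flag). Applying a bundle
to a new cohort replays the recipe verbatim — genera absent from the
target table are zero-filled (and logged), extra genera ignored — so
transfer never silently changes the feature space.

## Community statistics

Alpha diversity: Shannon −Σ pᵢ ln pᵢ (natural log by default,
configurable base), Gini-Simpson 1 − Σ pᵢ², and Chao1
S_obs + F₁²/(2F₂) with the classic F₂ = 0 fallback
S_obs + F₁(F₁−1)/2. Chao1 requires integer counts and is only computed
when a count table is supplied; relative abundances are the canonical
internal representation everywhere else.

Beta diversity is Bray-Curtis, d = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ). This is a
deliberate substitution for phylogeny-weighted community distances,
which require a reference taxonomy tree; every downstream function
accepts any precomputed `skbio.DistanceMatrix`, so a phylogenetic matrix
can be dropped in unchanged.

PERMANOVA is the classical one-factor decomposition on a distance
matrix: SS_total = Σ_{i<j} d²ᵢⱼ/N; SS_within = Σ_groups Σ_{i<j∈g}
d²ᵢⱼ/n_g; pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)); effect size
R² = SS_between/SS_total. The p-value uses random relabelings,
p = (1 + #{F_perm ≥ F_obs}) / (1 + B), default B = 999, seeded; F
comparisons carry a 1e-12 tolerance so symmetric relabelings count as
ties. For small N an exhaustive mode enumerates every distinct
group-size-preserving assignment and reports #{F ≥ F_obs}/#assignments
(identity included). Permutations are evaluated vectorized (an einsum
over the stacked group indicators), which keeps 500-replicate null
studies with B = 999 in seconds. Only single-factor models are
implemented — effect sizes are per-variable, not a sequential
partition — matching how the effect-size scan reports one R² per host
variable, sorted descending with name tie-breaks; single-level variables
are skipped with a warning. The package-wide significance threshold is
α = 0.01.

Rank statistics (Spearman correlation, two-sided Wilcoxon rank-sum) come
from scipy; constant input to Spearman yields a flagged undefined
result rather than an exception.

## Transfer protocols

**Hybrid calibration** (`calibrate_hybrid`): per randomization repeat,
`round(test_fraction × n_new)` new-batch samples are drawn as the test
set *first*, then n calibration samples are drawn from the remainder
(disjointness is asserted); the model is retrained from scratch on
base ∪ calibration with the bundle's fixed hyperparameters and evaluated
on the held-out set. Defaults mirror the study design: n ∈ {5, 10, 15,
20, 25, 30}, test fraction 0.3, 5 repeats, no stratification (a
stratified option exists); repeats whose random test draw contains a
single class contribute no AUC for that point. Hyperparameters are not
retuned and no warm-starting is used, so the curve is attributable to
data mixing alone. Points whose n exceeds the available remainder are
skipped with a warning; n = 0 degenerates to plain transfer.

**Cross-cohort refinement** (`cross_cohort_refine`): the per-batch
top-10 biomarker sets are intersected (an empty intersection is a
warning, not an error, at the set level; refinement itself requires a
non-empty set) and the model is rebuilt on the base cohort using only
the shared genera plus the encoded metadata, then evaluated on the
target region's cohort.

## Synthetic cohorts

The generator draws, per subject, a logistic-normal composition:
per-genus log-baseline ~ N(0, 1.5²) (drawn once per cohort), plus a
class effect of ±signal_effect/2 on the planted signal genera, plus
categorical host-variable effects (each variable loads on a sparse
random set of 5 genera, scaled by a per-category score in [−1, 1] and
the variable's effect size), plus per-batch and per-region offsets
~ N(0, sd²) per genus, plus per-sample noise with sd = 1/√dispersion;
the sum is passed through a softmax, so every effect is multiplicative
on relative abundance — the structure PERMANOVA detects. Selenium
values: Se_before is log-normal around 0.45 (hair content scale);
the rate is drawn uniformly in [10.1, 40] % for HE and [−10, 9.9] % for
LE, and Se_after is set from it, guaranteeing that re-deriving labels
from the stored measurements reproduces the planted class exactly.

Defaults and why:

| parameter            | default         | rationale |
|----------------------|-----------------|-----------|
| n_genera             | 49              | scale of a genus-filtered 16S table |
| n_samples_per_batch  | 156 / 43 / 7    | the study's batch sizes |
| signal_effect        | 0.45            | puts in-batch biomarker-model CV AUC near the 0.85 design point |
| batch_shift_sd       | 0.3             | mild within-region batch effect |
| region_shift_sd      | 0.6             | geography is the stronger confounder |
| dispersion           | 4 (noise sd 0.5)| realistic within-group spread |
| class_balance        | 0.5             | near-balanced HE/LE split |
| host effects         | age 0.5 > probiotics 0.4 > BMI 0.3 > gender 0.2 > health 0.1 | the effect-size ordering the scan should recover |

`stable_signal_genera` makes a subset of the planted markers
region-stable; the rest discriminate only in the first region (and can
additionally be suppressed toward absence via `unstable_suppression`,
emulating a biomarker genus missing from another city's batches). This
realizes the two-region scenario in which only 3 of 10 markers survive
the Venn intersection.

The scenario used by the heavier end-to-end checks and by
`scripts/acceptance.py` is three batches of 156/43/40 subjects over two
regions, 10 signal genera (3 stable) at effect 0.8 and batch shift
0.5–0.8. The 40-subject second-region cohort is a deliberate scale-up
of the study's 7-subject cohort so that a target-cohort AUC is
statistically measurable; cross-cohort AUCs are reported as medians over
replicate cohorts because a 40-sample AUC is still noisy.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: phylogenetic correlation between
genera and sparsity/zero-inflation of real 16S counts; any association
between host variables and the absorption class (host effects perturb
composition only, so fusing metadata cannot *improve* AUC here the way
it did in the real cohort — the tests only require that fusion not
degrade it); longitudinal structure beyond an optional single
after-intervention profile; and read-level sequencing noise.

## Numerical conventions

Rows are renormalized to sum 1 on every table construction (with a
logged notice past 1e-6 deviation); duplicate sample IDs and negative
abundances are hard errors. AUC ties count 0.5 (rank definition).
All random draws flow through explicit integer seeds (numpy
`default_rng`, XGBoost `random_state`), and the classifier runs
single-threaded histogram training, so identical configuration + seed
reproduce pipeline artifacts byte for byte. The pipeline manifest
records the SHA-256 of the canonical YAML config and the artifact list;
reruns verify against it.

## Known limitations

* Single-factor PERMANOVA only; covariate-adjusted or sequential
  partitions are out of scope, as are ComBat-style batch correction and
  domain-adaptation methods (the hybrid protocol is the point of
  comparison).
* The learning-curve selection optimism described above is inherent to
  the rank-then-CV protocol; treat small-k CV AUCs as relative, not
  absolute.
* Genus matching is exact string matching on `g__` names; no taxonomy
  reconciliation across annotation pipelines.
* With very small target cohorts (the study's second region had 7
  subjects) a single AUC is close to meaningless; use the replicate
  medians the tooling reports.
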