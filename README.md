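# sehybrid

Hybrid gut-microbiome modeling of individual selenium-absorption
efficiency.

Selenium supplementation does not work equally well for everyone: after
an identical two-month regimen, some people raise their hair selenium
content by ≥ 10 % (high-efficiency absorbers, **HE**) and some do not
(**LE**). `sehybrid` implements a machine-learning workflow that predicts
this efficiency class *before* supplementation from a subject's
genus-level gut-microbiome profile and routine host metadata — and, more
importantly, keeps that prediction usable when the test samples come from
a different sequencing batch or a different city than the training data.

The package is aimed at microbiome bioinformaticians working with 16S
genus tables (samples × genera relative abundances, `g__Name` columns)
plus per-sample clinical metadata.

## The method

1. **Labels.** absorption rate = (Se_after − Se_before)/Se_before × 100;
   HE iff rate ≥ 10 % (boundary inclusive).
2. **Community statistics.** Shannon (−Σ pᵢ ln pᵢ), Simpson (1 − Σ pᵢ²)
   and Chao1 (S_obs + F₁²/2F₂) alpha diversity; Bray-Curtis
   beta diversity; one-factor PERMANOVA (Adonis) with
   R² = SS_between/SS_total as each host variable's effect size on
   community composition (α = 0.01; any precomputed distance matrix can
   be substituted for Bray-Curtis).
3. **Biomarker refinement.** A gradient-boosted tree classifier
   (XGBoost) is trained on all genera; features are ranked by their
   split-count ("weight") importance, a learning curve over top-*k*
   prefixes locates the stabilization point, and the top 10 genera
   become the biomarkers.
4. **Host-variable fusion.** Gender, age (Young ≤ 35 / Middle 36–59 /
   Old ≥ 60), BMI (Low < 18.5 / Middle 18.5–23.9 / High ≥ 24),
   probiotics intake and health status are one-hot encoded — Male →
   (1, 0), Female → (0, 1), age 36 → (0, 1, 0), … — concatenated after
   the biomarker columns, and each sample row is L2-normalized.
5. **Hybrid cross-batch calibration.** A model trained on batch A is
   recalibrated for batch B by mixing n = 5…30 random batch-B samples
   into the training data and retraining (same hyperparameters),
   evaluating on a held-out 30 % of batch B, over 5 randomizations: the
   AUC-versus-n curve shows how many new samples absorb the batch
   effect.
6. **Cross-cohort feature screening.** Per-batch top-10 biomarker sets
   are intersected (Venn); a model rebuilt on only the shared,
   region-stable genera (metadata still fused) transfers to the other
   region's cohort far better than the unrefined model.

Performance is always the area under the ROC curve (AUC), equal to the
probability that a random HE subject outscores a random LE subject
(ties count ½).

Because the workflow needs multi-batch, multi-region cohorts to be
exercised at all, the package ships a first-class synthetic cohort
generator (`sehybrid.simulate`): a logistic-normal compositional model
with planted class-discriminative genera, categorical host-variable
effects, per-batch and per-region log-scale offsets, and selenium
measurements constructed to be consistent with the 10 % labeling rule —
so every pipeline stage can be validated against known ground truth.

## Worked example

```bash
sehybrid demo --seed 7 --out demo_run
```

simulates a 204-subject cohort (three sequencing batches, two regions,
ten planted discriminative genera of which three are region-stable) and
runs every stage. Selected output (`demo_run/summary.json`):

```
class_counts              HE 106 / LE 98
cv_auc.all_genus          0.932     # all 49 genera, 5-fold CV on batch 1
cv_auc.biomarkers         0.946     # top-10 genera only
cv_auc.fused              0.961     # top-10 + one-hot host variables
transfer_auc_new_batch    0.829     # batch-1 model applied verbatim to batch 2
cross_cohort_naive_auc    0.730     # region-1 model applied verbatim to region 2
cross_cohort_refined_auc  0.803     # rebuilt on the 3 shared biomarkers
shared_biomarkers         g__Genus000, g__Genus002, g__Genus005
```

Reading it: refinement and host-variable fusion improve the in-batch
model (0.932 → 0.961); applying the model unchanged to another sequencing
batch costs ~0.13 AUC (the batch effect); and in the cross-region
setting, keeping only the three biomarkers shared by all batches
recovers most of the loss (0.730 → 0.803). The learning curve
(`learning_curve.tsv`) stabilizes at k = 10 features (0.961), and the
calibration curve (`calibration_curve.tsv`) tracks AUC as batch-2 samples
are mixed in. The demo also writes the effect-size scan
(`effect_sizes.tsv`): batch and region dominate community variation,
with the absorption class far behind — exactly why naive cross-batch
prediction fails.

The same stages are available on your own data:

```bash
sehybrid biomarkers --abundance genus.tsv --metadata meta.tsv --top-k 10 --out ranking.tsv
sehybrid train      --abundance genus.tsv --metadata meta.tsv --out model/
sehybrid calibrate  --model model/ --base-abundance b1.tsv --base-metadata m1.tsv \
                    --new-abundance b2.tsv --new-metadata m2.tsv \
                    --n-mix 5:30:5 --repeats 5 --seed 0 --out curve.tsv
sehybrid adonis     --abundance genus.tsv --metadata meta.tsv --variable age_group
```

or from Python via `sehybrid.rank_features`, `sehybrid.train_bundle`,
`sehybrid.calibrate_hybrid`, `sehybrid.cross_cohort_refine`, …

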