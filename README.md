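# serfe

Entropy- and fractal-driven refinement of radiomics feature panels for
binary tumor classification (e.g. glioblastoma vs. other brain tumors on
T1/T2 MRI).

Radiomics extractors produce thousands of intensity, texture and shape
descriptors per patient, many of which are collinear, noisy or irreproducible
across repeated scans. Models trained on such panels overfit and transfer
poorly. `serfe` refines a raw patients × features table into a compact panel
that is information-dense, non-redundant and test–retest stable, then scores
its discriminative value with cross-validated classifiers. It is aimed at
radiomics researchers who already have a feature table (from any
IBSI-style extractor) or a segmented image volume, and want a reproducible,
auditable refinement step instead of ad-hoc post-hoc feature selection.

## Method

Starting from min–max normalized features `f_i ∈ [0,1]`, the pipeline applies
four transformations followed by two quality filters:

1. **Entropy weighting.** Each feature's Shannon entropy
   `H_i = −Σ_b p_b log₂ p_b` is estimated from an equal-width histogram of its
   cohort distribution. Features with `H_i` below a floor (default 0.5 bits)
   are discarded as uninformative; survivors are re-scaled by
   `f_i ← f_i · (H_i / H_max)^α`.
2. **Fractal augmentation.** The box-counting dimension `D_f` of each
   patient's binary tumor mask — the slope of `log N(ε)` vs `log(1/ε)` —
   summarizes lesion morphological complexity; every feature of patient *p*
   is shifted by `β·D_f(p)`.
3. **Adaptive weighting.** Each feature's cohort score `s_i` (mean over
   patients) is passed through `W_i = 1 / (1 + e^{−γ(s_i − μ)})` with `μ` the
   grand mean of scores; columns are re-scaled by `W_i`, and the per-patient
   weighted sum `Σ_i W_i f_i(p)` is kept as an auditable scalar summary.
4. **Redundancy filter.** Features are scanned in descending weight; a
   feature is dropped when its absolute Pearson correlation with an
   already-retained feature exceeds 0.85.
5. **Stability filter.** From repeated extractions, each feature's
   intraclass correlation `ICC = σ_b²/(σ_b² + σ_w²)` is estimated by one-way
   random-effects ANOVA; features with ICC < 0.75 are dropped. The stability
   score is the percentage of candidates with ICC ≥ 0.75.
6. **Evaluation.** Stratified 5-fold cross-validation with a linear SVM,
   a 200-tree random forest and 5-NN; balanced accuracy, precision, recall,
   F1 (percent) and rank-based ROC/AUC, with per-fold standardization fit on
   training folds only.

Every stage is also exposed as a scikit-learn style transformer
(`EntropyRefiner`, `AdaptiveWeighter`, `RedundancyFilter`, `StabilityFilter`,
`MinMaxNormalizer`) usable in sklearn pipelines. A compact image-feature
extractor (first-order statistics, 3-D GLCM texture over 13 directions,
mask shape descriptors, spectral entropy) turns NIfTI image + mask pairs
into feature rows, and a synthetic-cohort generator provides ground-truthed
inputs for every stage.

## Worked example

```python
from serfe import SyntheticCohortSpec, PipelineConfig, generate_cohort, run_serfe

base, labels, replicates, truth = generate_cohort(SyntheticCohortSpec(seed=7))
result = run_serfe(base, replicates=replicates, config=PipelineConfig(seed=7))

print(result.manifest.stage_counts)
fr = result.filter_report
print(f"redundancy rate {fr.redundancy_rate:.1f}%  stability {fr.stability_score:.1f}%")
for clf in ("svm", "random_forest", "knn"):
    ba = result.eval_report.summary[clf]["balanced_accuracy"]
    print(f"{clf}: BA {ba['mean']:.1f}% +/- {ba['sd']:.1f}, AUC {result.eval_report.auc[clf]:.3f}")
```

prints

```
{'initial': 300, 'post_entropy_filter': 290, 'post_redundancy_filter': 250, 'post_stability_filter': 212}
redundancy rate 13.8%  stability 84.8%
svm: BA 95.8% +/- 2.4, AUC 0.992
random_forest: BA 99.2% +/- 1.9, AUC 1.000
knn: BA 86.6% +/- 8.6, AUC 0.924
```

The funnel removed the 10 planted low-entropy columns, 40 near-duplicate
block members and 38 unstable features, keeping 212 of 300; all 20 planted
informative features survived, and the classifiers recover the planted
d = 1.5 class signal almost perfectly.

The same flow is available from the shell:

```bash
serfe simulate --out-dir sim --seed 7
serfe refine --features sim/features.csv --label-column label \
      --replicates sim/replicate_0.csv --replicates sim/replicate_1.csv \
      --replicates sim/replicate_2.csv --out-dir run --seed 7
serfe report --run-dir run
```

and `serfe extract --image t1.nii.gz --mask tumor.nii.gz --out features.csv`
computes the built-in panel from a segmented volume.

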