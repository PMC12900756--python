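# habitomics

Habitat radiomics for preoperative WHO/ISUP nuclear-grade prediction in
renal tumors — a tested, reusable reimplementation of the full analysis
pipeline: peritumoral ring geometry, K-means tumor subregion ("habitat")
segmentation with Calinski–Harabasz model selection, 1,015-feature radiomic
extraction per region, the ICC → z-score → univariate → correlation → LASSO
selection cascade, five-algorithm region modeling fused into a clinical
nomogram, and the complete evaluation statistics (DeLong AUC inference,
calibration curves, decision-curve analysis, Shapley attributions).

It is written for imaging scientists who want to run, audit, or extend a
habitat-radiomics study without access to the original patient data: a
seeded synthetic cohort generator produces 3-D contrast-enhanced-T1-like
kidney tumors with three planted intensity-distinct subregions, dual-reader
masks, and grade-linked covariates, so every stage is exercisable and
testable end to end.

## The model in brief

Voxel-wise local features (19 first-order statistics over a sliding 5×5×5
window inside the tumor VOI) are pooled across training patients, z-scored,
and clustered with K-means; the cluster count k is chosen by maximizing the
Calinski–Harabasz index

    CH(k) = [B/(k−1)] / [W/(n−k)]

over k = 2..10, where B and W are between- and within-cluster sums of
squared deviations. Habitats H1..Hk (ordered by descending mean-intensity
center) define subregion masks; each region (intratumoral, peritumoral rings
at 1–5 mm, habitats, integrated habitat) yields 1,015 radiomic features
(14 shape + 91 intensity/texture × 11 image types). Features pass ICC(2,1)
reliability filtering (≥ 0.75; habitat features exempt), normality-gated
univariate testing (p < 0.05), correlation pruning (|r| ≤ 0.9), and
ten-fold cross-validated LASSO. Region radscores (predicted probability of
high grade from the best of LR/SVM/RF/ExtraTrees/LightGBM, five-fold CV)
combine with the independent clinical predictor in a logistic nomogram.
Performance is compared with DeLong's test on paired AUCs and net benefit
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t).

## Worked example

```python
from habitomics import demo_config, run_pipeline

report = run_pipeline(demo_config(seed=1, n_patients=40), "demo_run/")
print(report["habitat"]["k"])
for name in ("Clinic", "Intra", "Peri2mm", "Habitat", "Combined"):
    m = report["metrics"]["test"][name]
    print(f"{name:9s} test AUC {m['auc']:.3f} ({m['ci_low']:.3f}-{m['ci_high']:.3f})")
```

On the 40-patient synthetic demo cohort this prints the selected habitat
count and the per-model test AUCs, e.g.

```
3
Clinic    test AUC 1.000 (1.000-1.000)
Intra     test AUC 0.926 (0.752-1.000)
Peri2mm   test AUC 0.778 (0.329-1.000)
Habitat   test AUC 0.889 (0.671-1.000)
Combined  test AUC 0.889 (0.671-1.000)
```

The CH index selected k = 3, matching the three planted subregions
(enhancing, necrotic, transitional), and the combined nomogram nests its
component models on the training set. Test-set intervals are wide — 12 test
patients, 3 of them high-grade — which is the point of the demo scale: it
exercises the pipeline mechanics, not clinical effect sizes.
`demo_run/` contains the full 12-model report (`report_models.csv`,
`report.json`), per-stage artifacts (habitat fractions, ICC report,
selection JSONs, nomogram points table) and a manifest whose config hash
makes reruns bit-identical.

A CLI wraps the same stages:

```bash
habitomics simulate --out cohort/ --seed 7
habitomics run-all --out run/ --seed 7
habitomics rings --mask cohort/P0000_mask_r1.nii.gz --distances 1,2,3,4,5 --out rings/
```

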