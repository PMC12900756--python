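# Methods

`habitomics` implements a habitat-radiomics analysis for preoperative
WHO/ISUP grade prediction in renal tumors: peritumoral ring geometry,
K-means tumor subregion ("habitat") segmentation, high-throughput radiomic
feature extraction, a multistep feature-selection cascade, five-algorithm
region modeling with nomogram fusion, and the full evaluation statistics
(DeLong AUC inference, calibration, decision curves, Shapley attributions).
Because no patient data ship with the package, a seeded synthetic cohort
generator provides the study conditions under which every stage is tested.

## Synthetic cohorts

Each patient is a 3-D contrast-enhanced-T1-like image (arbitrary units,
parenchyma at 100 ± 25) on an isotropic 1 mm grid (default 72³), containing
one smoothed, randomly deformed ellipsoidal tumor (radius 16–20 mm for
low-grade, 18–24 mm for high-grade patients). Three subregions are planted
along a random intratumoral axis, emulating the eccentric necrosis typical
of large renal tumors:

| habitat | reading | mean (a.u.) | texture SD (a.u.) |
|---|---|---|---|
| H1 | enhancing viable zone | 160 | 15 (white noise) |
| H2 | necrotic zone | 80 | 20 (white noise) |
| H3 | transitional zone | 120 | 45 (correlated speckle, ~0.8 voxel) |

The necrotic fraction is drawn per grade (0.15–0.28 low, 0.25–0.42 high);
the transitional band takes a further 0.35 of the tumor volume, leaving the
enhancing zone the largest compartment (as reported radiologically for such
tumors). The layout matters: early concentric-shell designs produced
subregions thinner than the 5³ local-statistics window, so windowed features
of almost every voxel mixed two habitats and no clustering could recover the
planted structure. Two planar-ish interfaces (eccentric layout) reduce
interface area roughly four-fold relative to concentric shells at the same
volume fractions. The transitional zone's strong correlated speckle is
equally deliberate: the three habitats then separate along *two* feature
axes (windowed mean and windowed dispersion) rather than lying on a single
intensity continuum, which is the geometry a Calinski–Harabasz-selected
K-means can recognize as exactly three clusters. Boundary voxels whose
windows straddle an interface remain genuinely ambiguous; they bound the
achievable label-recovery ARI at roughly (interface area × window half-width
/ tumor volume).

Grade effects are planted as in the cohort the generator emulates: ~27%
high-grade prevalence; larger radii and higher necrotic fraction in
high-grade tumors; P(low corticomedullary enhancement) = 0.27 given low
grade and 0.69 given high grade (the proportions in the emulated cohort's
baseline table), with low enhancement shifting the enhancing zone down by
12 a.u. A second reader's mask applies a smooth boundary jitter of up to
1 mm (Dice ≥ 0.7 against reader 1), so inter-rater (ICC) filtering is
exercised without being saturated. A multiplicative low-order bias field
(±15%) and a 0.4 mm Gaussian blur complete the image model. Not emulated:
MRI physics and artefacts, k-space sampling, organ anatomy, multi-sequence
data — so passing tests demonstrate the pipeline's correctness and the
recoverability of planted structure, not clinical performance.

## Preprocessing and ring geometry

Fixed order: bias correction → isotropic resampling → intensity
normalization. The default bias backend fits a degree-≤3 polynomial to log
intensities over the body region and divides out the exponentiated field
(unit geometric mean); SimpleITK's N4 can be substituted. Normalization is
a z-score over the whole body (non-air) region — not tumor-only — so habitat
intensity contrasts remain comparable across patients. Peritumoral rings at
1–5 mm are defined on the exact Euclidean distance transform of the tumor
mask in physical mm (voxel-centre to voxel-centre, ties at the distance
included), disjoint from the tumor and clipped at the image boundary; an
optional body-mask clip exists but is off by default.

## Habitat segmentation

A 5×5×5 window slides over the tumor VOI computing 19 first-order statistics
per voxel (window clipped to the mask; voxels with < 8 in-mask window
members flagged invalid). One K-means model is fitted on pooled, z-scored
training voxels — population-level clustering, so labels H1..Hk are
comparable across patients — for each k in 2..10 (k-means++, n_init = 10,
seeded), and k is chosen by maximizing the Calinski–Harabasz index on a
seeded subsample of up to 10⁵ voxels (cap chosen to keep desk-scale runs in
minutes; CH estimates are stable well below this size). Clusters are
relabeled H1..Hk by descending windowed-mean-intensity center. Test patients
are assigned with the training-fitted model only; invalid voxels inherit
their nearest valid neighbour's label so every habitat map partitions the
tumor mask.

## Feature extraction

Each region yields 1,015 features: 14 mesh-based shape descriptors from the
original geometry plus 91 intensity features (18 first-order, 22 GLCM, 16
GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM) on each of 11 image types — original, the
8 level-1 stationary coif1 wavelet sub-bands, and Laplacian-of-Gaussian at
σ ∈ {2, 3} mm. Discretization uses a fixed bin width of 25 on intensities
scaled by 100 (effective width 0.25 on z-scored images), bins anchored at
zero. Matrix conventions: 13 symmetric directions at distance 1 with
direction-averaged features (GLCM, GLRLM), 26-connectivity zones (GLSZM),
26-neighbour dependence with α = 0 counting the centre voxel (GLDM). The
mesh is built by marching cubes on a slightly pre-smoothed (σ = 0.7 voxel)
binary surface; without this anti-aliasing a voxelized sphere reads ~0.92
sphericity from staircase area, with it ~0.99 at ≤5% volume error. Regions
smaller than 10 voxels return a missing-flagged vector so absent habitats
flow into imputation rather than raising.

The integrated habitat region concatenates the three per-habitat vectors
(3,045 features, habitat-suffixed names). Missing habitat features are
imputed by a KNN imputer (k = 5) fitted on training rows only, distances on
standardized observed features; observed cells are never altered.

## Selection cascade

Fixed order, every stage fitted on training rows only: ICC(2,1) reliability
filter (two-way random effects, absolute agreement, single measurement;
threshold 0.75; habitat-region features exempt — they come from unsupervised
clustering with no second reading) → z-score (population SD; zero-SD columns
dropped) → univariate filter (per-class Shapiro–Wilk at α = 0.05 gates Welch
t vs Mann–Whitney U, keep p < 0.05) → greedy correlation pruning ordered by
ascending univariate p (drop |r| > 0.9 to a kept feature) → L1-penalized
logistic regression with stratified ten-fold CV over a 40-point log-spaced λ
grid (λ on the mean-deviance scale, C = 1/(nλ); minimum-deviance rule by
default, 1-SE optional). An empty LASSO selection is allowed and flagged.

## Modeling

Five algorithms (LR, SVM with Platt-scaled probabilities, RF, ExtraTrees,
LightGBM) are tuned by five-fold cross-validated AUC over small fixed grids
(tree counts {100, 300}, depths {3, unlimited}, C {0.1, 1, 10}, linear/RBF
kernels). The per-region "radscore" is the tuned model's predicted
probability of high grade. Algorithm selection policy: `cv` (default)
maximizes cross-validated AUC; `paper_faithful` maximizes test-set AUC and
emits an explicit selection-bias warning, since that choice reads test
labels. Ties break by the fixed order LR < SVM < RF < ExtraTrees < LightGBM.
Clinical covariates are screened univariately (logistic OR, 95% CI); those
with p < 0.05 enter one multivariate fit, and multivariate p < 0.05 defines
the independent predictors (perfect separation falls back to a ridge-
penalized fit, flagged). The combined nomogram is a logistic fit of grade on
the independent predictor(s) plus the intratumoral, 2 mm-peritumoral and
integrated-habitat radscores, with a conventional 0–100 points mapping
(largest |coefficient × input range| = 100 points).

## Evaluation

AUC is the Mann–Whitney pair-count statistic (ties ½); variance, CIs
(normal approximation truncated to [0, 1]) and paired model comparisons use
DeLong placement values (validated to machine precision against pROC).
Threshold metrics use the Youden-optimal threshold on *training* scores,
frozen for the test set (per-cohort optimization available but off by
default, as it leaks). Calibration uses equal-frequency bins plus the Brier
score; decision curves report net benefit TP/n − (FP/n)·p_t/(1−p_t) on a
0.01–0.99 grid with treat-all/treat-none references. Attributions are
Shapley values from telescoping marginal contributions averaged over sampled
feature permutations against a background set — each sample's attributions
plus the base value sum *exactly* to the model output — with LightGBM's
native tree-path attribution available for tree models (log-odds scale).

## Pipeline and problem sizes

`run_pipeline` chains simulate → preprocess → rings → habitat → extract →
select → train → evaluate, writing per-stage artifacts (CSV/JSON/optional
NIfTI) and a manifest with a canonical config hash; all stage seeds derive
deterministically from the master seed, so a rerun is bit-identical. The
demo configuration uses 40 patients on a 48³ grid with 10–16 mm tumors; the
habitat-recovery study uses 20-patient cohorts at the default 72³/16–24 mm
conditions over 20 replicate seeds. These sizes keep a full demo run in a
few minutes on one core while leaving every stage's statistics meaningful.

## Known limitations

- Boundary-voxel ambiguity bounds habitat ARI below ~0.9 at these tumor
  sizes; the planted-recovery claims hold for the stated geometry, not for
  arbitrarily small tumors.
- The univariate filter tests features one at a time; a feature informative
  only jointly can be lost before LASSO.
- The generator's covariates are few and clean; clinical screening on real
  tables (missingness, coding ambiguity) needs care the demo does not need.
- DeLong inference is asymptotic; with perfect separation the CI degenerates
  to a point and is flagged.
- Permutation-Shapley cost grows with features × permutations × background;
  the pipeline limits attribution to the selected habitat features and a
  subsampled background.
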