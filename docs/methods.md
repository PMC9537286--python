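# Methods

`rgx` re-implements, as a tested pipeline, an integrated radiogenomics
analysis for locally advanced head and neck squamous cell carcinoma
(HNSCC): CT radiomics feature extraction with stability filtering and batch
harmonisation, transcriptome-based molecular subtyping and metagene
scoring, and their combination into classification and prognostic models
with a strict discovery/validation split. Because no patient data ship
with the package, a synthetic cohort generator provides paired
image/expression/outcome data with planted, recoverable structure; every
downstream stage is exercised and tested against it.

## Image pre-processing and features

Planning-CT volumes and gross tumour volume (GTV) masks are resampled to a
1 mm isotropic grid (tricubic splines for intensities, trilinear + 0.5
threshold for masks). The region of interest is re-segmented to the closed
Hounsfield window [-150, 180]: voxels outside (air cavities, bone) are
excluded from intensity-based features rather than clamped, while
morphology always uses the full delineated mask. A response map is built
as the voxelwise mean of Laplacian-of-Gaussian filters at kernel widths
1-5 mm; the separable kernels are sampled Gaussians whose second-derivative
component is moment-corrected to exact zero DC response, and derivatives
are expressed per mm^2 so the response does not depend on the sampling
grid. Grey levels for histogram and texture features use fixed-bin-number
discretisation (default 32 bins) over the in-mask min-max range.

Five feature families are computed: first-order statistics, local
intensity peaks (mean in a 1 cm^3 sphere, via FFT convolution),
morphology (voxel-counted volume exported in cm^3 as the GTV feature,
marching-cubes surface area, sphericity, maximum 3D diameter, and the
axis-aligned bounding-box volume density `morph_vol_dens_aabb`), intensity
histogram, and texture (GLSZM with 26-connectivity, GLCM and GLRLM merged
over the 13 unique directions at distance 1). The LoG response map only
receives the statistical and intensity-histogram families: morphology does
not depend on intensities, and LoG texture is structurally unstable, so
neither is ever emitted for it. Degenerate single-voxel regions yield NaN
for undefined texture features and are flagged rather than silently
dropped. Volume and bounding-box density are voxel-counted (not mesh
volumes): the internal oracles are voxel-based and the downstream models
never mix the two conventions.

## Stability filtering and harmonisation

Feature robustness is probed by recomputing features on perturbed copies of
each discovery image: rotations of -4, -2, 0, 2, 4 degrees about the
cranio-caudal axis crossed with contour volume changes of -20, -10, +10,
+20 %, i.e. 20 variants per patient. Volume changes threshold the signed
Euclidean distance transform at an offset found by bisection; on a discrete
grid the boundary shell contains many equidistant voxels, so the shell is
split deterministically (stable voxel order) until the achieved count is
within 1 % of the target. Stability per feature is the one-way
random-effects ICC(1,1) across variants — the variants are exchangeable
"raters", which the one-way form assumes — with a 95 % CI from the
F-distribution; features whose CI lower bound falls below 0.75 are dropped
for both cohorts.

Scanner/centre batch effects are corrected by reference-batch ComBat. For
imaging, the reference population is found by consensus clustering:
features are z-scored, projected onto the PCA components covering 90 % of
variance, and complete-linkage clustering of 80 % patient subsamples (100
resamples) builds a co-clustering frequency matrix for each k in 2..6; the
reference set is the largest patient group that is pairwise co-assigned at
every k, and the remaining outliers are ComBat-aligned to it. Note that
forcing k >= 2 partitions on structureless data necessarily splits it, so
the reference is "the largest stable subset", not necessarily everyone.
The ComBat core standardises features by the reference batch's mean and
variance and shrinks per-batch location/scale effects by empirical Bayes —
parametric (normal/inverse-gamma priors solved by iterated moments) or
nonparametric (posterior means weighted on the empirical effect grid). A
plain `direct` mode without shrinkage is also provided; it is the only
mode that is exactly idempotent, which the tests exploit. The reference
batch is returned bit-unchanged in all modes. The same core harmonises
expression batches (study of origin, discovery as reference).

## Transcriptome side

Molecular subtypes (atypical, basal, classical, mesenchymal) are assigned
by median-centring each profile over the genes shared with the centroid
file and correlating with each subtype centroid (Pearson); a sample stays
unclassified when its best correlation is below 0.2 or the gap to the
runner-up is 0.2 or less (the asymmetry — strict `< 0.2` versus `<= 0.2`
gap — is deliberate and matches the published rule). Median-centring uses
the centroid-shared gene subset so the operation is self-contained given
only the centroid file.

Gene-signature surrogate classes are built by k-means (k = 2, 10 restarts)
on per-gene z-scored signature expression in the discovery cohort; class 1
is the cluster with higher mean signature expression. Validation samples
are assigned to the nearest stored centroid by Euclidean distance with the
stored z-parameters (ties to class 1), so transfer is leak-free by
construction.

GSVA metagene scores use the Gaussian kernel CDF with bandwidth s_i/4 per
gene, per-sample decreasing rank with symmetric weights |rank - (p+1)/2|
(tau = 1), and a weighted Kolmogorov-Smirnov-like random walk whose signed
maximum deviation is the score, bounded in [-1, 1]. Ranking ties break by
gene order after a stable sort. Because the kernel CDF couples samples,
scores are computed separately per cohort by the caller; the pipeline does
this for discovery and validation to avoid information leakage. The final
metagene pair (hallmark hedgehog signalling and E2F targets) is a
configuration list, standing in for the literature filter that selected
them.

## Model development

Redundant features are collapsed by complete-linkage clustering on
1 - |Spearman rho| cut at 0.3; each cluster is represented by the feature
with the highest mean absolute correlation to its co-members. For the
prognostic radiomics signature, features with |rho| > 0.5 against tumour
volume are discarded first and the GTV is always forced into the model.

Features are Yeo-Johnson transformed (lambda by maximum likelihood over
[-3, 3]) and z-standardised; parameters are estimated on discovery only and
applied frozen to validation. Feature selection runs minimum-redundancy
maximum-relevance (mutual information on 4-bin equal-frequency
discretisation, quotient criterion, name-order tie-breaks) inside 33
repetitions of stratified threefold cross-validation; each fold also
searches the model size 1..10 by inner 3-fold AUC (classification) or
concordance (survival; MRMR relevance uses the event-within-24-months
indicator). Fold selections are aggregated by the enhanced Borda score —
for a fold selecting M features, rank r contributes (M - r + 1)/M, summed
and divided by the total number of folds — and the final model uses the
top-ranked features at the half-up-rounded median fold size.

Final models are one-versus-all ridge logistic regressions (IRLS with the
penalty chosen from {0, 0.01, 0.1, 1, 10} by inner 3-fold AUC; the ridge
grid replaces Bayesian hyperparameter optimisation for reproducibility and
desk-scale runtime; Wald CIs from the penalised Fisher information) and
Cox proportional hazards models (Efron ties, Breslow baseline, Wald CIs;
fitted through lifelines). Both are exposed statsmodels-style: model
objects built from data whose `fit()` returns a results object with
coefficients, CIs, p-values, a `summary()` table, prediction and JSON
persistence.

## Evaluation

Discrimination: trapezoidal AUC and Harrell's C with percentile bootstrap
CIs (600 resamples). The f1 cutoff is chosen on discovery among observed
score midpoints whose median bootstrap f1 exceeds the reference value
2*pi/(1 + pi) — the f1 of an always-positive classifier, which maximises
expected f1 among label-independent rules — taking the candidate with the
highest CI lower bound; validation reuses the stored cutoff. Calibration:
Hosmer-Lemeshow (deciles of risk, df = g - 2; the df convention presumes
the probabilities come from a fitted model, which is how both the pipeline
and the null simulations use it) and the Greenwood-Nam-d'Agostino test at
24 months (risk-decile groups merged until each has at least two events
and a non-degenerate Greenwood variance; df = groups - 1, again assuming
fitted predictions). Risk stratification scans observed-risk midpoints
between the 10th and 90th percentiles for the threshold minimising the
discovery log-rank p; validation is split at the frozen threshold.
Proportional hazards are checked by the Grambsch-Therneau test on
Schoenfeld residuals with the Kaplan-Meier time transform; the
implementation reproduces lifelines' `proportional_hazard_test` to
numerical precision and adds the global statistic.

## Synthetic cohort

The generator emulates the study conditions: 122 discovery and 84
validation patients, subtype proportions 15.6/18.5/8.3/11.2 % with the
remainder unclassified (truth mixtures of two centroids, so the ambiguity
rule has positive cases). Tumours are spheres perturbed by sharpened
positive lobes of random degree-2..4 spherical harmonics — protrusions
stretch the axis-aligned bounding box while adding little volume, so the
`shape` dial lowers `morph_vol_dens_aabb` — filled with a Gaussian random
field whose amplitude grows and correlation length shrinks with the
`texture` dial, so size zones fragment and `szm_glnu` rises with it.
Air-like (-800 HU) and bone-like (+400 HU) inclusions exercise the HU
re-segmentation. Atypical tumours get reduced shape/texture dials and
slightly smaller size, mirroring the observation that atypical HNSCC is
more regular and homogeneous on CT; this is the signal the radiomics
subtype classifier recovers. Expression is centroid + Gaussian noise +
per-batch shift/scale; two planted gene-set activations (bimodal, with
per-gene loadings) define the true signature classes and metagene signal.
Survival times are exponential under a ground-truth Cox model on the
z-scored design of extracted image features and planted activations
(default per-SD log-hazard coefficients: log_stat_p90 0.5, tumour volume
0.3, hedgehog 0.5, E2F -0.4); censoring is an independent uniform draw
whose upper bound is calibrated by bisection to the requested censoring
fraction (default 35 %). All randomness flows from one root seed through
named substreams, so a fixed seed regenerates byte-identical cohorts.

What the generator does not emulate: CT physics (noise spectra,
reconstruction kernels, beam hardening), multi-lesion patients, realistic
gene-gene correlation structure, or non-exponential baseline hazards.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under controlled conditions, not that it would reach the
published effect sizes on real patients.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 122/84 design but with
scaled-down problem sizes chosen for desk-scale runtime: tumour diameters
around 13 mm at 1 mm isotropic spacing and a 280-gene universe (120
centroid genes + 160 others) instead of whole-transcriptome scale. The
discretisation and texture aggregation defaults (32 bins; merged 13
directions) are declared choices, config-overridable. Ties everywhere
break deterministically (name order, lower index, smallest threshold), and
bootstrap/cross-validation randomness is fully seeded. Known limitations:
the GLCM/GLRLM use merged-matrix aggregation rather than per-direction
feature averaging; mesh surface area is float32 (from marching cubes), so
geometric invariances hold to ~1e-6 relative rather than machine
precision; and empirical-Bayes ComBat is only asymptotically idempotent.
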