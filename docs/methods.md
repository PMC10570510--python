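# Methods

`habitatct` implements a habitat-imaging pipeline for inflamed lung CT: it
partitions the lung into phenotypically coherent subregions ("habitats"),
quantifies each patient with a bank of multiregional spatial interaction
(MSI) features, and classifies infectious pneumonia against immune
checkpoint inhibitor (ICI) pneumonitis, reporting Bayesian pre-/post-test
probabilities. Because the clinical CT data this kind of analysis is run
on cannot be redistributed, the package ships a synthetic phantom
generator that plays the role of the study cohort; everything downstream
is tested against it.

## Phantom generator

Each phantom is a 3-D HU volume (default 128 x 128 x 16 voxels at
1 x 1 x 2.5 mm) containing two disjoint ellipsoidal lung fields,
mirror-symmetric about the x midline. Five tissue classes are planted:

| class | mean HU | noise sd (HU) | role |
|---|---|---|---|
| parenchyma | -870 | 10 | aerated background |
| transition, low grade | -670 | 120 | coarse reticular pattern |
| transition, high grade | -460 | 14 | smooth haze |
| ground-glass opacity | -350 | 70 | heterogeneous GGO |
| consolidation | +20 | 20 | airspace filling |

Voxel values are the class mean plus Gaussian noise with a class-specific
standard deviation (base `noise_sd` = 20 HU times a per-class texture
multiplier), truncated at -180 HU for every class except consolidation:
sub-solid tissue never reaches soft-tissue attenuation, which also keeps
the mediastinal window blank outside consolidation, as on real lung CT.
The minimum separation between adjacent class means is 110 HU, at least
five times the base noise sd. Each tissue class is distinct in *both*
attenuation and texture; the two transition grades differ in texture
direction (coarse vs smooth), so the five classes spread across two
feature axes rather than sitting on a single intensity chain.

Lesions are hard-edged ellipsoids (radii ~9-13 voxels in-plane) planted
mostly non-overlapping, each patch a single tissue class. Pneumonia-like
phantoms (`condition=0`) use a consolidation-dominant recipe, all in one
lung; pneumonitis-like phantoms (`condition=1`) a GGO-dominant recipe
with small consolidation foci. The left/right symmetry knob is
volume-preserving: every lesion gets a same-class partner, mirrored into
the contralateral lung with probability `symmetry` (default 1.0 for
pneumonitis, 0.0 for pneumonia) or reflected anterior-posteriorly within
the same lung otherwise. Lesion centers are confined to the anterior
half so the partner's territory is disjoint. Total lesion burden is
therefore statistically identical between the two conditions; the
left/right arrangement is the discriminating signal. With
`matched_composition=True` both conditions share one recipe, making
asymmetry the *only* class signal — the configuration used to show that
whole-lung radiomics (blind to arrangement) falls to chance while the
habitat model does not.

What the phantoms do *not* emulate: airway/vessel anatomy, scanner noise
spectra, partial-volume gradients at lesion rims (planted classes are
patches, not concentric rims), respiratory or reconstruction artifacts,
and any correlation between imaging and the clinical covariates. Passing
tests therefore demonstrate that the pipeline recovers the signals it is
designed for, not that it would reach any particular accuracy on patients.

The paired clinical/blood table draws binary symptoms (cough, fever,
shortness of breath at baseline and at syndrome), age, sex, and nine
blood measurements per patient. Blood counts are log-normal (positive,
right-skewed; the models later log-transform WBC and platelets), with
class-conditional medians echoing the study cohort (e.g. baseline
platelets 34 vs 29 x 10^3/uL). `ClinicalEffectConfig.zero_effects()`
removes all class effects for null-calibration tests.

## Preprocessing

The composite image stacks four channels in [0, 1]: lung-window
(center -600, width 1500 HU) and mediastinal-window (center 40, width
400 HU) clip-and-rescale normalizations — the standard radiology
conventions, both configurable — plus the local-entropy map of each.
Entropy is computed per axial slice (2.5 mm slices are too thick to mix),
as the Shannon entropy (bits) of the 32-bin intensity histogram in a disk
neighborhood, divided by log2(32). The neighborhood is restricted to the
lung mask so boundary voxels measure lung texture, not the lung/soft-tissue
edge. The module default radius is 4 voxels (a GGO-scale window at
clinical in-plane resolution); the pipeline configuration uses radius 2,
matched to the phantom scale where lesions are only ~20 voxels across.
Windowing itself is the contrast-enhancement step — a monotone map, so
no histogram equalization is applied and results are reproducible.
Fusion is channel stacking, not blending, because superpixel statistics
are defined per channel. Masks are smoothed by morphological closing;
lungs are split into left/right by connected components (largest two,
with a midline fallback and warnings for degenerate masks).

## Habitat detection

**Patient level.** Each axial slice is oversegmented with SLIC restricted
to the mask, targeting ~700 superpixels per volume (shares proportional
to slice mask area), compactness 0.1. Segmentation is driven by the two
intensity channels: the entropy channels carry a blurred ridge along
every tissue edge that otherwise pulls superpixel boundaries off the true
edge (measured lesion-class purity rises from ~0.83 to ~0.95+). Each
superpixel is summarized by ten statistics — skewness, kurtosis, mean,
median, Q1, Q3, IQR, sample standard deviation, variance, energy (mean of
squares, size-invariant) — on each of the four channels: 40 features.
Degenerate (constant) superpixels get skewness = kurtosis = 0.

**Population level.** Superpixel rows are pooled across patients,
standardized, subsampled (stratified by patient, seeded, default <= 3000
rows), and clustered with agglomerative Ward/Euclidean clustering.
Standardization is min-max (each feature rescaled to [0, 1] by its pooled
range) rather than z-scoring: several features are informative only
inside a minority habitat (the mediastinal-window statistics are
non-degenerate only in consolidation), and dividing such a feature by its
tiny pooled standard deviation amplifies estimation noise by the inverse
square root of the habitat's frequency, visibly degrading cluster
recovery. Habitat labels are canonically reordered by ascending
lung-window mean intensity, so SR1 is always the most aerated habitat
(parenchyma) and SR-K the densest (consolidation), stable across runs.
Assignment maps every superpixel to its nearest centroid (Euclidean in
standardized space; ties to the lowest label), and its voxels inherit the
label.

**Choosing K.** `select_k_gap` implements the Tibshirani gap statistic:
Ward-cluster the rows and B uniform-over-bounding-box reference draws,
and return the smallest K with Gap(K) >= Gap(K+1) - s(K+1). On
well-separated clusters with roughly isotropic within-cluster dispersion
this rule is reliable (it recovers planted Gaussian mixtures exactly, and
those cases are unit-tested). On the 40-statistic superpixel bank it is
not: the ten statistics of one sample are intrinsically correlated, so
within-habitat clouds are strongly anisotropic; Ward then gains more from
every additional split than the isotropic uniform reference does, and the
gap curve rises monotonically to the top of the range. This is a
structural property of the criterion, reproducible with synthetic
Gaussians given a shared anisotropic covariance, and insensitive to the
reference variant (PCA-aligned boxes, k-means inertia curves, subsample
size). `fit_population_clusters` therefore cross-checks the gap result
against the dendrogram: when the gap rule saturates (returned K equals
the top of `k_range` with no elbow — reported with a warning), K falls
back to the largest relative merge-height jump in the dendrogram. On the
default phantoms this selects K = 3: the hierarchy is genuinely dominated
by the parenchyma / sub-solid / consolidation super-groups, with the two
transition grades and GGO as sub-structure. Cutting at K = 5 recovers
the five planted classes at 0.86-1.00 cluster/truth matching, so the
five-class structure is present but less prominent than the three-way
split; no automatic prominence rule we examined prefers 5 over 3 on this
data. Analyses that need the planted habitat count pass `k=5` explicitly.

## MSI features

From a K=5 habitat map, 44 whole-lung features in fixed order: four
co-occurrence (GLCM) statistics of the habitat labels — contrast,
correlation, homogeneity, energy, with the matrix built from the four
in-plane unit offsets at distance 1 (slice spacing is much larger than
in-plane spacing), symmetrized and normalized; a constant map has
correlation defined as 0 — then absolute subregion volumes (SR1-SR5),
absolute subregion-to-border interactions, the ten absolute pairwise
interactions in order (1,2)...(4,5), and their normalized counterparts.
"Interaction" is face adjacency (6-connectivity in 3-D): a pairwise
interaction counts adjacent voxel pairs straddling two habitats, a border
interaction counts habitat voxel faces exposed to non-mask voxels
(including the grid boundary). Normalizers: volumes by mask voxel count,
border interactions by total boundary face count, pairwise interactions
by total adjacent in-mask pair count. The full 88-vector appends the
left/right symmetric-difference block: |MSI_L - MSI_W| x |MSI_R - MSI_W|
elementwise, with the left, right, and whole blocks each computed
independently on its own mask (the whole-mask block is not the sum of the
sides). A machine-readable feature dictionary maps each MSI name to its
definition. All counts are verified against brute-force voxel-pair
enumeration in the test suite.

The whole-lung radiomics comparator applies the same ten-statistic bank
to all mask voxels of each composite channel plus the four GLCM
statistics of the 32-level-quantized lung-window channel (44 values). It
sees composition but not arrangement, which is exactly the contrast the
habitat model is designed to expose.

## Diagnostic models

Features are ranked univariately by a chi-square test of the
quantile-binned feature (4 bins; binary features as-is; no continuity
correction) against the label, scored as -ln(p) (p floored at 1e-300;
constant features get p = 1), ties broken by feature name. The
classifier is an ensemble of 100 boosted classification trees, realized
as adaptive boosting of depth-2 trees with learning rate 0.5. Class
imbalance is handled by SMOTE (synthetic minority points interpolated
between a minority sample and one of its k = 5 nearest minority
neighbors, k reduced automatically in small folds), implemented
in-package and applied strictly inside each training fold of
leave-one-out cross-validation: the held-out sample is removed before
ranking, oversampling, or fitting — the leakage-safe reading, enforced
by a probe test that compares against a permuted-label baseline.
`select_top_k` grows the model over a feature-count grid and keeps the
accuracy-maximizing k (ties to the smaller k). The clinical-blood
benchmark uses 17 columns: six symptom indicators, age, sex, and nine
blood measures with WBC and platelets replaced by natural logs at both
timepoints (floored at 1e-6). The composite model concatenates the 88
MSI and 17 benchmark columns and refits the same pipeline. The cascade
rule diagnoses when the benchmark and habitat models agree and labels
disagreements "ambiguous"; the ambiguous rate equals the disagreement
rate by construction.

## Bayesian reporting

Pneumonitis (coded 1) is the positive class everywhere. From a
cross-validated confusion matrix: accuracy (TP+TN)/n, sensitivity
TP/(TP+FN), specificity TN/(TN+FP) (empty denominators give 0 with a
warning). The pre-test probability is the prevalence; the post-test
probability given a positive call is sens*prev / (sens*prev +
(1-spec)(1-prev)), which equals the prevalence exactly when the positive
likelihood ratio is 1, and is monotone in both sensitivity and
specificity (property-tested). Percentages are rounded half-up to whole
percents, matching the granularity of published diagnostic tables; raw
probabilities are always retained in the JSON reports. One arithmetic
note: with prevalence 0.23, sensitivity 0.48, specificity 0.88 the
formula gives 0.5444, i.e. 54% at whole-percent rounding (55% is obtained
only with an unrounded sensitivity near 14/29 = 0.483).

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 12-21 phantoms at
96-128 px in-plane with 16 slices, ~700 superpixels per patient,
gap references B = 8-10, and cluster-fitting subsamples of <= 3000 rows —
sizes at which each stage's behavior is measurable in seconds to minutes
while leaving all algorithmic parameters at their defaults. Determinism:
every stochastic step takes an explicit seed; per-patient and per-fold
seeds are derived with `numpy.random.default_rng([seed, index])`; SLIC
and Ward are deterministic given their inputs. Degenerate inputs are
defined, not special-cased at call sites: constant superpixels (zero
skew/kurtosis), all-identical cluster rows (K = 1 with a warning),
single-label GLCM (correlation 0), empty masks (errors), fused lung
masks (midline split with a warning).

## Known limitations

- Habitat-count selection resolves the dominant hierarchy level (3
  super-groups on phantoms), not necessarily the planted class count; see
  "Choosing K" above.
- Voxel-level habitat/truth agreement on phantoms is ~0.7-0.85, bounded
  by partial-volume superpixels at lesion boundaries and entropy-window
  mixing; at zero noise the texture signatures vanish and agreement does
  not improve.
- The phantom cohort is far easier to classify than real patients
  (cross-validated accuracies near 1.0 under matched composition); the
  printed accuracies of any clinical study are not reproducible from
  synthetic data and are not targets of this package.
- The clinical covariate generator draws each column independently given
  the class; real covariates are correlated.
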