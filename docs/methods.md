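# Methods

This note documents the models, algorithms and design decisions behind
`braingmm`, and what its synthetic-data validation does and does not show.

## The intensity-mixture model

A segmented region's pixel intensities are treated as i.i.d. draws from a
K-component univariate Gaussian mixture p(x|λ) = Σ wᵢ N(x; μᵢ, vᵢ).  K = 3
by default: bright gliomas typically show a dark (necrotic/edematous), a
mid, and a bright (enhancing) intensity population, and three components
describe the region histograms well while keeping the feature vector short.
The fitted λ is flattened into R = [w₁…w₃, μ₁…μ₃, v₁…v₃], with components
ordered by ascending mean and mean ties broken by descending weight, so the
vector is a canonical function of the fitted mixture.

**Fitting.** Maximum-likelihood EM, not least-squares curve fitting of the
histogram envelope: the mixture is a probability density, and EM's ascent
property gives a clean convergence diagnostic (the per-iteration
log-likelihood trace is stored on the results object and asserted
non-decreasing in the tests).  Histogram input is treated as weighted
samples at bin centers, which agrees with raw-sample fits to within binning
error and lets the same code serve images and precomputed histograms.

**Numerical choices.**
- Initialization is deterministic: component means at the (i/(K+1))-th
  weighted quantiles (25/50/75 % for K = 3), equal weights, pooled variance.
  A seeded k-means initializer is available but not the default, so repeated
  fits are bit-reproducible without a seed.
- Convergence: relative log-likelihood change < 1e-8 or 500 iterations.
- Variance floor: 1e-6 × the sample variance (never below 1e-12), applied
  every M-step.  Degenerate inputs (all pixels equal, K > 1) converge to
  floored components instead of collapsing; the floor can in principle break
  exact monotonicity, which is why the ascent assertion carries a 1e-10
  slack.
- Components are renormalized and sorted once at the end.

## Segmentation

Multilevel Otsu: the m thresholds maximizing the between-class variance are
found by exhaustive search over all increasing tuples of histogram bin
centers.  For the default 256 bins and m = 3 this is C(255,3) ≈ 2.7M
candidates, evaluated vectorized from prefix sums in well under a second
(the candidate table is cached).  Exactness was preferred over the usual
dynamic-programming or coarse-to-fine speedups because the search is cheap
at this size and the result is then provably optimal; scores equal up to
float accumulation error (relative 1e-10) count as ties and resolve toward
the lexicographically smallest tuple, making the output deterministic.
Quantization uses half-open bands [0..t₁], (t₁..t₂], …, (t_m..max].

Skull stripping takes the largest 8-connected non-background component after
removing border-touching components, then erodes with a disk (default
radius 5) to peel the bright skull ring.  Because the skull dominates the
top whole-image band, the pipeline re-runs Otsu restricted to the brain
mask before picking the tumor band — without this, a bright skull remnant
rather than the lesion would define the top class.  Tumor extraction keeps
the highest brain-band (configurable, since T2/FLAIR contrast can differ),
applies a disk-2 opening, removes components under 30 px, and returns the
largest component.  A "no tumor detected" condition is a distinct exception,
reported and excluded at the cohort level rather than aborting a run.

The normal-brain reference region is a same-area quasi-disk of brain pixels
centered at the interior point farthest from the tumor mask.  Equal area
keeps the two regions' mixture fits comparably conditioned; maximal distance
minimizes partial-volume contamination.  This sampling policy is a package
convention — clinical studies rarely state theirs.

## PCA and wavelet baselines

PCA operates on the sample covariance (denominator n−1) of the feature
matrix; eigenpairs come from a symmetric eigendecomposition, sorted by
descending eigenvalue with a deterministic sign convention
(largest-magnitude loading positive).  Projection centers rows by the
basis's mean vector — covariance-based PCA presumes centered data — with a
`center=False` mode for the literal uncentered projection.  Three components
are retained by default; a variance-fraction mode (e.g. 0.97) picks the
smallest k reaching that cumulative share.  For classification the basis is
fitted on the pooled training fold inside each CV split (a held-out sample
has no class, so per-class bases would leave its projection undefined);
descriptive per-class bases remain available separately.

Wavelet features use level-1 separable DWTs (db1, coif1) on the region's
bounding box, out-of-mask pixels filled with the region mean and the box
zero-padded to even sides.  The transform uses orthonormal filters with
**periodized** extension so that it is an exact orthonormal change of basis
on even-sided inputs — coefficient energy equals image energy to machine
precision, which the tests assert at 1e-8 relative.  (Symmetric extension
was considered and rejected: for filters longer than Haar it produces
redundant coefficients and breaks Parseval.)  Each subband is summarized by
its mean, population standard deviation, and the Shannon entropy (bits) of
the 64-bin histogram of absolute coefficients, with 0·log 0 = 0 and a
degenerate-range guard so numerically constant subbands report zero entropy.

## Classifiers and evaluation

- **Kernel naïve Bayes**: per class and per feature, a Gaussian KDE with
  Silverman bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5), floored at 1e-3 of the
  feature's global spread so zero-spread features cannot produce singular
  densities; the class score is the prior times the product of feature
  densities, computed in log space.
- **RBF SVM**: soft-margin SVC, C = 1, gamma = 1/(d · pooled variance);
  signed decision values oriented so positive means tumor.
- **PNN**: Parzen-window posterior, isotropic Gaussian kernels of bandwidth
  `spread` (default 0.1 on standardized features) averaged per class.

Features are z-scored with training-fold statistics by default (all three
kernels are scale-sensitive).  Leave-one-out CV holds out one region per
fold, or one patient's regions together in grouped mode.  Accuracy, false
alarm and missed detection all divide by the total sample count, so they sum
to 100 % identically — an invariant asserted on every evaluation.  AUC is
computed from the score sweep and equals the Mann–Whitney pair statistic
(ties counted ½), which the tests verify against a brute-force pair count.

## The phantom and what passing means

The generator emulates only the structure the chain relies on: an elliptical
brain of mixed "normal" intensities, a bright skull ring (intensity 245), a
circular tumor blob whose pixels follow a declared 3-component mixture, and
additive Gaussian noise (sd 4, clipped to [0, 255]; a Rician option exists
for realism).  Defaults: 128-px rasters (segmentation behavior does not
depend on the acquisition matrix, and the smaller raster keeps full-cohort
runs fast), normal means 70/100/130 vs tumor means ≈170–230, i.e.
well-separated classes; cohorts of 17 patients × 3 pseudo-sequences (51
images) with per-patient jitter of tumor position (±4 px), radius (±15 %)
and mixture means (±5 gray levels) from one seeded stream.

What the phantom does **not** emulate: bias-field inhomogeneity, partial
volume at tissue boundaries, anatomy (ventricles, gyri), infiltrative tumor
margins, or sequence physics.  Passing tests therefore demonstrate the
correctness of the algorithms and the internal consistency of the chain
under its stated assumptions — not clinical segmentation or classification
performance.  On real data, the bright-band assumption, the erosion-based
skull strip and the normal-region policy would all need validation.

Test problem sizes are the package's own choices: 50,000 draws for mixture
recovery (means within ±2 gray levels, weights ±0.02, sigma ±10 %), 200
random histograms (≤64 bins, m ≤ 3) for the exhaustive-Otsu oracle, and the
full 51-image cohort for the end-to-end discrimination check (tumor Dice
≥ 0.90, kernel-NB LOOCV ≥ 95 %, and chance-level accuracy after label
shuffling).

## Known limitations

- Single bright lesion per slice: multifocal tumors return only the largest
  component.
- The tumor band default (highest class) assumes lesion-bright contrast;
  dark-lesion sequences need `tumor_band` set explicitly.
- EM with K fixed at 3: no automatic order selection (BIC/AIC) and no
  multivariate mixtures.
- LOOCV on small cohorts has high variance; the pooled mode and grouped
  (per-patient) folds are provided but cannot fix the sample size.
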