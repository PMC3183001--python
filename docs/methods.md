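# Methods

## Data model

An imaging MS dataset is a grid of pixel spectra on a shared, strictly
increasing m/z axis (`MSIDataset`); after feature extraction it becomes a
pixels × features matrix with per-feature integration windows and per-pixel
provenance (`ReducedDataset`). Coordinates are 0-based `(x, y)` with `x` the
column; imzML's 1-based coordinates are shifted on read and restored on
write. Processed-mode imzML (per-pixel axes) is resampled onto the union of
all axes by linear interpolation, with zero intensity outside a spectrum's
own range.

Zero-TIC pixels are retained, not dropped: total-ion-count normalization
leaves them as zero vectors and reports their indices, so image geometry is
preserved through the whole pipeline.

The interchange format for reduced data is plain tab-separated text with a
JSON metadata header (dataset id, normalization state, feature list) and
columns `x, y, source_id, src_x, src_y, off_x, off_y, <one per feature>`.
Floats are written with `repr` and parsed with round-trip precision, so
write→read is bit-exact.

## Preprocessing

Each pixel spectrum is smoothed and then baseline-corrected, in that order.

**Smoothing** is repeated convolution with a unit-area Gaussian whose
full-width-at-half-maximum is `smooth_width_mz` (default 2 Da, 4 cycles).
"Width" is interpreted as FWHM — the common vendor convention; the constant
is configurable. The convolution is evaluated in the DCT domain with the
transfer function `exp(-σ²ω²/2)`: this *is* the symmetric-boundary
convolution, conserves total intensity exactly (the DC coefficient is
untouched), and composes exactly — n cycles equal one pass with n-fold
variance, which a truncated sampled kernel only approximates. A non-uniform
axis is rejected with instructions to resample.

**Baseline** is the lower convex hull of the (m/z, intensity) points,
computed by a monotone-chain sweep and linearly interpolated between hull
vertices. The corrected spectrum is non-negative everywhere and exactly zero
at hull vertices; adding a constant to the input leaves the output unchanged.
Fewer than three points degrade to subtracting the endpoint minimum.
Proprietary vendor baselines are not emulated beyond this documented
geometric contract.

## Feature detection and extraction

Peak detection runs on four spectral representations of a dataset: the mean
spectrum; the base-peak spectrum (per-channel maximum over pixels); the
variance-to-mean ratio spectrum; and the block-max-of-means (per-channel
maximum over the mean spectra of 8×8-pixel blocks). The last three exist to
expose features confined to small tissue regions, which the mean spectrum
dilutes below the detection threshold.

The picker takes local maxima whose median-relative signal,
`(intensity − running median) / (1.4826 × MAD)`, exceeds the S/N threshold
(default 4). Both running statistics use a sliding window of 2 % of the axis
length; MAD × 1.4826 is the consistent σ estimator for Gaussian noise.
Median-relative signal keeps S/N meaningful when a residual offset survives
baseline correction. Maxima closer than the peak width (default ±500 ppm,
relative to the lower mass) are merged keeping the higher apex. A constant
(zero-noise) spectrum yields no peaks, with a warning. Endpoint channels
that exceed their single neighbour count as apexes — irrelevant on long
profile axes but necessary when the picker is reused on short feature-space
vectors.

Peak lists are collated by single-linkage: entries within the tolerance
(default 100 ppm, relative to the lower mass) chain into one cluster whose
center is the unweighted mean of its members. The operation is idempotent
and order-independent; ties break toward lower m/z. Note one consequence of
single linkage: a chain of peaks each within tolerance of its neighbour can
span more than one tolerance end to end.

Extraction integrates a ±500 ppm (default) window around each collated
center in every pixel spectrum. Windows may overlap — a channel can
legitimately contribute to two adjacent features — and an empty window
yields a zero feature with a warning naming the center. For multi-dataset
projects the raw data of every dataset is re-integrated against the project
peak list (not reusing per-dataset extractions), then the reduced datasets
are merged side by side with a 5-pixel horizontal gutter. Provenance records
each pixel's source and offset, so merging is exactly invertible, and the
MAF shift matrix (below) never pairs pixels across a gutter or dataset
boundary.

## Decompositions

All methods consume the TIC-normalized matrix; PCA, MAF, k-means and fuzzy
c-means mean-center it first, NNMF and PLSA require non-negative input and
do not. Defaults: K = 8 components everywhere (the class count for the
clustering methods is deliberately the same as the factor count, both
configurable).

* **PCA** — `sklearn.decomposition.PCA` (full SVD); components ordered by
  explained variance, orthonormal loadings; K above the numerical rank
  truncates with a warning.
* **NNMF** — Lee–Seung multiplicative updates for squared Frobenius error,
  written in-house so the per-iteration objective trace is part of the
  output contract (the updates never increase it). 100 iterations, extended
  until the relative objective change drops below 1e-6 (cap 1000); three
  non-negative random restarts, best objective kept. Loading rows are scaled
  to unit maximum and components ordered by score energy.
* **MAF** — pooled covariance Σ_Δ of one-pixel horizontal and vertical
  difference vectors (boundary-crossing pairs excluded), generalized
  eigenproblem Σ_Δ w = λ Σ w solved with `scipy.linalg.eigh`; components
  ordered by ascending λ, i.e. descending spatial autocorrelation 1 − λ/2.
  A singular Σ (TIC normalization introduces one exact linear dependency)
  is ridge-regularized with ε = 1e-9 · trace(Σ)/F and a warning.
* **k-means** — `sklearn.cluster.KMeans`, k-means++ init, 10 restarts;
  one-hot scores, centroid-spectrum loadings, classes ordered by size.
  Available for exploratory output but excluded from the default agreement
  set of five.
* **Fuzzy c-means** — alternating membership/centroid updates with fuzziness
  m = 1.25, k-means++ seeding, stop at membership change < 1e-6 or 300
  iterations. With m = 1.25 the membership exponent 2/(m−1) = 8 makes naive
  powers overflow near centroids, so memberships are computed as a row-wise
  softmax of −(power/2)·log d²; a pixel exactly on a centroid receives full
  membership. Coincident duplicate centroids trigger one re-seed, then an
  error.
* **PLSA** — EM for the aspect model p(d,w) = Σ_z p(z) p(d|z) p(w|z) with
  intensities as fractional counts; stop at relative log-likelihood change
  < 1e-5 or 500 iterations; no tempering or regularization. Topics ordered
  by p(z). The log-likelihood trace is exposed and is non-decreasing.

Sign-indefinite methods (PCA, MAF) store each component with the sign making
its score image's skewness non-negative — localized structure then sticks
out positively — and all downstream consumers re-derive this canonical
orientation, so negating any stored component changes nothing end to end.

Stochastic methods derive their generators from the run seed via
`np.random.SeedSequence`, making full runs bit-reproducible.

## Agreement analysis

For each method in turn, each of its top-8 component images is a template;
every other method contributes its best-correlated component (both signs
tried for sign-indefinite candidates, ties to the lower index; many-to-one
matching allowed). The template's own image plus the M−1 matches — sign
oriented, negatives clipped to zero — are each binarized at strictly above
40 % of their maximum and summed: an integer agreement image in 0..M. The
template's own image is included in the sum, so "agreement level 4" with
five methods means the template plus three others. A continuous variant
sums the same images min–max scaled to [0, 1]; min-max scaling keeps the
differently-scaled methods commensurable. The consensus spectrum is the
mean of the matched base-peak-normalized loadings, renormalized to max 1.

Cutdown ranks the M × 8 plots by the number of matches with r ≥ 0.7
(ties by mean match correlation) and greedily drops any plot whose
*continuous* image correlates above 0.7 with an already-kept plot. The
continuous image is used for this comparison (and for target validation)
because the thresholded images' tiny dynamic range makes Pearson
correlations uninformative.

**Cross-validated agreement**: datasets are randomly split into k groups;
agreement runs on each leave-one-group-out fold; surviving plots are
compared across folds by correlating their continuous images on the pixels
of datasets retained by both folds (defined for k ≥ 3; with k = 2 the folds
share no dataset). The returned k × k matrix holds the mean best-match
correlation of fold i's plots against fold j's.

## Target images and validation

A target image encodes independently known heterogeneity: the mean spectrum
over an ROI is peak-picked at S/N > 5, and the images of all selected peaks
over the whole dataset are algebraically summed. Targets are deliberately
"unrefined" — ubiquitous peaks are included alongside the ROI's differential
ones. On profile data the detection is the standard picker; on reduced data,
where every feature already is a peak, selection is a robust z-score
(value − median)/(1.4826·MAD) > S/N over the ROI mean feature vector —
a local-maximum criterion is meaningless on an arbitrary feature ordering.

`validate_against_targets` reports, per target, the best-correlated
component of each method (|r| for sign-indefinite methods, whose sign is
arbitrary) and the best continuous agreement plot, plus a spectrum
correlation on features matched within 100 ppm after base-peak
normalization of both sides.

## Phantom generator

The generator emulates the study conditions of a nodular heterogeneous
tumor: a full-grid tissue carrying a shared peptide/protein peak panel, plus
elliptical nodules each expressing a private differential panel, with peaks
in m/z 2,000–25,000. Default study conditions (`default_nodule_spec`): a
64 × 48 grid (3,072 pixels), ~100 features, three well-separated elliptical
nodules covering ~8–10 % of the grid each, 12 shared peaks at mean intensity
40, six differential peaks per nodule at mean intensity 80, additive
Gaussian noise with σ = 5 (differential peak S/N 16, shared 8) clipped at
zero, and a lognormal per-pixel TIC factor with σ = 0.15 emulating
shot-to-shot MALDI yield drift — a deliberately visible drift that TIC
normalization must remove. Peak positions are drawn per seed on a fixed
lattice with a guard that differential peaks may never sit within twice
their width of each other (ground truth would be ambiguous).

The profile-level generator adds Gaussian peak shapes (FWHM in ppm of the
center), an exponential chemical baseline, and the same noise model on a
uniform axis; the reduced-level generator emits the feature matrix directly
for fast multivariate tests. Both are bit-reproducible from their seed, and
`truth_target` derives the exact noise-free target image of any planted
region (shared + differential panel summed over the grid).

What the phantom does *not* emulate: Poisson/detector noise statistics
(noise is Gaussian-plus-clipping; a hook for other noise models is the
`noise_sd`/generator split), correlated chemical noise, ionization
suppression between co-located analytes, isotope patterns, and mass-
calibration drift between datasets. Tests passing on phantoms therefore
demonstrate the bookkeeping and the statistical machinery, not robustness
to every artifact of real spectra.

## Numerical and design choices

* Pearson correlations are computed over tissue pixels only (images are
  stored unfolded); a zero-variance image correlates as r = 0 with a
  warning rather than NaN.
* Thresholding is a strict inequality (`> frac·max`), so a constant positive
  image becomes all ones and level counts can only drop as the threshold
  rises (monotonicity).
* "Number of correlated images" in the cutdown ranking is operationalized
  as the count of matches with r ≥ 0.7 — the same constant as the
  redundancy cut.
* Binary megabytes (1 MB = 1024² bytes) in the resource accounting; the
  decimal convention does not reproduce the standard per-spectrum/
  per-variable figures. The PCA FLOP formula 14kN² + 8N³ is implemented
  exactly as printed.
* Seeds: every stochastic component accepts one integer seed; derived seeds
  stay below 2³¹.

## Problem sizes in tests

The default test suite runs phantoms of 768 pixels × 60 features for module
tests and 3,072 × 100 (20 seeds) for the end-to-end recovery and validation
checks; these sizes were chosen so the whole suite completes in a few
minutes while leaving every planted effect far above its detection
threshold.

## Known limitations

* PLSA EM cost is O(pixels × features × K) per iteration in dense numpy;
  very large merged projects would need a sparse or minibatch variant.
* The LIMPC peak picker cited in the vendor literature is not public; the
  documented MAD-based local-maximum picker is this package's contract, with
  the same S/N and width parameters.
* Heavy-tailed representations (base-peak, variance/mean) admit occasional
  false peaks near the S/N threshold on pure white noise; in practice these
  become low-information features that TIC normalization and the consensus
  machinery ignore.
* Statistical significance of agreement levels is out of scope; an
  agreement value is a vote count, not a p-value.
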