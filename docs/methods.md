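# Methods

This note records the models, conventions and parameter choices behind
`lymphir`, and what the phantom-based validation does and does not
establish.

## Data model and conventions

A `SpectralCube` is a `(rows, cols, bands)` absorbance array (AU) with
a strictly increasing, uniformly spaced wavenumber axis (cm⁻¹) and a
pixel pitch (μm/pixel). Coordinates are 0-based, row-major,
(row, col) = (down, right); the cube origin is the top-left pixel.
ENVI files are written little-endian as float32 by default (float64 via
the header's `data type`); readers normalise any on-disk band order to
ascending wavenumber, and a header in micrometres is converted by
ν = 10⁴/λ with a logged warning. Mosaics abut tiles with no seam
blending — tile overlap handling is deliberately out of scope — and
absent grid positions are fill-valued with `validity=False`.

## Preprocessing

* **Absorbance**: A = −log₁₀(S/B). Non-positive sample intensities are
  clamped to a configurable floor (default 10⁻⁶·B) with a logged count
  rather than raising: stray detector pixels routinely go negative.
* **Truncation** to 900–3800 cm⁻¹ uses a closed interval on both ends.
* **Baseline correction** is a two-point linear baseline through the
  spectrum at two anchor wavenumbers (snapped to the nearest band, no
  interpolation). Rubber-band and polynomial baselines are not
  implemented; the linear variant is the simplest reproducible
  convention and the one the spectral-metric literature uses.
* **Savitzky–Golay second derivative**: window 13 points, polynomial
  order 2 (the minimum admitting a second derivative), scaled by the
  band spacing squared so units are physical. Within half a window of
  the range edges the derivative is undefined, so the output is trimmed
  to the valid interior instead of padding with fabricated values.
* **Vector normalisation** divides each pixel's spectrum restricted to
  the analysis range by its Euclidean norm; zero-norm pixels are
  flagged and excluded downstream rather than raising.
* **Pixel binning** averages non-overlapping f×f blocks and drops
  remainder rows/columns (logged); the pitch is multiplied by f.

## MNF denoising

The Minimum Noise Fraction transform solves the generalized symmetric
eigenproblem Σ_data·w = λ·Σ_noise·w, equivalent to noise-whitening
followed by PCA; eigenvalues order components by an SNR proxy and
reconstruction from the leading k components re-adds the mean spectrum.

* **Noise estimator**: covariance of horizontal shift differences
  d = (x[r,c] − x[r,c+1])/√2 over in-mask adjacent pairs (vertical or
  averaged variants configurable). This assumes signal varies slowly
  across neighbouring pixels; on scenes whose signal fluctuates
  pixel-to-pixel the estimate absorbs signal and MNF degrades toward
  an uninformative whitening — the phantoms therefore use spatially
  smooth structure, as real tissue does.
* **Rank selection**: k defaults to the number of eigenvalues above
  1.5× the median eigenvalue (at least 1), logged prominently since
  results depend on it; any fixed k can be forced.
* A near-singular noise covariance is ridge-regularised by
  ε·trace/bands (ε = 10⁻⁸, logged). Eigenvector signs are fixed
  (largest-magnitude loading positive) so repeated fits are identical.
* Masked pixels are excluded from both covariances but still
  reconstructed.

## Tissue mask and spectral metrics

A pixel is tissue iff A(1654 cm⁻¹) > 0.2 AU, strictly — the boundary
value is excluded. The default feature set holds 11 metrics over
980–3000 cm⁻¹: peak heights at 1080, 1236, 1546, 1654, 2852 and
2924 cm⁻¹ with local linear baselines; areas over 1000–1140 and
1500–1700; the 1080/1546 and 1654/1546 height ratios; and the Amide I
centroid over 1600–1700 (baseline-corrected, negatives clamped to
zero). This set spans the stated range with the bands tissue IR
spectroscopy conventionally uses, but it is a package default, not a
canonical table; any metric list can be supplied as YAML. Ratios whose
denominator magnitude falls below 10⁻⁶ AU yield a NaN sentinel and the
pixel is flagged. Wavenumbers snap to the nearest band; there is no
spectral interpolation.

## Classification

A 40-tree random forest with canonical defaults: unlimited depth,
√(n_features) candidates per split, full bootstrap, no class
weighting. Prediction is a per-tree majority vote with ties broken
toward the lowest class label, making output independent of tree
enumeration order; out-of-bag accuracy is recorded at training time.
The "other" class is a trained class with its own ROIs, not a rejection
rule (an optional posterior-threshold reject mode is deliberately not
the default). Flagged in-mask pixels are imputed with training-set
medians before prediction (logged). Label 0 marks below-mask pixels,
exactly.

**Evaluation protocol.** Phantom accuracy uses a spatially *blocked*
split: whole image blocks (default 32 px) are held out, so test pixels
never neighbour training pixels — per-pixel random splits would be
inflated by spatial autocorrelation. The draw is stratified: a block
assignment leaving any class with fewer than 30 ROI pixels on either
side is redrawn deterministically (incrementing the split seed), since
a split that holds out none of a class cannot measure that class at
all. Accuracy is scored on ROI pixels (3-px-eroded class interiors) of
the test blocks: boundary pixels are physically mixed by optical blur
and have no single true class, so including them would measure blur
geometry rather than classifier quality.

## HCA

The unsupervised arm applies SG second derivative → vector
normalisation over 940–1265 cm⁻¹ (the fingerprint region) → exact
agglomerative clustering cut at 10 clusters by default. Distances are
Euclidean (Ward linkage default) or "D-values" d = (1 − r)·scale with
r the Pearson correlation (average linkage default, since Ward assumes
Euclidean geometry); the scale convention (1 vs 1000) changes
dendrogram heights but never the partition. Cluster labels are
renumbered by descending size for determinism. Exact agglomeration is
quadratic in pixels, so a hard cap (default 40 000 in-mask pixels)
forces explicit binning rather than silently subsampling. The binning
study re-clusters one scene at several factors and reports pixel
counts and adjusted Rand agreement with block-majority-downsampled
ground truth.

## Phantoms

The generator emulates what an HD acquisition of a lymph node section
looks like, with every parameter seeded:

* **Endmembers**: each class is a sum of Gaussian absorption bands at
  the standard tissue wavenumbers (Amide A/B, C–H stretches, ester
  carbonyl, Amide I/II/III, nucleic-acid phosphates, carbohydrate and
  collagen C–O) over a gentle scattering baseline. Amplitudes encode
  the expected biochemistry (proliferating germinal-center B cells
  nucleic-acid-rich; red cells protein-rich and nucleus-free; collagen
  bands in connective tissue; lipid-heavy debris). The light-zone and
  dark-zone activated-B endmembers differ *only* in nucleic-acid band
  amplitudes and are deliberately the most correlated pair — so under
  rising noise the classifier's first confusions appear between them.
  A 1 % seeded amplitude jitter makes libraries seed-dependent without
  disturbing that ordering. Band shape is Gaussian (a Voigt hook would
  be straightforward but adds nothing to validation).
* **Scene**: the follicle layout paints capsule (connective tissue)
  and a smooth-muscle band along the top, a mantle of naïve B cells
  around a germinal center split into upper light and lower dark
  zones, T-cell paracortex elsewhere, two vessels (red-cell lumen in a
  fibrovascular wall) and a debris blob — all nine classes. Grid,
  stripe and uniform layouts exist for controlled tests.
* **Per-pixel variation**: a lognormal thickness factor (σ_log = 0.1,
  emulating section-thickness variability around nominally 6 μm cuts)
  scales whole spectra; two smoothed Gaussian texture fields (±8 %,
  ~2 px correlation length) modulate the nucleic-acid and lipid band
  groups, emulating nucleus/cytoplasm heterogeneity at subcellular
  pixel sizes. Optical mixing is a Gaussian blur of σ = 1.5 μm;
  noise is additive i.i.d. Gaussian, σ = 0.01 AU per band by default,
  with an optional band-dependent profile rising toward the range
  edges. ROIs sample 3-px-eroded class interiors (mirroring how a
  pathologist avoids ambiguous boundaries); classes too small to erode
  fall back to their full region with a warning.
* **Low-resolution degradation** blurs at the coarser optical scale
  (FWHM = target pitch) and area-average-resamples to the target grid
  (default 6.25 μm), for HD-vs-conventional comparisons.

**What phantom results do not show.** Real per-class spectral
contrasts — how separable T cells truly are from naïve B cells in
metric space — are not calibrated against measured tissue, because no
public dataset accompanies this problem; phantom contrast levels are
package parameters. Phantoms also omit scattering artifacts
(resonant-Mie distortion), atmospheric residuals, and instrument
drift. Passing tests therefore demonstrate the *pipeline's*
correctness and its qualitative behaviour (noise ordering of
confusions, binning effects on clustering), not clinical performance.

## Problem sizes and numerical tolerances

The validation suite runs phantoms at 24²–256² pixels with the full
726-band axis; the held-out classification benchmark uses the 256×256
follicle phantom (≈15 000 held-out ROI pixels), and the MNF
denoising-benefit check uses 100 seeded 24×24×60 rank-5 replicates.
Full-rank MNF round trips are exact to <10⁻⁸ max absolute error;
SG second derivatives reproduce sampled quadratics to 10⁻¹⁰;
correlation distances match the direct Pearson formula to 10⁻¹²;
degenerate generator settings (no noise, blur, texture or thickness
variation) reproduce endmember spectra to float32 precision.

## Known limitations

* The exact ENVI MNF variant of commercial software is configurable
  and proprietary; equivalence is claimed to the published MNF
  definition, not bit-for-bit to any product.
* Exact HCA is memory-quadratic; very large images must be binned.
* The metric engine evaluates per pixel independently; no spatial
  regularisation of class maps is provided (by design — per-pixel
  output is the honest primitive).
* Interferogram-level processing (apodization, FFT), atmospheric and
  scattering corrections, and registration to stained serial sections
  are out of scope.
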