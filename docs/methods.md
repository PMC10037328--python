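# Methods

This note documents the models, conventions, defaults and numerical
choices behind each stage of the `geometab` pipeline, and what the
synthetic validation suite does and does not demonstrate about real data.

## Spectral model and processing chain

A free induction decay (FID) is modelled as a sum of decaying complex
exponentials, one per multiplet component, sampled at the dwell time
1/SW (SW the sweep width in Hz). Defaults describe a 600.13 MHz proton
experiment: SW = 8401.82 Hz (14.0 ppm), 32 768 complex points
(acquisition time 3.9 s), carrier at 4.7 ppm.

The processing chain is the conventional one:

* **Apodization** multiplies sample k by exp(−π·lb·t_k); lb = 0.3 Hz by
  default. This convolves every line with a Lorentzian of FWHM lb, so a
  line with natural width w ends at w + lb.
* **FFT** zero-fills to the next power of two after at least doubling the
  record (65 536 points by default; digital resolution 0.128 Hz ≈
  2.1 × 10⁻⁴ ppm). The first FID point is halved so one-sided sampling
  leaves no constant baseline offset, and the output is scaled by the
  dwell time so that a component of complex amplitude A has absorption
  area A/2 in Hz units, independent of apodization (the frequency-domain
  integral equals the t = 0 sample). The ppm axis is stored in
  conventional decreasing order.
* **Phasing** applies φ(x) = φ₀ + φ₁·x with x ∈ [−1, 1] across the axis
  (pivot at the centre). Automatic phasing minimizes the integrated
  negative intensity — a robust criterion for absorption-mode spectra
  dominated by positive lines — by a coarse 15°-step grid search refined
  with Nelder–Mead.
* **Baseline** is estimated by asymmetric least squares (asymmetry
  p = 10⁻³, 10 reweighting iterations) on the real channel and
  subtracted. The smoothness is λ = 10⁹: the second-difference penalty
  scales steeply with sampling density, and at 65 536 points a softer
  baseline (λ ≈ 10⁷) climbs into Lorentzian tails and distorts areas by
  several percent, while 10⁹ recovers a slowly varying (e.g. quadratic)
  drift to within 2% of the tallest peak and perturbs line areas by
  ≲ 0.1%. The pentadiagonal system is solved in banded form.
* **Calibration** finds the tallest local maximum within ±0.5 ppm of
  0 ppm, fits its centre with a four-parameter Lorentzian, and rigidly
  shifts the axis so the centre lands exactly on the DSS reference at
  0.015 ppm. All other lines move by the same offset.

All operations are pure functions of their inputs.

## Multiplet deconvolution

Quantification is targeted: a catalog lists, per metabolite, the chemical
shift and multiplet shape of one quantifiable resonance. Each multiplet
is a sum of Lorentzian components

L(δ) = (2/(πw)) · 1/(1 + 4(δ − δ₀)²/w²),  w = FWHM in ppm,

at fixed J-coupling offsets with fixed relative intensities — 1 (s),
1:1 at ±J/2 (d), 1:1:1:1 at ±(J₁±J₂)/2 (dd), 1:4:6:4:1 at −2J…+2J (5m) —
sharing a single centre, linewidth and total-area parameter. Tying the
within-multiplet parameters removes most of the degeneracy in crowded
regions. Unknown couplings default to 7.0 Hz (a typical three-bond ¹H–¹H
coupling) and are refined within ±3 Hz during the fit; `dd` entries in
the built-in catalogs carry explicit (7.0, 3.0) Hz couplings, because two
equal couplings would collapse the four components into a degenerate
1:2:1 triplet.

Annotation matches every catalog entry to its nearest spectral local
maximum within a tolerance (default 0.01 ppm); entries whose nearest
maximum coincides are flagged ambiguous, entries without one unmatched.
Fit windows extend 10 initial linewidths beyond the outermost component
of each multiplet; overlapping windows are merged and their multiplets
fit jointly (the polysaccharide/sucrose cluster at 5.38–5.44 ppm and the
GABA/acetic-acid overlap at 1.91–1.92 ppm always fit jointly). Each
window carries one constant offset parameter that absorbs the nearly flat
tails of lines outside the window; without it, distant-tail leakage
biases areas by ~1%. Areas are initialized by nonnegative linear least
squares at the catalogued shapes, then all parameters are refined with
bounded trust-region least squares (ftol 10⁻¹⁰; centre bounded to
±0.02 ppm of the catalog shift; FWHM in [0.1, 20] Hz; areas ≥ 0).
Reported areas are total multiplet areas. A sample whose annotation
leaves more than half of the catalog unmatched is flagged and excluded
from the concentration matrix.

On noise-free synthetic spectra the full chain (synthesis → processing →
joint deconvolution) recovers input areas to 0.1% and multiplet centres
to ≲ 2 × 10⁻⁵ ppm, an order of magnitude below the digital resolution.

## Metabolic indexes

With z<sub>ij</sub> the standardized concentrations (population σ, ÷n — matching
the standard-scaler convention, so the PCA index variance equals the top
covariance eigenvalue exactly), MI_i = Σ_j w_j z_ij with:

* **mean** — w_j = 1/N;
* **cov** — w_j = CoV_j / Σ CoV_j, CoV_j = σ_j/μ_j computed on the *raw*
  concentration scale (after standardization μ = 0 makes σ/μ undefined;
  computing the weights on raw data and applying them to standardized
  variables is the only well-defined composition of the two steps).
  Metabolites with zero raw mean are excluded with a warning. Note these
  weights are invariant to positive rescaling of a column but not to
  offsets — an intrinsic property of the coefficient of variation;
* **pca** — w = leading unit eigenvector of the standardized-data
  covariance, sign fixed so the largest-magnitude loading is positive
  (the eigenvector sign is otherwise arbitrary); the explained-variance
  fraction is reported. Ties between the top two eigenvalues (within
  10⁻⁹) produce a warning and are resolved by the deterministic ordering
  of the symmetric eigensolver.

Zero-variance metabolites are dropped with a warning before any scheme.

## Projection

WGS84 geographic coordinates are projected to UTM (default zone 34N,
EPSG:32634; k₀ = 0.9996, false easting 500 000 m) with the Krüger series
in the third flattening n truncated at n⁶ — sub-millimetre accuracy far
beyond a zone's width, verified in the test suite against an exact
transverse-Mercator evaluation built from the conformal-mapping
definition (complex root-finding plus numerical continuation of the
meridian-arc integral at 30-digit precision). The inverse projection
round-trips to < 10⁻⁶ m. Survey-scale synthetic positions use a local
equirectangular metric (1° lat ≈ 111 320 m, longitude scaled by cos φ)
for the ~3 m GPS jitter, where the approximation error is nanometres.

## Spatial weights, Moran's I and LISA

Spatial weights use a triangular kernel with adaptive bandwidth: h_i is
the exact distance to the k-th nearest neighbour (k = 7 by default) and
w_ij = max(0, 1 − d_ij/h_i), w_ii = 0. Sites exactly at the bandwidth get
weight zero, and the matrix is generally asymmetric, as adaptive kernels
produce. Row standardization is on by default (the convention of the
spatial-econometrics libraries this mirrors); both behaviours are
selectable.

Global Moran's I = (n/S₀)·Σ_ij w_ij z_i z_j / Σ z_i², expectation
−1/(n − 1) under exchangeability. Inference is by random relabeling:
the two-sided p-value counts permutations at least as far from the
expectation as observed, with the (x + 1)/(m + 1) estimator (999
permutations by default, explicit seeds). The local Moran
I_i = (z_i/m₂)·Σ_j w_ij z_j decomposes S₀·I and is classified into
HH/LL/HL/LH quadrants by the signs of z_i and its spatial lag; p-values
use conditional permutations (site i held fixed, the remaining values
permuted). The type-I error of the global test on independent fields is
within the exact binomial 95% interval of the nominal 5% over 400
replicates in the acceptance suite.

## Variography and interpolation

The empirical semivariogram γ̂(h) = (1/2N(h)) Σ (z_i − z_j)² uses 20
equal-width bins over [0, max pairwise distance/2]; empty bins are
dropped. The exponential model γ(h) = c₀ + c·(1 − e^(−h/ℓ)) is fit by
weighted least squares with pair-count weights, bounds c₀ ≥ 0, c > 0,
ℓ ∈ (0, 10 × max lag]. The weighted objective has a second basin — a
near-linear ramp with ℓ at its bound — so the fit is started from four
length scales and the best weighted residual kept. The reported
correlation length is the exponential length-scale ℓ itself; the
conventional effective range 3ℓ (95% of the sill) is exposed alongside,
since survey reports rarely say which convention they use.

A field is declared structureless (`no_spatial_structure`) when the
binned variogram cannot be distinguished from a flat one: the
exponential's weighted-residual reduction over a constant fit fails an
F-ratio screen at the 90% level, the fitted partial sill is < 2% of the
total, or ℓ falls below a third of the shortest resolved lag (pure
nugget appearance). Kriging from such a model is meaningless; the
pipeline then falls back to deterministic interpolation and records the
fallback in its manifest. Exactly flat input reports ℓ at its upper
bound with the flag set.

Ordinary kriging solves, per grid node, the standard system (data
semivariance matrix augmented with the unbiasedness row; right-hand side
the data-to-node semivariances) through one LU factorization shared by
all nodes. Weights sum to 1 to 10⁻¹⁰; with zero nugget predictions at
data sites reproduce the data to 10⁻⁸ and the kriging variance is
reported everywhere. The default grid is 100 × 100 nodes over the
bounding box plus a 5% margin, unmasked (no field polygon is assumed).
Deterministic interpolation uses SciPy's thin-plate-spline RBF with an
affine polynomial tail, which reproduces affine surfaces exactly.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes:
stationary Gaussian random fields with exponential covariance
C(h) = sill·e^(−h/ℓ) plus nugget, drawn exactly by dense Cholesky
factorization (adequate below ~1000 sites; no FFT-based simulation);
clustered bimodal mixtures built by thresholding a latent unit GRF at
the empirical (1 − frac_hi) quantile — the simplest construction giving
spatially contiguous modes (defaults: modes −0.5 and 2.0 on the
standardized scale, 30% high fraction, within-mode scatter
sd = √nugget); quasi-grid sampling with 3 m Gaussian GPS jitter; and
synthetic FIDs carrying the full catalog plus a DSS line whose position
can be deliberately offset to exercise calibration. Amplitudes are
specified directly as post-transform absorption areas so round-trips
compare in one unit system.

Real spectra differ in ways the generator deliberately omits: solvent
suppression artefacts (the residual HOD line is a hardware-level effect
and is simply absent), peak-position drift with pH and ionic strength,
non-Lorentzian field inhomogeneity, rolling baselines from protein
background, and inter-metabolite correlation in the concentration
fields (each metabolite's field is drawn independently unless a bimodal
pattern is planted; per-metabolite noise levels are free parameters).
Passing the synthetic suite therefore demonstrates correctness of the
algorithms under their stated models, not robustness to every artefact
of real plant-extract spectra.

Validation problem sizes were chosen as realistic survey scales that the
estimators can resolve: variogram recovery uses 150 sites on a
300 × 150 m field (sample spacing ≈ ℓ/2 for ℓ = 30 m — a survey designed
to resolve a 30 m correlation length must sample below it; with spacing
comparable to ℓ the length estimate is unidentifiable and medians drift
by 30% or more), and the end-to-end recovery run uses 48 sites on
400 × 200 m with 90 m clusters. All generators are bit-reproducible from
their seeds.

## Known limitations

* Quantification assumes first-order multiplets with the catalogued
  shapes; strongly coupled systems (roofing, second-order distortion)
  are outside the model.
* The CoV index is undefined when concentrations are mean-centred
  upstream; it must see raw areas.
* Variogram fitting assumes isotropy and stationarity; no anisotropic or
  universal-kriging variants are provided.
* LISA p-values are not corrected for multiple testing across sites;
  cluster cores should be read as descriptive, as is standard.
* The kriging solver is dense (O(n³) once per surface) — appropriate for
  surveys of tens to hundreds of sites, not thousands.
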