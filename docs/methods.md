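# Methods

## Data model

A lesion is one representative 2-D section through the index mass, imaged
at T ≥ 4 contrast phases (`DceSeries`: a T×H×W stack with acquisition
times in minutes, pre-contrast phase at t = 0, and in-plane pixel spacing
in mm) together with a binary mask (`RoiMask`, ≥ 16 pixels, one 8-connected
component). All texture operators work on the minimal bounding box of the
mask so border ROI pixels keep image neighbours; statistics are then
averaged over ROI pixels only. Multi-lesion sections and 3-D features are
out of scope.

## Pharmacokinetics

The standard two-parameter Tofts model is used throughout:

    C(t) = Ktrans · ∫₀ᵗ Cp(τ) · exp(−kep (t−τ)) dτ,   kep = Ktrans / ve.

Cp is the Tofts–Kermode biexponential population AIF,
Cp(t) = D·(a₁e^(−m₁t) + a₂e^(−m₂t)) with defaults D = 0.1 mmol/kg,
a₁ = 3.99, a₂ = 4.78 kg/L, m₁ = 0.144, m₂ = 0.0111 min⁻¹; all five numbers
are configurable. Because the AIF is an analytic biexponential, the
convolution has the closed form
Ktrans·D·aᵢ·(e^(−mᵢt) − e^(−kep·t))/(kep − mᵢ) (with the t·e^(−mt) limit
at kep → mᵢ), which both the simulator and the fit evaluate exactly — no
quadrature on the time grid.

Relative enhancement (S(t) − S(0))/S(0) is treated as proportional to
C(t); no T1 mapping or SPGR signal equation is used. Fitting is bounded
(Ktrans ∈ [10⁻⁴, 5] min⁻¹, ve ∈ [0.01, 1]):

* `fit_tofts` — single curve, bounded trust-region least squares from 4
  multi-starts; flat curves return a flagged result at the lower bound,
  never a silent NaN.
* `fit_tofts_map` — per-pixel maps via variable projection: for fixed kep
  the model is linear in Ktrans (closed-form optimum), and the 1-D kep
  problem is solved on an iteratively refined log grid (6 rounds × 25
  points, bracket shrinks ~12× per round), fully vectorized over pixels.
  Noiseless recovery error is ~10⁻⁶ relative; the scalar PK features are
  the means of the per-pixel estimates over successfully fitted pixels
  (whole-ROI fitting of the mean curve is available via `fit_tofts`).

## Shape

Six radial-distance features are computed from the Moore-traced boundary:
centroid = foreground pixel mean, perimeter = summed 1/√2 step lengths,
and the radial-distance signature d(θ) resampled at 128 even polar angles
(outermost boundary point per angular bin, circular interpolation across
empty bins). Resampling at fixed angles rather than using every traced
pixel matters: pixel-level staircase jitter otherwise dominates the
smoothness and variance measures, making them resolution-dependent and
insensitive to genuine spiculation. With ρ = d/max(d): area overlap
ratio = area/(π·max(d)²), variance of distance ratio = var(ρ),
compactness = −perimeter²/(4π·area), smoothness =
mean|d(i) − (d(i−1)+d(i+1))/2| / max(d), plus mean(ρ) and std(ρ).
Compactness is emitted negated so that more spiculated margins score
lower, matching the reporting convention of the radial-distance shape
literature for breast masses.

## Enhancement, intensity and textural kinetics

EK: with E(t) the ROI-mean relative enhancement, the features are max E,
time of first maximum (minutes from baseline), their ratio (0 if the peak
is at baseline), and the mean decline per minute from peak to last phase
(0 if the peak is last).

IK/TK: curves are reduced to the 4 coefficients of a least-squares cubic
on normalized time u = (t − t₀)/(t_last − t₀) ∈ [0, 1]. Normalizing time
makes coefficients comparable across acquisitions of different duration
and phase count; curve values are deliberately not rescaled. With T = 4
the cubic interpolates exactly.

The 37 per-phase texture statistics (TK = 37 × 4 = 148):

* first-order — mean, median, range, standard deviation in sliding
  windows w ∈ {3, 5, 7} (reflect boundary), 12 curves;
* Sobel — mean |gx|, |gy| and gradient magnitude, 3 curves;
* Kirsch — the 8 standard compass 3×3 kernels (mean absolute response
  each) plus the per-pixel maximum over directions, 9 curves;
* Haralick — 13 statistics of a per-pixel grey-level co-occurrence
  matrix: 5×5 window, ROI-range min–max quantization to G = 64 levels per
  phase, distance-1 offsets in 4 directions, symmetrized. "Contrast"
  moments/entropy are computed on the |i−j| marginal, "intensity" ones on
  the (i+j)/2 marginal; information measures 1/2 use the classical
  definitions with 0·log 0 = 0 and the exponent clamped non-negative.
  ROI-range quantization makes all 13 invariant to global intensity
  offset and scale. The windowed-GLCM kernel is numba-compiled (a lesion
  box holds thousands of pixels, each with its own GLCM).

## Dynamic texture descriptors

DHoG: per phase, central-difference gradients on the bounding box;
orientation = atan2(gy, gx) ∈ [0°, 360°); pixels with zero magnitude have
no orientation and are excluded. A 3-level grid pyramid (1×1, 2×2, 4×4
cells) partitions the box; per cell, valid-pixel orientations are counted
(unweighted; magnitude weighting available behind a flag) into B even
bins, and all cell histograms are summed, so each per-phase aggregate
totals valid_pixels × levels. Aggregates are averaged over phases; the
scalar per B ∈ {2, 4, 6, 8, 10} is the Shannon entropy (bits) of the
normalized averaged histogram.

DLBP: per phase, each ROI pixel is compared with its 8 box neighbours
(clockwise from top-left, top-left = most significant bit, ties count as
≥) giving a code 0..255; codes are binned into B equal-width channels
(B = 256 is the identity), histogrammed per cell of a fixed 4×4 grid and
normalized to unit mass per phase; cell histograms are averaged over the
phases in which the cell had valid pixels and concatenated; the scalar
per B ∈ {8, 16, 32, 64, 128, 256} is the entropy of the renormalized
concatenation. Coarser-B histograms are exact block aggregations of the
B = 256 histogram.

Entropy is the histogram→scalar reduction because both descriptors are
read as lesion-heterogeneity measures; the raw per-phase and per-cell
histograms are retained on the descriptor objects for other reductions.
Direction of the response: under additive acquisition noise, a
*homogeneous* lesion's orientations/codes are noise-driven and nearly
uniformly distributed, so its entropy is close to the log₂ B ceiling;
planted spatial structure makes the histograms less uniform. The entropy
scalars therefore *decrease* monotonically as heterogeneity rises (the
class difference, not its sign, carries the discrimination). In a
noise-free limit the direction inverts (a perfectly flat lesion has no
valid gradients at all); the package documents and tests the noisy-regime
behaviour, which is the realistic one. DLBP, comparing immediate
neighbours only, needs the structure resolvable at the 1-pixel scale: at
the default 2%-of-baseline noise its response is weak, and its
heterogeneity-response tests are run at 0.5% noise.

## Evaluation harness

LDA with pooled within-class covariance, ridge λ = 10⁻⁶·trace(Σ)/p (so
subsets with p > n stay solvable), empirical priors, and train-fold
z-scoring of features (families differ in scale by orders of magnitude).
Protocol: repeated stratified 2-fold cross-validation (default R = 100
repeats); per repeat the pooled out-of-fold posteriors give Az
(trapezoidal/Mann–Whitney), PPV/NPV at posterior 0.5 (undefined
denominators flagged as NaN, excluded from means) and error rate; means
with 2.5/97.5 percentile CIs over repeats are reported and the per-repeat
Az values retained. Stability is RSD = 100·σ(Az)/μ(Az) (sample σ).
Feature ranking keeps features with Az above the grand mean and RSD below
it (both strict).

SFFS is the classic floating search with criterion J = mean repeated-CV
Az (R = 25 inside the search, splits fixed by seed so subsets are
compared on identical resamples), conditional backward steps, ties broken
toward the lower feature index, best subset ≤ max_k returned.

Learning curves hold out a fixed stratified 25% test set; for each
training size n, R seeded subsamples of the pool are fitted and the mean
test error recorded; err(n) = a·n^(−α) + ε is fitted by bounded least
squares (a > 0, α ∈ (0, 2], ε ∈ [0, 0.5]) from 8 multi-starts on a
log-grid of (a, α). A constant error sequence is a degenerate ridge and is
returned flagged.

## Synthetic phantom

The generator emulates two-site 1.5 T breast DCE-MRI acquisitions: 6–8
phases 1 min apart, per-lesion in-plane spacing drawn from 0.4–0.8 mm,
baseline signal S₀ = 100 scaled by a per-lesion receiver gain 0.6–1.6
(MRI signal is arbitrary-units), Gaussian noise sd = 2 (2% of S₀; a
Rician switch exists), lesion mean radii 3.5–7.5 mm. Lesion masks are
star-convex: r(θ) = R·(1 + s·f(θ)) with f a seeded unit-RMS sum of 8 sine
harmonics and s the spiculation amplitude. Ktrans inside the lesion is a
log-normal random field (Gaussian-smoothed white noise, physical
correlation length 1.5 mm, i.e. 3 px at the 0.5 mm default spacing)
scaled to a target spatial coefficient of variation — the heterogeneity
dial; ve is uniform per lesion in 0.25–0.55. The signal model is linear,
S(t) = S₀·(1 + γ·C(t)) with γ = 1 L/mmol, so no T1 mapping is needed
anywhere.

Cohorts draw two classes that differ in heterogeneity, spiculation and
mean Ktrans by configurable effect sizes, with 15% relative within-class
jitter on those parameters; zero effects make the classes exchangeable.
`strong_effects()` is the reference strong condition: heterogeneity CV
0.05 vs 0.5, spiculation 0.08 vs 0.16, shared mean Ktrans 0.15 min⁻¹.

What the phantom does *not* model: breast anatomy and background
parenchymal enhancement, motion, coil inhomogeneity, T2* effects, bolus
dispersion. Consequently the synthetic classification problems are much
cleaner than clinical ones — single texture-kinetic features can reach
cross-validated Az near 1 at strong effect sizes — so passing pipeline
tests demonstrate correctness and calibration of the machinery, not
clinical effect sizes.

## Problem sizes and numerical choices

Default test/acceptance workloads are sized for a single CPU: cohorts of
30+30 lesions (full 176-feature extraction runs in well under a second
per lesion after the texture kernel is compiled), 100 CV repeats for
reporting, 25 inside SFFS, 12 replicate null cohorts of 20+20 for
calibration checks. GLCM levels (64), window (5×5), DHoG pyramid depth
(3), DLBP grid (4×4) and all bin sets are configurable; defaults follow
common radiomics practice and keep ≥ ~10 px per cell for the smallest
lesions. Degenerate inputs fail loudly: masks violating their invariants,
flat baselines, ROIs smaller than the largest texture window, single-class
labels, and constant features for Spearman correlation all raise or flag
rather than returning silent numbers.
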