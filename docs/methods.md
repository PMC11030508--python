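# Methods

This note records the models, parameter choices and numerical decisions
behind `organoidqpi`, and what the synthetic validation does and does not
establish about real data.

## Imaging model

qOBM measures phase gradients: opposing oblique illuminations produce
intensity modulations of opposite sign, and the normalized difference
`DPC = (I_a − I_b)/(I_a + I_b)` isolates them. We model the mapping from
sample phase φ (radians) to each DPC channel as a linear filter in
frequency space,

    H_j(k) = i · g · (ŝ_j · k̂) · A(|k|),      H_j(0) = 0,

with ŝ_j the channel's obliquity axis, `A` a cosine-taper low-pass envelope
with cutoff `2·NA/λ` (the incoherent passband limit; NA 0.45, λ 720 nm →
1.25 µm⁻¹), and `g` a dimensionless contrast gain. The exact transfer
function of a scattering-medium epi-illumination system depends on the
sample's scattering properties and is not modeled here; this parametric
form reproduces its defining structure (antisymmetric, zero at DC, bounded
passband) and is shared between the simulator and the reconstructor.
Because inverse and forward model share `A`, round-trip tests alone would
be circular ("inverse crime"); robustness is therefore always additionally
checked with a 10% mis-specified envelope and 20 dB intensity noise.

**Gain.** `g = 0.3` rad⁻¹ by default. Two constraints bound it: larger `g`
amplifies phase contrast into the DPC channels and would push the simulated
intensity modulation past the physical bound |DPC| ≤ 1 at droplet edges
(frames would go negative), while smaller `g` amplifies measurement noise
in the deconvolution by 1/g. At `g = 0.3` the strongest structures in a
default phantom reach |DPC| ≈ 0.98 and the noisy, mismatched round-trip
error stays under 10% of the phase range.

**Inversion.** Joint Tikhonov deconvolution of both channels:
`φ̂ = IFFT(Σ conj(H_j)·FFT(DPC_j) / (Σ|H_j|² + β))`. Since the two axes are
orthogonal, `Σ|H_j|² = g²A²` is isotropic; the only information lost is DC
and the band edge. β defaults to 1e-3 (1e-6 suffices for noiseless data;
1e-3 stabilizes 20 dB noise). The unrecoverable additive constant is fixed
by zeroing the median of an 8 px image border band — valid because phantoms
(and dish-mounted organoid fields) are surrounded by medium; for
organoid-filling fields a caller-supplied background mask replaces the
border rule.

## Phase → refractive index

`Δn = λ·Δφ/(2π·Δz)` with λ and Δz converted to µm internally. The medium
index is the PDMS tissue-mimicking value n_m = 1.3440; the effective
optical section thickness Δz is instrument-dependent and not published, so
it is a configuration knob (default 2.5 µm) used self-consistently by the
simulator and the analysis — the recovered Δn is insensitive to its value
as long as both sides agree. High-RI material (lipid droplets, membranes,
nucleic content) is segmented at absolute n ≥ 1.46 by default. The
alternative convention of thresholding the contrast Δn is selectable
(`threshold_on="delta"`), since source descriptions of this procedure are
ambiguous between the two; Δn ≥ 1.46 itself is physically implausible
(it would require n₀ ≥ 2.8), which is why absolute n is the default.

## Phantoms and the cohort generator

Phantoms are 2D sections: every reconstruction and metric operates
per-plane, so a 3D stack adds nothing but runtime to validation. A phantom
is an elliptical organoid of cytoplasm (n = 1.360) containing:

* **rosettes** — disks of radius 25–40 µm with an interior lumen
  (0.35× radius) offset by a configurable fraction of the available radius;
* **fissures** — smoothed random chords rendered as ~2 µm clefts, flanked
  (±10 µm) by *directional cells*: 18 µm ellipses of aspect 2.5 aligned
  with the local fissure tangent, at 3000 cells/mm² of band by default;
* **nuclei** — 6 µm disks at 600 /mm²;
* **droplets** — disks of 3–8 µm placed until the droplet-label fraction of
  the organoid reaches the requested target (rejection sampling; a
  capacity error is raised rather than silently under-filling);
* a smooth Gaussian-filtered RI texture (amplitude 0.002) over tissue.

Compartment indices (cytoplasm 1.360, rosette 1.370, directional cell
1.385, nucleus 1.395, droplet 1.500, lumen 1.348, fissure 1.350) are
chosen so that only droplets cross the 1.46 segmentation threshold, with
realistic ordering (nucleic material densest among non-lipid content).
Every placed structure is recorded in a label map, so ground truth is exact
by construction: counts are exact, droplet fractions are within the
granularity of one droplet (±10% relative at the default loads).

The two-arm cohort generator emulates a control-vs-disease longitudinal
design at reduced scale: 6 organoids per arm (the per-experiment batch size
of the emulated study; the full study pooled 24 per arm across four
experiments), four weekly time points spanning a differentiation media
switch, 256 µm fields at 1 µm/px. Trends are: directional-cell and
surface-rosette retention per post-switch week (control 0.5 and 0.6,
experimental 1.0 — the disease arm retains folded, rosette-rich surface
structure) and droplet-fraction growth per post-switch week (control
+0.005, experimental +0.015). Before the switch the arms are statistically
identical by construction. A per-organoid lognormal-like severity jitter
(σ = 0.1, consistent across that organoid's weeks) makes organoids, not
tiles, the unit of biological variation.

**What the phantoms do not contain:** multiple scattering and depth-dependent
aberrations, stitching artifacts, out-of-focus structure, organoid-to-organoid
morphological diversity beyond the severity jitter, and any molecular
specificity (a "droplet" is anything high-RI). Passing tests therefore
demonstrate that the *analysis chain* is correct and sensitive at realistic
noise levels — not that the features transfer to any particular instrument
without recalibrating Δz, the gain, and the envelope.

## Tile features

Images are tiled into 50 µm squares (full tiles only). Families:

* **Texture** — symmetric GLCM at offset 1 px, averaged over 0°/45°/90°/135°,
  32 gray levels over the 1–99 percentile range; contrast, energy (Σp²),
  homogeneity, correlation, entropy (bits) from the angle-averaged matrix.
  Constant tiles give energy 1, contrast/entropy 0 by convention.
* **Fractal** — tiles are binarized against their background at
  median + 3·MAD (robust σ). Otsu thresholding is available but not the
  default: it forces a foreground split even in structure-free tiles, so
  reconstruction noise floods the sparse pattern scores — in cohort
  validation the directional-cell score under Otsu was dominated by
  correlated droplet content and its group ordering inverted, while the
  robust rule leaves noise-only tiles empty and tracks the actual
  directional-cell content. The global
  box-counting dimension uses divisor box sizes of the tile side (exactly
  triadic ladders for 3ᵏ fixtures, dyadic for powers of two), fit as
  −slope of log N(ε) vs log ε; band dimensions restrict ε to 5–9 µm and
  17–23 µm. Pattern scores are morphological rather than spectral:
  the *elongated* score at scale L is the tile-normalized area surviving an
  opening by the best-oriented L-line but not by an L-disk (long-and-thin
  structures — directional cells); the *circular* score for an area band is
  the area surviving a disk opening inscribed in the band's lower bound but
  not the next larger disk (compact droplet-scale blobs, 34–38 µm²).
  Convenience scores at the band midpoints (7 µm, 20 µm) are emitted as the
  directional-cell pattern features used in trend comparisons.
* **Fourier** — Hann-windowed, mean-subtracted spectra partitioned into
  radial bands cut at 23/17/9/5 µm periods (band powers sum to the windowed
  tile's mean square — Parseval); anisotropy is the resultant length of the
  power-weighted doubled orientation (1 − circular variance).
* **Autocorrelation** — normalized FFT autocorrelation; correlation length
  is the interpolated 1/e crossing of the azimuthal mean; anisotropy is
  1 − minor/major of the central above-1/e region's moment ellipse.

## Morphometrics

Perimeter is measured on marching-squares contours smoothed by a circular
moving average whose window scales with contour length (max(5, n/64)
points): raw pixel-edge counting overestimates smooth perimeters by up to
4/π and would make circularity of a disk ≈ 0.64. With this estimator an
ideal rasterized disk scores circularity ≥ 0.99 (clipped at 1.0), an
axis-aligned rectangle is within 1% of its exact perimeter, and the
estimate is stable within 2% under 2× upsampling and 30° rotations. Aspect
ratio comes from the moment-matched ellipse; "diameter" defaults to the
equivalent-area diameter √(4A/π) with the maximal Feret diameter also
reported. Lumen centeredness is the rosette-to-lumen centroid distance,
reported both in µm and normalized by the rosette equivalent radius (the
normalized form removes the rosette-size confound and is the default for
group comparisons).

## Feature selection and statistics

mRMR is the greedy MID scheme (relevance minus mean redundancy, mutual
information on equal-frequency 8-bin discretizations; MIQ optional),
deterministic with lexicographic tie-breaks. NCA fits per-feature weights
on standardized features by maximizing expected leave-one-out stochastic
1-NN accuracy with weighted-L1 distances, L2 penalty λ = 1/n, L-BFGS from
w = 1 (analytic gradient, verified numerically); ranking is by w². Note
that at λ = 1/n NCA retains sizeable weights even on permuted labels
(metric overfitting), so null behavior is assessed by rank displacement of
a planted feature, not by weight shrinkage. Chi-square uses the binned
feature × class contingency statistic. The consensus is the union of each
method's top-k (k = 150 by default) with per-method ranks attached.

Welch's t-test uses the Satterthwaite df; the variance F-test reports the
symmetric two-tailed p = 2·min(CDF, 1 − CDF). Both p-values are validated
against an independently implemented incomplete-beta series and a
binomial-sum identity to 1e-8. No multiple-testing correction is applied by
default (Benjamini–Hochberg is available), matching the raw-p reporting
convention of the emulated analysis. Longitudinal comparisons aggregate
tiles to one value per organoid per week before testing, so the sample unit
is the organoid; weeks with fewer than two organoids per arm are skipped
and logged.

## Histology

Optical density is `−log10(I/I0)` per channel (zero intensities clipped to
one count). The stain matrix defaults to the published FastRed/FastBlue
unit OD vectors with an orthogonal residual channel retained for QC;
deconvolution is the per-pixel matrix inverse and round-trips synthetic
mixtures to <1e-6. Particle counting thresholds the red density (Otsu
within tissue unless given), drops components under 4 px, and uses
8-connectivity; an optional binary closing merges sub-resolution gaps.
Both the component count and the positive-pixel count normalized by tissue
area are reported, since "particle count" is ambiguous between the two.

## Validation problem sizes

Validation runs use 512² px for reconstruction fidelity, 256² px phantoms
for recovery and cohort studies, 10 seeded cohorts per trend condition and
10 matched null cohorts, 20 seeded datasets (n = 200, 50 features) for
selection recovery, and 100 (statistic, df) pairs for the statistics
oracles. These sizes give stable pass/fail margins (binomial noise on a
9/10 criterion, ±20% recovery bands) while keeping a full validation run
in the minutes range on a single CPU.

## Known limitations

* Absolute phase scale is validated only self-consistently against the
  shared forward model; calibrating `g` and Δz against a real instrument
  requires a reference target.
* The envelope/gain model omits partial-coherence and vectorial effects;
  band-edge structure (< ~1.6 px period) is attenuated, so droplets below
  ~2 µm are undercounted.
* The fractal band "dimensions" use few box sizes inside each physical
  band and are best treated as comparative scores, not dimension estimates.
* Lipid vs nucleic contributions to high-RI content are not separable by
  construction, mirroring the physical ambiguity of RI contrast.
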