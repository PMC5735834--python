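# Methods

## The problem being modeled

Cine MRI of the rodent heart acquired with a birdcage volume coil has low SNR;
denoising the magnitude images before manual segmentation can change both the
accuracy and the observer-to-observer reproducibility of left-ventricular
(LV) function parameters (EDV, ESV, EF, LVM).  This package implements the
full evaluation loop — three denoisers, image-quality metrics, function
quantification and agreement statistics — and, because no real acquisition is
bundled, closes the loop with a synthetic LV phantom with exact ground truth
and a stochastic model of imperfect human observers.

## Phantom

The LV is a stack of circular discs on a short-axis grid (default 256×256 at
0.195 mm in-plane, 15 slices of 1 mm, 16 phases): a cavity of radius `r(p)`
surrounded by a myocardial annulus.  The cavity radius follows a raised
cosine over the cycle, `r(p) = r_es + (r_ed − r_es)(1 + cos 2πp/P)/2`, so
end-diastole is phase 0 and end-systole mid-cycle, as in gated acquisitions.
The annulus outer radius is chosen per phase so the total myocardial volume
is constant (the wall thickens at systole); voxelized, the per-phase
myocardial volume varies by < 3% at 0.195 mm.  Intensities are
`i_blood = 2.0` inside the cavity, `i_myo = 1.0` in the wall and 0 outside —
the bright-blood/grey-myocardium contrast of a FLASH cine.  Defaults
`r_ed = 4.5 mm`, `r_es = 2.46 mm` (EF ≈ 70%) and a 700 mm³ wall put EDV, EF
and LVM in the middle of healthy-rat ranges.  There are no papillary muscles
and no apex taper: every ventricle-containing slice carries full discs.  The
phantom is entirely deterministic.

Simplifications that matter for interpretation: the cylinder-of-discs
geometry makes volume quantification *easier* than real anatomy (no basal
partial volumes, no trabeculation), and the zero-intensity background is
cleaner than a real bore (no ghosting, no chest wall).  Passing tests
therefore demonstrate correctness of the computations, not segmentation
difficulty on real data.

## Noise model and level estimation

Magnitude noise is Rician: `M = √((S + n₁)² + n₂²)` with independent Gaussian
channels of SD σ.  The background (S = 0) is then Rayleigh with mean
`σ√(π/2)` and SD `σ√(2 − π/2)`, and `E[M²] = S² + 2σ²`.  The noise generator
derives one substream per cardiac phase from its seed, so any single phase
can be re-noised reproducibly.

`estimate_sigma` measures the SD of a signal-free background region (default:
a 24×24-voxel bottom-right corner on all slices, outside the animal).  The
default method divides by `√(2 − π/2)` to return the Gaussian-channel σ —
this corrected value is what the Rician bias correction needs.  The raw,
uncorrected SD is kept as a second method because the SNR definition divides
by exactly that quantity.  Estimation is per 3D phase volume, consistent with
per-phase filtering.

## Filters and their defaults

All three operate on one 3D phase volume; the driver maps them over phases
and clips the rare small negatives produced by smoothing around the zero
background.

- **Anisotropic diffusion** — exponential Perona–Malik conduction, explicit
  flux-form scheme, Neumann boundaries; `n_iter = 10`, `dt = 1/14` (the
  stability bound in voxel units is 1/6; the default leaves headroom), and
  `κ = 2σ̂` when driven by the study (no canonical value exists for this
  protocol; tying κ to the noise level makes the filter scale-free).
  Gradients are in voxel units by default; a `spacing` field enables
  mm-aware diffusion.
- **Total variation** — ROF objective solved by Chambolle's dual projection
  with dual step `1/(2·ndims)`, stopping at relative change `1e-4` or 200
  sweeps; strength `λ = σ̂` in the study for the same scale-free reason.  The
  ROF minimizer is unique, so the implementation is cross-checked against an
  independent reference solver at tight tolerance.
- **ORNLM** — search radius 5 (11³ = 1331-voxel search volume), patch
  radius 1 (26 patch neighbours, i.e. 3³ − 1), voxelwise (not blockwise).
  The patch distance is the Gaussian-weighted (SD 1 voxel, weights summing
  to 1) mean squared difference of magnitudes; with that normalization the
  distance of two identical noisy patches has expectation 2σ², and the
  default bandwidth is `h = 1.0·σ`.  Weights include the natural self weight
  `w = 1`.  Patches near borders sample an edge-replicated padding; candidate
  centres are clipped to the volume.  The averaged quantity is the *squared*
  image, and `√(max(· − 2σ², 0))` removes the Rician bias.

## Quality metrics

SNR is the ROI mean over the raw background SD (n − 1 denominator), CNR the
blood–myocardium SNR difference, both on the mid-ventricular slice of the
end-diastolic phase (maximal cavity volume).  ROIs are built once from the
ground-truth masks — eroded cavity for blood, eroded wall for myocardium,
the background corner — and reused identically across raw and filtered
conditions.  The report flags whether min SNR > 4, the regime where Rician
noise is approximately Gaussian.

## Function parameters

Volumes are voxel counts times voxel volume (mm³ ≡ µL).  ED/ES are the
phases of maximal/minimal cavity volume (the acquisitions' frame ordering is
irrelevant).  LVM uses the ED-phase myocardial volume by default (wall
thinnest, least partial-volume at this resolution; `es` and `mean` policies
are available) times 1.05 g/cm³, reported in mg.

## Observer simulation and the study driver

A simulated observer displaces each slice's endocardial and epicardial
contours radially by `bias + jitter·g(θ)`, where `g` is a smooth periodic
field (DC term plus 3 Fourier harmonics, unit pointwise variance, variance
split equally) drawn independently per contour and slice, then re-rasterizes
labels.  Thresholds between inside/outside voxels are taken per angular bin
at the midpoint of the separating gap, so a zero displacement reproduces the
input exactly; crossings of the two contours are clamped with a warning.
With ~1 voxel of jitter the intra-observer spreads (EDV ≈ 2–4%, LVM ≈ 4–6%)
match the raw-image levels reported for human observers in this setting.

The study driver ties observer precision to image quality:
`jitter = c/CNR` with `c = 6`, so the calibrated raw images (CNR ≈ 6) get
~1 voxel of jitter and better-contrasted filtered images get proportionally
less.  Observer 2 additionally dilates both contours by
`0.5 · jitter` voxels — a systematic placement tendency whose magnitude
scales with boundary ambiguity; a bias held constant across conditions would
make the inter-observer offset condition-independent and the filter
comparison uninformative.  Observer 1's repeat differs only by seed.

Per subject the driver: draws heart geometry (`r_ed` uniform in
3.9–5.9 mm, EF 67–80%, myocardial volume 1.0–1.2× EDV — spans matching the
deliberately heterogeneous cohort the protocol describes), calibrates σ by
bisection until the measured raw blood SNR is within 5% of the target 12
(replaying one noise substream so the objective is deterministic), filters,
measures quality with shared ROIs, simulates 3 segmentations per condition,
and computes function parameters.  The truth segmentation's LVM serves as the
ex-vivo gold standard.  All randomness descends from `master_seed` via a
per-subject, per-stage `SeedSequence` spawn tree; reruns are byte-identical.

Because observers segment label maps rather than pixels, the filtered voxel
data affect downstream numbers only through the measured CNR of the metrics
slice.  The driver therefore filters only the end-diastolic phase by default
(`filter_scope="metrics_phase"`); `"full"` filters all 16 phases and is the
faithful-but-slower mode for producing complete filtered series.

## Problem sizes

Unit and property tests run on coarse phantoms (48³-scale grids, 0.5 mm).
The multi-replicate study runs at 64×64 in-plane, 0.39 mm, 10 slices,
16 phases, 10 subjects — the same 25 mm field of view and heart sizes as the
full 256×256 protocol at a quarter of the in-plane sampling — chosen so a
20-replicate study completes in minutes on one CPU.  Voxel-counting accuracy
claims (2% against analytic disc volumes) hold at the protocol's 0.195 mm
resolution and are tested there.

## Numerical choices

- Diffusion rejects time steps above the explicit-scheme bound
  `1/(2·Σ 1/h²)` and reports the admissible bound.
- TV with `weight = 0` returns the input; constant volumes are fixed points
  of all three filters (for ORNLM via the degenerate `h = 0` limit, where
  only exactly matching patches receive weight).
- ORNLM exploits weight symmetry (each offset serves both `±δ`), costing
  half the naive 1331-offset sweep.
- Paired SDs use the n − 1 denominator throughout; the two
  relative-difference conventions (pair-average denominator for observer
  studies, gold denominator for the mass comparison) are separate functions
  and never interchanged.  Undefined correlations (constant inputs) are
  reported as NaN in tables rather than failing the run.
- A paired t-test on identical vectors returns (t = 0, p = 1); zero-SD
  nonzero differences are rejected as degenerate.

## Known limitations

- No MR physics: no sequence-dependent contrast, no motion or flow
  artifacts, no multi-coil (noncentral-χ) noise, no spatially varying noise.
- The CNR-linked observer model captures "better contrast → tighter
  contours" but not contour *sharpness*: a filter that flattens the
  background (TV especially) can reach extreme measured CNR and thus
  near-perfect simulated observers, whereas human observers on real TV-
  filtered images are limited by edge blurring the model does not see.
  Rankings among the three filters produced by this simulation inherit that
  bias and should not be read as statements about real manual segmentation.
- The Rician clamp makes the ORNLM background a half-zero speckle field;
  its measured SNR is sensitive to the sqrt's steep slope near zero.
- The ex-vivo stand-in is the phantom's own truth mass, so gold-standard
  rows measure segmentation error only, not physiological in-vivo/ex-vivo
  differences.
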