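# Methods

## Dynamic-speckle model

Each pixel's optical field is modeled as a complex circular Gaussian
process — the fully developed speckle regime, where many independent
scatterers contribute to every pixel — with single-exponential field
autocorrelation |g1(τ)| = exp(−τ/τc). The exponential form corresponds to
unordered (Brownian-type) scatterer motion and is the simplest model
consistent with the closed-form integrated contrast

    K²(x) = (e^(−2x) − 1 + 2x) / (2x²),   x = T / τc,

used as the validation oracle throughout. A Gaussian-shaped g1 (ordered
flow) is available via `AcquisitionConfig(g1_model="gaussian")` but is not
the default and has no closed-form oracle here.

**Synthesis.** The field is advanced as a first-order autoregressive
complex Gaussian process: E(t+δt) = ρE(t) + √(1−ρ²)ξ with
ρ = exp(−δt/τc) and ξ a unit circular Gaussian draw. A camera frame is the
mean of |E|² over sub-steps spanning the exposure T; between frames the
process jumps the readout gap in one exact AR update, so the field evolves
continuously across the whole acquisition. The sub-step is
δt = min(τc/8, T/16), chosen per group of pixels sharing a τc; a
caller-supplied δt coarser than τc/4 raises rather than silently biasing
the statistics. With δt = τc/8 the left-endpoint Riemann discretization of
the exposure integral biases K by well under 1%, far inside the 5%
validation band. Pixels are grouped by unique τc and the recursion runs
through a C-level IIR filter in single-precision complex arithmetic; all
draws come from one `numpy` Generator seeded from the acquisition config,
so stacks are reproducible bit for bit.

**τc–speed mapping.** τc = a / v with a single global calibration constant
a (default 1 ms·a.u.). The imaging modality is relative-only, so a is
arbitrary; phantom studies here use a = 0.5 ms at unit baseline speed,
i.e. x = T/τc = 40 at a 20 ms exposure — comfortably in the x ≫ 1 regime
where 1/K² grows linearly with speed. τc is capped at 200 ms: tissue with
zero perfusion still shows slow residual dynamics (Brownian motion,
physiological movement), and a literally frozen field would make temporal
contrast zero and the flow index diverge. A separate `static` compartment
label produces a truly frozen field for artifact testing only.

**Acquisition defaults.** 40 frames, 20 ms exposure. The inter-frame
interval is not part of the protocol being emulated beyond those two
numbers; the default of 25 ms (a 5 ms readout gap) is an assumption and is
recorded in every stack's sidecar. Detector noise defaults to none (pure
speckle); additive-Gaussian and scaled-Poisson models are available.

## Stroke scenarios

Stroke is represented purely as per-compartment flow multipliers over time
— no photochemistry. Compartments (`core`, `large_vessel`, `small_vessel`,
`outside_vessel`, `parenchyma`) partition the image; multipliers
interpolate piecewise-linearly between breakpoints, equal 1 at time 0, and
a dose-0 (light-only control) scenario is constrained to the band
[0.9, 1.1] at construction. Two canned scenarios cover the studied
conditions:

- **Acute 6-h course** (hours): the irradiated core falls to 0.5 at 2 h
  and 0.3 at 6 h; large in-spot vessels to 0.5 by 3 h then plateau; small
  in-spot vessels to 0.5 at 1.5 h and 0.2 at 6 h; out-of-spot vessels
  drift to 0.9.
- **14-day dose–recovery course** (days), mean over the 2-mm evaluation
  circle: 5-min dose {day 1: 0.00, day 4: 0.00, day 7: 0.38, day 14:
  0.64}; 2-min {0.27, 0.69, 0.84, 1.00}; 1-min {0.39, 0.84, 1.07, 0.94};
  dose 0 stays at 1.

A multiplier of 0 combined with the τc cap yields a small but nonzero
flow index (x = 0.1 at the 200 ms residual), which is the physically
sensible reading of "no flow signal".

## Contrast analysis and ROI statistics

Temporal contrast uses the population (divide-by-N) standard deviation:
it makes the toy closed-form cases exact, and at N = 40 differs from the
sample form by < 1.3%, far below every tolerance in use. Zero-mean pixels
are flagged invalid, never zeroed; pixels with Kt ≤ ε (default 10⁻³) join
the invalid mask of the flow-index map instead of being clipped, keeping
the static-scatterer artifact explicit. Invalid pixels are excluded from
all ROI statistics, never imputed.

**Relative CBF at ROI level is a ratio of means, not a mean of ratios.**
`roi_relative_flow` divides the ROI-mean flow index by the ROI-mean
baseline flow index. The per-pixel ratio map (`relative_cbf`) is kept for
visualization and exact identities, but its ROI average is biased upward
by the baseline estimator's squared coefficient of variation — about +5 to
+8% at 40 frames — because each pixel's denominator carries independent
sampling noise. Averaging ~10³ ROI pixels before dividing removes that
bias; it is also the natural reading of normalizing a region's CBF value
against its baseline value. An optional no-flow offset (mean flow index of
a designated static region) can be subtracted from both numerator and
denominator; the default applies no correction.

ROIs are defined in bregma-relative mm (AP, ML) and rasterized by
pixel-center-in-shape membership with no anti-aliasing: deterministic, and
the O(1/r) rasterization error is tolerance-tested. Convention: AP
decreases downward in the image (negative AP = caudal), ML increases
rightward. Vessel ROIs use the full-width mask around the polyline.
Replicates are reported as mean ± SD. One-way ANOVA is computed by direct
between/within sums of squares with an F(k−1, N−k) tail probability; the
0/0 case (zero within-group variance, equal means) reports F = 0, p = 1,
flagged degenerate. No multiple-testing correction is applied.

## Section phantoms and ex-vivo measures

The section generator realizes measured quantities exactly in pixel
arithmetic: infarct areas follow an ellipsoidal-cap axial profile
(area ∝ 1 − z²) whose pixel counts are adjusted so Σ area·h matches the
target volume to one voxel quantum, and vessel masks are drawn so the
vascular fraction inside each 1 mm × 1 mm evaluation ROI equals the
configured truth exactly. Slices are generated at the 100 μm measurement
spacing.

Infarct segmentation thresholds at 50% of the median stained-tissue
intensity (the threshold fraction is exposed — "unstained" is not a
numeric criterion), keeps connected components above a 0.01 mm² noise
floor (the largest component when no calibration is supplied), and
integrates area × h with no interpolation between slices. Vessel
binarization defaults to Otsu, with a fixed threshold available for
reproducibility studies; density is areal fraction only — no
skeletonization, tracing or diameter weighting.

## Beam metrics

The spot center defaults to the intensity centroid of the top-decile
pixels (overridable). Radial profiles use 0.02 mm annular bins with empty
bins omitted; the half-intensity distance interpolates linearly between
the bins bracketing the crossing of half the central intensity and raises
when no crossing exists. Power ratios subtract a 10-pixel border median
as background from each image before summing. Beam phantoms are parametric
(Gaussian, top-hat, Gaussian-plus-halo) with analytic half-radius truths —
e.g. a Gaussian I(r) = I₀e^(−r²/2s²) has half radius s√(2 ln 2); no
photon-transport modeling is attempted.

## Problem sizes used in validation

Speckle validation runs at desk scale: single-pixel ensembles of 2000
frames for the closed-form contrast check; 64 × 64 stacks of 40 frames,
3 seeds, for multiplier recovery (0.02 mm/px for 1-mm-spot studies,
0.04 mm/px when the 2-mm evaluation circle must fit); 128 × 128 for the
four-ROI consistency check; 256 × 256 sections for volumetry and density.
These sizes put the ROI-mean sampling error near 0.01 — an order below
the ±0.05 recovery tolerances — while keeping the full validation suite
in minutes.

## What the phantoms do and do not show

Passing recovery tests demonstrates that the analysis chain — contrast
estimation, flow indexing, baseline normalization, ROI geometry,
segmentation and integration — is unbiased and correctly calibrated under
the stated speckle model. The phantoms do **not** emulate: static-scatterer
mixing from the skull (a partially coherent static background would lower
contrast and is only representable here via the no-flow offset), shot and
read noise unless enabled, inter-day registration error (acquisitions are
assumed co-registered), vessel geometry realism, multiple-scattering
optics, or any biology of photothrombosis. Absolute velocity calibration
is out of scope: all flow quantities are relative, and only ratios to
baseline are ever interpreted.
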