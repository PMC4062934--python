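# Methods

## Scope and model overview

`petalpol` implements the computational core of a flower-polarization
learning study: (i) rotating-analyzer Stokes imaging polarimetry of
bull's-eye targets whose two concentric linear-polarizer regions are either
perpendicular ("contrast") or parallel ("plain"), and (ii) the statistical
analysis of differential-conditioning choice sequences with a
random-effects logistic learning model. Because no image or choice data are
distributed with the original study, both halves are driven by a
first-class synthetic layer with known ground truth.

## Imaging forward model

A pixel with radiance R (linear counts), degree of linear polarization
d ∈ [0, 1] and angle of polarization φ seen through an ideal linear
analyzer at angle θ produces

    I(θ) = ½ R (1 + d cos 2(θ − φ)) + dark,

the Malus response for partially linearly polarized light. The ½ is fixed
by the ideal-polarizer convention (an unpolarized pixel transmits half its
radiance at any θ); consequently the recovered S0 equals R, and AoP/DoLP —
the quantities of interest — are invariant to the overall scale. The AoP
reference axis is the image x-axis (columns), counterclockwise, period
180°; the study never states a reference axis, so this is a package
convention, applied consistently in rendering and recovery.

Acquisition defaults mirror the described protocol: seven analyzer frames
in 20° increments plus one dark frame. The angular range (0–120°) is an
assumption — any ≥3 distinct angles mod 180° are accepted — and is
configurable. Optional degradations: Gaussian read noise (counts), Poisson
shot noise with a gain (counts/photon), per-frame integer translation
jitter, and clipping to the sensor full scale (default 16-bit). With all
noise off, frames are exact, unquantized evaluations of the forward model,
which is what makes the end-to-end identity tests exact; quantization
happens only when a stack is written to 16-bit TIFF.

Target geometry: inner polarizer disk of 24 mm outer diameter and outer
annulus of 38 mm outer diameter, at a default scale of 10 px/mm (so 120 px
and 190 px radii) with a 1 px unfilled gap between the regions, over an
unpolarized background at one quarter of the ring radiance. The scale and
all radii are parameters; the defaults merely make "default geometry"
reproducible. Ring DoLP defaults to 1 (ideal polarizer film) and ring
radiance to 40 000 counts (strong but unsaturated 16-bit exposure).

## Stokes estimation and maps

The study names per-pixel Stokes parameters but no estimator. We use
ordinary least squares of the N frame intensities against
I(θ) = ½(S0 + S1 cos 2θ + S2 sin 2θ), sharing one pseudoinverse of the
N×3 design matrix across pixels; this is the standard rotating-analyzer
estimator and is exact for the synthetic forward model. For any angle set
containing {0°, 60°, 120°} it must agree with the closed-form three-point
solution, which the tests enforce at 1e-9 relative. Per-pixel residual RMS
is kept as a diagnostic. S3 is not estimable with a rotating linear
analyzer and is not reported.

Maps: φ = ½·atan2(S2, S1) folded into [0, 180); d = √(S1²+S2²)/S0 clipped
to [0, 1]. Validity excludes saturated pixels, pixels invalidated by
registration, S0 ≤ s0_min and d < dolp_min. Defaults dolp_min = 0.05 and
s0_min = 5× the dark-noise SD when an estimate is supplied (else 0): AoP is
numerically unstable below these, and the study shows masked/weighted
images without stating thresholds, so these are package choices. Degenerate
pixels are flagged, never NaN-propagated. False-color rendering maps AoP to
a cyclic hue over [0, 180) with brightness optionally weighted by DoLP
(invalid pixels black); DoLP alone renders as a 0–100% grayscale.

Ring summaries use the axial circular mean (angles doubled, vector-averaged,
halved) per region and report the inter-ring AoP difference as the axial
distance in [0°, 90°]; an exact 90° tie is reported as 90°.

## Ingest

Bayer separation is pure subsampling of the four RGGB/BGGR/GRBG/GBRG
sub-grids — no interpolation, bit-exact, with `merge_bayer` as the inverse.
The analyzed channel defaults to G1 (configurable; the study does not say
which channel it used). All processing is in linear counts end to end.

Dark subtraction clamps at zero, records full-scale pixels in a saturation
mask that propagates to map validity, and must be explicitly bypassed if no
dark frame exists — silent pass-through is disallowed.

Registration is translation-only: the acquisition was tripod-mounted, so
richer transforms are unnecessary. Shifts are estimated by FFT
cross-correlation of Sobel gradient-magnitude images. Gradient magnitude,
not raw intensity, is correlated because analyzer frames of the same scene
redistribute brightness across regions (ring contrast can invert between
analyzer angles), which biases raw-intensity correlation; edge magnitude is
invariant to the sign of local contrast. Whitened ("phase") normalization
was found to introduce ±1 px bias on such stacks and plain correlation
recovers all integer shifts exactly, so plain correlation is the default.
Subpixel refinement (Fourier upsampling) exists but is off by default.
Pixels shifted in from outside the field are removed from the valid mask; a
featureless frame is left unshifted with a warning.

## Choice simulation

Bee i's trial-t success is Bernoulli with

    logit P(y_it = 1) = (β0 + b_i) + (β1 + s_i) x_t,
    b_i ~ N(0, σ_b²), s_i ~ N(0, σ_s²) independent,

with x_t = (t−1)/(T−1) ∈ [0, 1]; the unit scaling is a numerical-
conditioning choice, as the study does not state its covariate coding.
Defaults define the emulated study conditions: 9 bees ("minimum of nine
motivated foragers"), 100 trials each, β0 = 0 (chance at the first trial,
as in the observed curves), β1 = log 3 ≈ 1.0986 so the average bee ends the
session near 75% correct (a slow, difficult task), and σ_b = σ_s = 0.5 for
the "strong between-subject differences" in ability and learning rate. For
the no-learning calibration condition we set β1 = 0 **and** σ_s = 0: with
no acquisition there is no acquisition-rate heterogeneity; ability
differences (σ_b) remain.

With `dfic=True` each trial carries a condition label 1–4 read off a 4×4
Latin-square layout that is re-shuffled under the three bout-rearrangement
constraints after every bout of 5 choices (bout length is a free parameter;
real bout lengths vary with crop capacity). Conditions never influence the
response probability: intensity contrast is uninformative by design.

What the generator does **not** emulate: sequential dependence between
choices (win-stay/lose-shift), spatial position effects, motivation drift
within a session, and any real camera's optics (vignetting, defocus,
polarizer diattenuation, spectral response). Passing tests therefore
demonstrate correctness of the estimators and procedures under the stated
model, not robustness to these real-data features.

## Learning-model fitting

The model is a logistic GLMM with per-bee random intercept and (by
default) an uncorrelated per-bee random slope on experience; the study
says only "random between-subject effects" while noting differences in
both ability and rate, which this structure captures with the fewest
parameters. The marginal likelihood integrates the random effects out per
bee with a Laplace approximation: the 2-D (or 1-D) penalized-likelihood
mode is found by damped Newton (the objective is globally concave), and

    log L_i = ℓ_pen(û_i) − ½ log det H_i − ½ log det D,

with H_i the penalized-likelihood curvature at the mode and
D = diag(σ_b², σ_s²). At 100 trials per bee the Laplace approximation is
accurate; adaptive quadrature is a possible extension. The summed −2·log L
is minimized over (β, log σ_b, log σ_s) by L-BFGS-B with fixed starting
values (logit of the pooled mean, log σ = log 0.3), bounds
σ ∈ [1e-3, 30] on the log scale, and a deterministic Nelder-Mead restart on
optimizer failure — the fit is a deterministic function of the data. The
implementation agrees with lme4's `glmer` (Laplace) to ~1e-4 on fixed
effects, variance components and −2·logLik on test data.

Deviance is −2× the maximized approximate log-likelihood. AIC counts fixed
effects plus variance components (the common mixed-model convention); this
is documented because the original printed AICs cannot be regenerated
without the unreleased data — they serve only as internal-consistency
anchors (Δdeviance ↔ ΔAIC ↔ p relations), which the package reproduces
exactly. Nested comparison: Δdeviance with an upper-tail χ²(Δdf) p-value
and ΔAIC = Δdeviance − 2Δdf; a negative Δdeviance beyond a small tolerance
(0.05, optimizer noise) is an error, smaller negatives are clamped to 0.
All specs share the same random structure, so nested fits differ only in
fixed effects.

The interaction test maps DFIC conditions 1–4 to their intensity-contrast
type (1/3 darker outer ring, 2/4 lighter) and compares
experience×intensity against the main-effects model (Δdf = 1 for two
levels).

Learning curves pool successes across bees within consecutive trial bins
and attach Wilson score 95% intervals (the study does not name its
interval; Wilson behaves well near 0 and 1). The Clopper–Pearson exact
interval is used as an independent check, with the two methods' documented
≲0.03 divergence at n = 100 as the comparison band.

## Latin-square rearrangement

All 576 order-4 Latin squares are enumerated once (backtracking) and
cached; a bout rearrangement rejection-samples from them until the
candidate is discordant with the previous grid (different condition in
every cell — constraint 2). Discordance makes each condition's old and new
cell sets disjoint, so assigning the condition's four physical targets to
its four new cells by a seeded random permutation automatically satisfies
constraint 1 (no target in its previous place); constraint 3 (Latin
square) holds by construction. Discordant squares are plentiful (a few
draws suffice), and existence is guaranteed at order 4, so the loop always
terminates.

## Problem sizes and numerical choices

Simulation suites run at the experimental scale of 9 bees × 100 trials:
500 replicates for size/calibration checks (2 SE binomial bands around the
5% nominal rate), 200 for power and parameter recovery — sizes chosen to
make binomial Monte-Carlo error small relative to the bands they certify.
Imaging tests use the default 420×420 geometry (or a 4 px/mm reduction
where geometry is incidental), 20 seeds for the 1%-read-noise robustness
suite. All randomness flows from explicit per-call seeds; there is no
global RNG state anywhere.

Known limitations: no polarizer non-ideality (diattenuation) correction,
no Mueller-matrix polarimetry, no UV/spectral modeling, no demosaicing
(channels are analyzed at half resolution by design), and the
χ²-reference LRT for fixed effects in small samples (9 subjects) is only
asymptotically calibrated — the simulation suite shows it is mildly
conservative at this scale.
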