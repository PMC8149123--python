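# Methods

This note documents the models, parameter choices, and numerical decisions
behind `capdyn`, and what the synthetic validation does and does not show.

## Synthetic cap movies

Each movie renders `n_caps` caps on a lattice in a (t, z, y, x) stack
(default 67 frames at 5 s, 15 z planes at 0.3 µm, 224×224 px at 0.25 µm/px,
16-bit). A cap is a flat-top ellipse with a 2 px Gaussian edge roll-off whose
half-maximum contour encloses exactly the analytic area, so thresholding at
half-maximum recovers the truth area to sub-pixel accuracy. The life cycle
follows a fixed phase schedule (defaults 120 / 90 / 60 / 60 s):

- **expansion** — area `A(t) = A₀·e^(g t)` with `A₀ = 34 µm²` and
  `g = ln 6 / 120 s⁻¹`, i.e. a sixfold area increase over the phase, the
  regime reported for wild-type caps;
- **stabilization** — constant area;
- **elongation** — area constant, aspect ratio ramps at 0.05 s⁻¹ and
  saturates at 2 (eccentricity 0.87); caps elongate along the x axis;
- **fragmentation** — area decays at 0.01 s⁻¹ and three interior disk-shaped
  holes (radius 2 px, seeded placement per frame) punch low-intensity gaps.

Intensity heterogeneity is a frozen Gaussian random field (unit SD, 1 px
correlation) added only on the flat-top interior and scaled to
`σ_het = 120 AU`; at fragmentation the field is regenerated at half
amplitude, so normalized heterogeneity drops below ¾ of its running maximum
exactly when caps begin to break up — mirroring the observed drop of roughly
a quarter at the end of stabilization. Axial intensity follows a one-sided
Gaussian (σ = 1.2 µm) peaking at the cap plane three z-steps below the apical
surface, with nothing above the surface. Caps random-walk at 0.05 µm/frame.
Noise is additive Gaussian (σ = 30 AU against a 1800 AU cap amplitude), not
Poisson: sufficient for exercising the estimators and parameterized directly
by its SD. Ground-truth area is the analytic schedule; ground-truth mean/SD
are measured on the rendered noiseless flat-top pixels, so they are exact by
construction (SD is exactly 0 when `σ_het = 0`).

The generator does **not** model optical PSF blur, photobleaching during
acquisition, nuclei or furrows, cap duplication, or intensity gradients
within a cap. Passing tests therefore demonstrate estimator correctness
under controlled geometry and noise, not robustness to real optics.

Lattice spacing (26 µm) keeps fully elongated caps separated; the spec of a
well-formed scene requires caps that never merge, matching the original
practice of measuring well-separated caps.

## Segmentation and tracking

The measurement plane is the shallowest z whose robust foreground (95th
percentile) exceeds twice the plane median, plus `round(0.9 µm / z-step)`
planes — one plane, not a projection (a 3-plane maximum projection is
available by flag). Background is a 5th-percentile estimate, clipped at zero.

Segmentation is a deterministic surrogate for manual outlining: Gaussian
smooth (σ = 1 px) → global Otsu → per-object half-maximum refinement → hole
filling → area filter → 8-connected labeling, labels ordered by descending
area. The refinement re-thresholds each Otsu object at half its own robust
amplitude (95th percentile of member pixels, within the object dilated by
3 px): a global Otsu cut lands systematically below half-maximum on flat-top
objects and inflates a 10 px-radius disk by ~8 %, while the half-maximum
boundary is where the rendered area is exact; measured bias on the default
movie is under 2 %. Manual ROIs supplied as label TIFFs override the
automated path. Touching or border objects are flagged and excluded from
dynamics rather than split — no watershed, because no splitting criterion is
defined by the source analysis.

Tracking is greedy nearest-centroid linking resolved globally by ascending
distance, with a displacement gate (2 µm per frame of gap) and a
configurable frame gap (default 1). On default movies it recovers 100 % of
identities; the acceptance check requires ≥ 99 %.

## Trace alignment and phases

Traces are aligned to the first elongation frame (in practice the frame of
centrosome separation, supplied externally or taken from generator truth)
and `t = 0` is placed 180 s earlier, at cap initiation; area and intensity
SD are normalized to their values there. Rolling expansion rates are
least-squares slopes over a centered 30 s window (7 samples at 5 s), shrunk
at the trace edges — windowed regression rather than two-point differences
for noise robustness.

Phase rules (thresholds configurable): expansion is the initial run with
normalized rate > 0.01 s⁻¹; stabilization begins when the rate first drops
to that threshold; elongation begins at the supplied anchor or, unanchored,
when 3-point-smoothed eccentricity exceeds 0.6 for three consecutive points;
fragmentation begins at the first point opening three consecutive area
declines with normalized heterogeneity below 0.75 of its running maximum.
The 30 s window blurs the expansion/stabilization boundary by up to two
frames; boundaries on ground-truth traces land within ±2 frames of the
schedule, which is the documented accuracy.

The expansion fit `Y = a·exp(k·X)` uses nonlinear least squares started from
a log-linear regression (with a small fixed multi-start fallback on `k`);
`R` is reported as the Pearson correlation between observed and fitted
values, with `r²` alongside, since the upstream "R value" is otherwise
undefined. `X` defaults to frames of 5 s: a rate of ~0.097 per unit over a
0–60 s window is dimensionally consistent with 12 frames (≈5.3-fold), not
with 60 seconds; a seconds option is provided and the unit is recorded in
every fit.

## FRAP

Normalization follows the printed formula; with several reference caps the
denominator is the mean of their (intensity − background)·area products (the
formula shows one reference, the protocol used two; the mean is the
symmetric choice). `Y₋₁` is computed identically from the prebleach row, and
an optional rescale sets it to 1.

The two-phase association is fitted with `Y₀` fixed at `Y(0)` and parameters
(span, fast fraction, `K_fast`, ratio `K_slow/K_fast`) estimated by bounded
least squares from a fixed 15-point multi-start grid (log-spaced `K_fast` ×
three ratios); no randomness. Two constraints make the decomposition
identifiable, because two nearby rate constants fit a single-exponential
dataset equally well in infinitely many ways: the fast component must carry
at least half of the recovery (the slow phase explicitly represents *minor*
residual cap growth), and `K_fast/K_slow ≥ 10` (a slow phase within one
order of magnitude of the fast one is not separable at realistic noise, and
residual growth over a ≤ 2 min acquisition is near-linear, i.e. slow). Both
bounds are arguments and can be lifted. A slow component contributing
nothing over the observation window is collapsed to `pctFast = 100`;
constant traces return a flagged single-phase fallback with immobile
fraction 1.

`PlateauFast` is evaluated verbatim as `2·SpanFast·(1 − e^(−K_fast t₅₀)) + Y₀`;
since `t₅₀ = ln 2 / K_fast`, this reduces exactly to `Y₀ + SpanFast`, and the
identity is asserted to 1e-12 on every call as a consistency check rather
than used as an alternative definition. A secondary half-time — the time at
which the *total* recovery reaches half of `Plateau − Y₀` — is also emitted.
Default simulation parameters place the truth in the wild-type cap regime
(`K_fast = ln 2 / 8.2 s⁻¹`, immobile fraction 0.19 with `Y₀ = 0.2`,
`Plateau = 0.92`, `%fast = 90`, `K_slow = 0.01 s⁻¹`); under 2 % proportional
noise, 1 s sampling and 60 s duration the median errors over 50 traces are
≤ 5 % (relative, t₅₀) and ≤ 0.03 (absolute, immobile fraction).

## Colocalization

Object calls: puncta strictly larger than 8 µm² (8.10 µm² passes, 8.00 µm²
does not), colocalized when any partner shares ≥ 10 pixels. The percent is
computed over the denominator channel (Arp3-positive compartments by
default; swap the arguments for the opposite direction). The
recruitment-ability reference pool defaults to the gated mCherry-puncta
pixels and is configurable, since "normalized" is otherwise unspecified.

Costes thresholds come from an orthogonal (total least squares) regression
`B ≈ m·A + c`; `T_A` descends linearly from the image maximum in 256 fixed
steps, stopping the first time the below-threshold Pearson correlation
reaches ≤ 0, and `r` is computed over pixels above both thresholds. Two
degenerate regimes are handled explicitly: a non-positive regression slope
(channels with no joint positive signal) and an above-threshold set smaller
than 25 pixels both fall back to the full-image Pearson with a
`thresholds_degenerate` flag — without the fallback, uncorrelated images
would be scored on a handful of extreme pixels. The randomization test
permutes non-overlapping PSF-sized tiles of channel A (same-shape tiles
permute among themselves; edge strips form their own groups) and reports the
fraction of 10 randomized correlations at least as large as the observed one.

## Statistics

Student's pooled t-test is the default (that is the named test); Welch is a
flag. Two-sided p-values; significance bands `*` < 0.05, `**` < 0.005,
`***` < 0.0005. No multiple-testing correction by default, matching
per-comparison reporting; Benjamini-Hochberg is available to users. The
fallout correlation asserts `R² = P²` to 1e-12 on every simple regression.
Zero-variance two-sample inputs with equal means return (t = 0, p = 1);
with unequal means they are an error rather than an infinite statistic.

## Problem sizes and determinism

Default validation sizes: one 67-frame, 4-cap movie for segmentation and
tracking; five movies × four caps (20 traces) for phase boundaries; 50
seeded FRAP traces; 1000 random parameter sets for the immobile-fraction
oracle; 2000 replicates for t-test calibration; 256² images for Costes.
These sizes give stable estimates of every reported error while keeping the
whole validation suite in the minutes range on one CPU. All randomness flows
through explicit integer seeds into `numpy.random.default_rng`; the fitters
are seed-free, and two pipeline runs with the same config produce
byte-identical output manifests (SHA-256 over every CSV/JSON/PNG).

## Known limitations

- Segmentation assumes compact, flat-top caps on a darker background;
  heavily textured or overlapping caps are flagged, not resolved.
- The phase classifier depends on its thresholds; they default to values
  that reproduce the generator's schedule and the reported heterogeneity
  drop, but real traces may need tuning, and elongation detection without an
  anchor requires a visible eccentricity rise.
- The FRAP identifiability constraints encode the assumption that the fast
  phase dominates; data with a genuinely slow-dominated recovery should be
  fitted with the constraints lifted.
- Reported headline values from the original live-imaging experiments (cap
  t₅₀ 8.2 s, furrow 15.1 s, immobile fraction 17 %) are used only to place
  the synthetic regimes; the underlying microscopy data are not public, so
  no test reproduces them directly.
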