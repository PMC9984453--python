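# Methods

This note documents the models, default parameters and numerical choices
behind gapscale, and what the synthetic validation does and does not show
about real data.

## Study design emulated by the generator

Four inbred lines form two pairs. Within a pair, the large and small
lines' mean lengths differ by 24.5% (`P_A`, amplitude-scaled Bicoid) and
23.6% (`P_lambda`, length-constant-scaled Bicoid) of the pair mean
⟨L⟩ = 500 µm. Within-line lengths are Gaussian, truncated at ±4 s.d.; the
default s.d. of 12 µm (cv ≈ 2.4%) is a placeholder for inbred-line
variance, exposed in `LineSpec.length_sd_um`, since only between-line mean
differences are pinned down by the design.

Embryos belong to one of 10 time classes (nc13, then T1–T9 subdividing
nc14), grouped into initial (nc13–T2), intermediate (T4–T5) and final
(T8–T9) stages; T3, T6, T7 buffer the stages.

### Boundary trajectories and the S construction

Each of the 20 registry boundaries carries a pair-level mean-position
track ξ̄(t) (linear from T1 to T9; nc13 equals T1) and a true scaling
coefficient track S(t). Per embryo of length L,

    ξ_true = ξ̄(t) + S(t) · (L − ⟨L⟩)/⟨L⟩,
    ξ_obs  = ξ_true + N(0, σ_pos),   σ_pos = 0.01 by default,

which makes the pooled OLS slope of ξ on L/⟨L⟩ an exactly unbiased
estimand of S — parameter recovery is therefore well-posed by
construction. Draws are rejected and redrawn until the registry order and
within-gene minimum gaps (2 bin widths) hold, so *every* generated embryo
obeys the registry; at the default noise this redraws ≲15% of embryos.

Default tracks: anterior boundaries drift posterior (otd1 +0.09 over
T1→T9), posterior boundaries drift anterior (gt6 −0.08), mid-embryo
(hb2/Kr1) and the most anterior (kni1) are static. Default S: at the final
stage S_f(ξ) = 0.41 − 0.83·ξ plus an alternating ±0.04 boundary-specific
deviation, clipped to [−0.28, +0.22] so that even ±4 s.d. lengths keep all
true positions inside (0.01, 0.99) — this is the global scaling tilt, with
e.g. tll3 near S ≈ −0.25. At early classes (through T3) the anterior
boundary set instead holds S = +0.05 (`P_A`) or −0.05 (`P_lambda`),
mirroring the sign of each pair's Bcd-encoded anterior difference, then
ramps linearly to S_f; this produces the early-group anterior ΔξP sign
flip between pairs (≈ ±0.012 at the configured values) and its
disappearance in the later group.

Detectability: gt1/gt2 (anterior *gt* domain) appear only from T5; hb1 is
absent at T3, modelled by extending the anterior *hb* domain to the pole
at that class so only hb2 is seen.

### Expression profiles

Profiles are 50-bin (centers (k+0.5)/50) sums of unit-peak domains with
logistic flanks (10–90% span 0.05 ξ by default). A profile's half-maximum
crossings are the construction contract, not the inter-flank shape: when
both flanks of a domain are present their tails interact, so the flank
centres are pulled inward by a closed-form compensation (solving
σ(u+v)σ(v−u) = ½σ(v)² for the half-gap offset) and the domain is
renormalised to unit peak, placing the realised crossings exactly on the
drawn positions. Zero-noise cohorts round-trip through spline detection
within 4×10⁻⁴ ξ. Multiplicative per-bin intensity noise is available but
defaults to 0 — positional noise is the study's error model.

### Bcd gradients

C(ξ) = A·exp(−ξL/λ). `P_A`: common λ = 100 µm (λ/⟨L⟩ = 0.2), amplitudes
set by A_L/A_S = exp(ξ*·ΔL/λ) so relative encoded positions coincide at
ξ* = 0.5 — anterior over-scaled. `P_lambda`: equal-order amplitudes with
λ/L = 0.210 (large) vs 0.195 (small) — the large line's relative gradient
is shallower but starts lower (A_L/A_S chosen so the crossing again sits
at ξ* = 0.5) — anterior under-scaled, ΔξB ≈ −0.027 averaged over ξ < 0.3.
With pure exponentials the amplitude mechanism's anterior offset
(≈ +0.08) is larger in magnitude than the λ mechanism's; real gradients
are not exactly exponential, so only the signs and the mid-embryo zero are
treated as the reproducible signature. Ensemble noise is cv = 0.15 of the
mean per bin.

### Renderer

Deliberately schematic; the fidelity target is extractor-recoverability,
not photorealism. The embryo mask is a horizontal superellipse (length L,
half-height 0.2 L) with a blunter anterior end (exponent 2.5 vs 2.0) so
orientation is decidable from shape; the dorsal nuclear layer is a row of
Gaussian blobs whose FWHM height equals the class's nuclear length and
whose spacing equals the internuclear distance; the FISH channel is the
gene profile interpolated at each pixel's fractional AP position; the
DIC-proxy channel draws the membrane invagination as a mid-AP vertical
ridge of depth ratio × half-height. Per-class invagination ratios are the
midpoints of the classifier's bins (no within-class jitter), making the
render → classify round trip a bin-table identity — a deliberate
idealisation; real staging confronts continuous ratios.

## Imaging measurements

Orientation: segment the combined nuclear+FISH background (single
connected component required), put the long axis horizontal, choose the
blunter end as anterior (heuristic, documented as such) and the
nuclear-layer side as dorsal. Length is the mask's AP extent.

Profile extraction follows the band convention: the lower border of the
dorsal nuclear layer per column, smoothed by robust lowess (frac 0.1, two
robustifying iterations — the span is a package default; the protocol
names the method but not its span), extended ventrally by half a nuclear
length; near the poles, where the fitted border exits the curved mask, the
band clamps onto the mask's own dorsal edge. Mean FISH intensity in 100
equal AP regions, self-background subtracted by the per-embryo minimum
region mean, clipped at 0, aggregated pairwise to 50 bins.

Staging: nc13 by short nuclei (≤7.5 µm) with large internuclear distance
(≥9 µm); within nc14, T1/T2 split on nuclear length at 11 µm while
invagination < 0.03; T3–T9 from a monotone partition of the invagination
ratio at cuts (0.03, 0.08, 0.15, 0.24, 0.35, 0.47, 0.61). These cuts are
configurable placeholders: the original protocol defers its exact values
to antecedent work without printing them, so no claim is made that these
match it; edge values clamp to the nearest class.

## Boundary detection and naming

A cubic smoothing spline (default roughness λ = 10⁻⁹, near-interpolating;
calibrated so zero-noise trapezoids are recovered within 10⁻³ ξ and
exposed as a parameter; `smoothing=0` selects exact piecewise-linear
interpolation) is segmented into domains above a detectability floor of
0.2 × profile maximum (the protocol excludes low-abundance domains without
printing a number). Each flank's half-of-domain-peak crossing is
root-found (Brent) at sub-bin resolution; with multiple crossings on one
flank (noise wiggles) the one closest to the peak wins — most robust to
tail noise. Detection is per gene; abutting boundaries of different genes
are never reconciled against each other.

Naming aligns detections to the expected named flanks at that time class
(order-preserving minimum-cost alignment; polarity must match, position
deviation is the cost, skips cost 0.08). No fixed AP search windows are
assumed — whether the original analysis used windows is not stated, so
window-free order-based assignment is used. Unmatched detections are
flagged, never dropped; a competing same-polarity detection within 0.05 of
a named boundary yields an ambiguity record.

## Dynamics and scaling statistics

Stage means pool embryos across the stage's classes. Spans and ΔξP are
differences of means with propagated standard error
√(sd_a²/n_a + sd_b²/n_b), assuming independence between cells (true for
the design); whether published ± values on spans are this propagated error
or the spread across boundaries is ambiguous, so the propagated error is
what the tables label `delta_sd` and any across-boundary spread is left to
the caller. Missing cells propagate as NaN records (never 0) and are
excluded pairwise from regressions and correlations.

Span regressions fit slope and intercept by OLS; the slope with t-based
95% CI is the reported quantity. S is the pooled OLS slope of ξ on L/⟨L⟩
with ⟨L⟩ the mean of the two lines' mean lengths; CI is t-based by default
with a percentile bootstrap behind a flag. An S estimate requires ≥2
embryos from each line and nonzero length variance. No multiple-testing
correction is applied anywhere — raw p-values are reported, matching the
reporting style the pipeline emulates.

## Bcd threshold model

"Random embryos satisfying the mean and s.d." is read as independent
per-bin Gaussian perturbations of the mean profile, truncated at zero
(truncation rather than resampling; the alternative is unstated in the
protocol). A correlated mode (per-embryo log-normal jitter of A and λ) is
provided behind a flag because the mean/s.d. summary does not pin down the
noise covariance. Crossings use the first-from-anterior rule; monotone
repair is available but off by default. Thresholds default to the
pair-averaged mean profile's values at the 50 bin centers, so ΔξB is
indexed by AP position. The n₁, n₂ in the s.d. formula default to the
ensemble sizes and are overridable (real-embryo counts are an equally
defensible reading).

Interpolation between bracketing bins is log-linear by default: it is
exact for exponential gradients (the zero-noise A = 1, λ/L = 0.2 gradient
crosses T = e⁻² at ξ = 0.400 to machine precision), whereas plain linear
interpolation carries a convexity bias of ≈ 2.5×10⁻⁴ at 50 bins; linear is
available as an option. Note a genuine property of noisy threshold
readouts: the ensemble-mean crossing is biased relative to the noiseless
crossing at O(cv²) (ratio-of-noisy-values interpolation, pole truncation,
first-crossing selection), so closed-form oracle comparisons are run at
small cv (5×10⁻⁴–10⁻²) where first-order Monte-Carlo error dominates,
while the pair-signature analyses run at the realistic cv = 0.15.

## Validation scope and problem sizes

The test suite and acceptance script validate by parameter recovery on
synthetic cohorts: S recovery (7 true values × 200 replicates of 50
embryos/line; MAE ≈ 0.007, CI coverage ≈ 0.95), span-ratio recovery (a
1.5× construction recovered as 1.49 ± 0.02 over the full initial→final
interval — chosen because it maximises the across-boundary span spread
that conditions the regression), a 200-image zero-noise rendering round
trip (length within 0.3%, time classes exact, boundaries within 0.005 ξ),
and the two qualitative signatures (anterior ΔξB signs; final-stage tilt
r < −0.5).

What this does not show: the generator imposes trajectories rather than
deriving them from gap-gene cross-regulation, uses idealised exponential
gradients, Gaussian independent noise, and schematic images free of
illumination fields, saturation, texture or 3-D effects. Passing tests
demonstrate that the estimators recover what the constructions put in at
realistic noise levels — not that real images would be measured without
bias. Real-data entry points are the 50-bin profile CSV dialect and the
boundary-table CSV.

## Known limitations

- Orientation relies on an end-bluntness heuristic; real embryos may need
  the manual override.
- The invagination-ratio staging cuts are placeholders (see above).
- The hb4 track treats the posterior *hb* expression as a single domain
  with a falling posterior flank; a separate terminal cap is not modelled.
- `anterior_group_compare` fixes the six-boundary anterior set by name;
  with non-default trajectories the ξ < 0.3 label may not describe them.
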