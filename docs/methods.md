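# Methods

`optoquant` quantifies presynaptic release properties from wide-field
fluorescence movies of genetically encoded transmitter indicators (GEIs such
as GRAB-type serotonin and oxytocin sensors), and ships a synthetic-movie
generator so that every stage can be validated by parameter recovery in the
absence of public raw data.  This note documents the models, the estimators,
the numerical choices, and what the recovery tests do and do not demonstrate.

## Forward model (simulate)

A movie is rendered as

    F(p, t) = F0(p) · [ 1 + Σ_e k_e · q · exp(−d(p, c_e)/λ) · h(t − t_e) ] · B(t)

followed by per-frame drift, Gaussian PSF blur (σ in μm), Poisson photon
noise and Gaussian read noise, quantized to 16-bit counts.

- **Spatial spread.** Each release site produces a single-exponential ΔF/F0
  domain `exp(−r/λ)` with spread length constant λ (≈0.6–0.8 μm for the
  neuromodulators this workflow addresses).
- **Sensor kinetics.** `h(t) = (1 − e^{−t/τ_rise}) e^{−t/τ_off}`, normalized
  to unit peak; τ_off defaults: 8.96 s (5-HT sensor preset), 3.15 s (OXT
  sensor preset).  τ_rise defaults to 0.1 s.  The off-rate correction in the
  pool stage deliberately ignores the rise (see below); the generator keeps
  it so that this approximation is exercised, not hidden.  In recovery runs
  the rise mismatch inflates the RRP estimate by roughly +5%.
- **Release dynamics.** Per stimulus a site succeeds with probability Pr; on
  success it releases k vesicles drawn from a configurable distribution
  truncated to the available pool; the pool is capped at the RRP.
  **Refill is modelled as discrete whole-vesicle arrivals**: the integer part
  of the per-stimulus refill rate arrives deterministically, the fractional
  part as a Bernoulli event.  A continuous fractional accrual was rejected
  for two reasons: identical sites then refill in lock-step (synchronised
  release staircases that no real cell shows), and the half-vesicle of
  fractional inventory standing in each pool is invisible to cumulative-curve
  back-extrapolation, biasing the recovered RRP by ≈ −25% for ~2-vesicle
  pools.  Bernoulli arrivals keep the mean rate exact, desynchronise sites,
  and leave essentially no standing inventory.
- **Basal fluorescence.** F0 is a smoothed lognormal field with configurable
  mean and CV (heterogeneous sensor expression); bleaching B(t) is a
  normalized two-term exponential.

Ground truth (config echo, per-site parameters, full release tables) is
written as a versioned JSON sidecar next to each multi-page 16-bit TIFF.

## Preprocessing

Stages run in a fixed order — alignment, Landweber deconvolution, baseline
adjustment, denoising, background subtraction — and the applied order is
recorded in every result.

- **Alignment.** Translational, phase cross-correlation on mean-subtracted,
  Hann-windowed frames (the taper suppresses FFT wrap-around that otherwise
  dominates smooth fields), iterated to diminishing returns (< 0.02 px) with
  an upper bound of 200 iterations; shifts are applied by cubic spline
  interpolation.  Guards: registration of a featureless field is ill-posed
  and must not corrupt the stack, so a frame whose estimated shift exceeds
  25% of the field is left in place and flagged, and a shift larger than
  0.75 px is only applied when it improves the correlation with the
  reference by more than the correlation's own sampling noise
  (3·(1−r²)/√N_pixels) — on a flat noisy field spurious shift estimates
  never clear that margin.
- **Movement diagnostics.** Dense displacement fields from iterative
  Lucas–Kanade optical flow; the movement score of a frame is the mean
  displacement magnitude, and AMMS (adjusted maximum movement score) is the
  maximum deviation of the score from its pre-stimulus mean during
  stimulation.
- **Landweber deconvolution.** `x ← max(0, x + α Hᵀ(y − Hx))` with H the PSF
  convolution under reflective padding; α = 1/L by default with L the
  largest eigenvalue of HᵀH from power iteration, which makes the residual
  MSE non-increasing.  Fifty iterations are the default operating point;
  per-iteration residual-MSE and SNR traces are returned so convergence can
  be inspected.  At 50 iterations a Gaussian blur is only partially
  inverted: the core of a point-like source stays slightly flattened while
  the exponential tail is already unbiased — this motivates the fit-range
  choice below.
- **Baseline.** Per-pixel two-term exponential `a·e^{bt} + c·e^{dt}` (decay
  rates constrained non-positive) fitted on the first and last control
  windows; multiplication factors evaluated from the fitted curve flatten
  every frame in between.  Fallback chain per pixel: two-term → single
  exponential → flat, recorded in a per-pixel code.
- **Denoising.** Per-pixel LOWESS (tricube local-linear) over time, default
  span 15 frames; for strictly positive traces a local-exponential variant
  (LOWESS on the log trace) is also computed and the lower-residual variant
  kept.
- **ΔF/F0.** `(F − F0)/F0` with F0 the per-pixel pre-stimulus mean; pixels
  with F0 below 5% of the median F0 are masked.

## Hotspot detection and spread fitting

Release sites are detected on a maximal-ΔF/F0 map: DBSCAN (defaults eps
3 px, min 5 points) over pixels above threshold (default 5× the
pre-stimulus pixel noise SD).  Clusters holding several sites are split by
subtracting the dominant site's exponential footprint — fitted on pixels
within ~1 μm of its centre, where neighbour contamination is least — and
re-clustering the residual.  A site is "isolated" if no other centre lies
within three length constants.

The radial profile averages full annuli (one-pixel-wide bins); each bin
reports the **mean pixel distance** rather than the nominal bin centre,
because axial and diagonal neighbours mix different radii within a bin and
the nominal centre would bias the fit.  The spread fit is nonlinear least
squares of `A·exp(−r/λ)` (offset fixed at 0 by default, free via flag) with
a CI from the fit covariance.  Two numerical choices matter and are defaults
in the pipeline wrappers:

- the site centre is taken from a lightly smoothed map (σ = 2 px), because
  the raw argmax selects a noise maximum and steepens the apparent decay;
- bins at r < 2 px are excluded from the fit (`r_min_um`), because after
  finite-iteration deconvolution residual blur is concentrated in the core
  while the tail slope of a Gaussian-blurred exponential is asymptotically
  exact.

For spatial analysis of a stimulus-locked response the pipeline selects
the **frame of maximal response** and deconvolves the temporal average of a
short (≤5-frame) window around it — the slow sensor holds the spatial
pattern essentially constant there, so averaging cuts shot noise without
touching the profile shape, and the fit then runs on that single averaged
map (a one-frame window of the max-map operation).  A per-pixel maximum
over a wide window would instead add the expectation of the maximum of
many noise draws — an offset that lifts the profile tail and can inflate λ
by tens of percent.

Under the fixture conditions used for validation (pixel 0.1625 μm, Gaussian
PSF σ 0.25 μm, peak photon-shot SNR 10, 50 iterations) the recovered mean λ
is within ~3–5% of truth with mean absolute relative error 0.06–0.07.

## Quantal analysis

0.1 Hz trials are independent because the inter-stimulus interval (10 s)
exceeds the sensor decay.  Trial amplitude = (max over a post-stimulus
window) − (mean over a pre-stimulus window).  Because the max of a noisy
window is positively biased under the null, the same max statistic is
evaluated on each trial's baseline segment; the pooled null mean is
subtracted from all amplitudes (a common shift that cannot change the
quantal spacing) and the pooled null SD is the trial noise estimate.

Failures are classified in two passes: amplitude < 2× noise SD
(noise-based), then amplitude < q/2 once q is known.  The quantal size is
fitted as an equal-spacing Gaussian mixture on the raw amplitudes (never a
histogram): components at {0, q, …, Kq}, variances σ0² + k σ1² (failure
noise plus optional per-quantum variance), q located on a grid at 1% of the
amplitude range and refined by EM under the spacing constraint, K chosen by
BIC over 1..5 with ties to the smallest K.  Release probability is
1 − failures/trials; quantal content is reported both per success
(mean/max of round(a/q)) and per stimulus (Pr × mean), because the two
conventions differ and published summaries do not always say which is meant
— the per-success convention is used for recovery comparisons.

## Pool analysis (RRP and refilling rate)

A 1,920-pulse 16 Hz train drives the pool to its depletion/refilling steady
state while the slow sensor smears per-pulse responses into an envelope.
The measured trace is modelled as `Σ_i r_i h(t − t_i)` and the nonnegative
amplitudes r_i are recovered by least-squares regression onto the bank of
shifted unit-peak impulse responses (rise ignored, as the off-rate
correction convention in this field has it).  Numerics: a direct
minimum-norm solve (cached pseudoinverse per protocol) is used when already
nonnegative — exact to machine precision in the noiseless identifiable case
— otherwise FISTA projected-gradient NNLS with a 10⁻⁶ ridge.

At 16 Hz stimulation sampled at 10 Hz the template bank is rank-deficient:
two pulses falling between consecutive frames have exactly collinear
templates, so individual r_i are not identifiable — only local sums are,
which is all the cumulative curve uses.

The cumulative sum of r_i versus stimulus number is fitted linearly over the
late phase (default: final third; sensitivity to final quarter/half is
available through the `late_frac` parameter); the back-extrapolated
intercept is the RRP in ΔF/F0 units, the slope the refill per stimulus, and
division by q converts to vesicles.  Diagnostic flags (short late window,
late-phase R² < 0.9, negative intercept) are always returned, never
silently dropped.

**Noise floor.**  Nonnegativity makes the correction absorb part of any
zero-mean noise as spurious release; the induced late-phase intercept and
slope grow linearly with the noise SD (about +0.4 vesicles/1,000 pulses at
a noise SD of 0.2 q through the 3.15 s sensor — larger than a near-zero
refill signal itself).  `pool.noise_floor` therefore runs the identical
correction (same bank, same pre-smoothing) on matched noise-only traces and
the measured floor is subtracted from the estimates, scaled to each trace's
pre-stimulus noise SD.  This is a parametric-bootstrap debias; it leaves
the NNLS estimator itself untouched.

**What the recovery runs show.**  With whole-cell refill of 22 vesicles per
1,000 pulses only ~14 discrete refill events fall into the final-third
window (and ~0.7 events for the 1.12/1,000 condition), so per-cell slope
and — through the ~1,300-stimulus extrapolation lever arm — per-cell RRP
estimates scatter widely (per-cell RRP SD ≈ 10 vesicles for a 20-vesicle
pool).  This scatter is a property of back-extrapolation on quantized
release at these rates, not of the implementation: fitting the ground-truth
event staircases directly reproduces it.  Means over 13 (or 12) simulated
cells recover the generating values within the documented 15%/20% bands,
with residual uncertainty of a few percent from exactly this sampling
scatter.

## Statistics

Mann–Whitney (two-sided) with rank-biserial r = 1 − 2U_a/(n₁n₂) (sign
convention fixed and documented: +1 when every value of the first group
lies below every value of the second), bootstrap percentile CIs;
Kruskal–Wallis (tie-corrected) with two effect-size conventions:
(H − k + 1)/(n − k) — the eta-squared_H form, which is what most published
reports print under the name epsilon-squared — and the textbook
epsilon-squared H/((n² − 1)/(n + 1)), both always emitted.
`epsilon_squared_from_p` inverts the χ² approximation to recompute effect
sizes from printed (p, k, n) summaries alone.

## Synthetic-fixture study conditions

Recovery fixtures use: pixel size 0.1625 μm (40× objective, 6.5 μm camera
pixels), 10 Hz sampling, Gaussian PSF σ 0.25 μm, peak photon-shot SNR 10
for spread fixtures; 10 hotspots × 100 trials with trial noise 0.2 q for
quantal fixtures; 13 (or 12) cells × 1,920 pulses with whole-cell trace
noise 0.2 q per frame for pool fixtures — the pool noise level is chosen by
analogy with the quantal trial-noise convention, as no separate convention
exists for whole-cell train recordings.  Problem sizes (48×48-pixel fields,
single-site movies, event-table-level pool traces) are the smallest at which
every estimator operates in its intended regime; they keep a full recovery
suite in the minutes range.

## What the generator does not emulate

Axial (3-D) optics and out-of-focus fluorescence; receptor/sensor
saturation and cooperativity; stimulus artefacts; non-rigid tissue motion;
spatially correlated noise.  Passing recovery tests therefore demonstrate
estimator correctness under the stated generative model, not robustness to
every property of real recordings — in particular, axial blur in thick
slices can widen apparent spread constants in ways no lateral deconvolution
can undo.

## Known limitations

- The equal-spacing mixture assumes linear summation of quanta; strong
  sensor saturation would compress high-k peaks and bias q downward.
- The off-rate correction ignores the sensor rise; at 0.1 s rise and 16 Hz
  stimulation this inflates recovered RRP by roughly +5%.
- Back-extrapolated refill rates below ~1 event per late window per cell
  are estimable only as averages over many cells.
- Registration is translational only; rotational or non-rigid motion is
  flagged (AMMS) but not corrected.
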