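# Methods

## The channel model

A single cell is treated as a memoryless information channel from agonist
concentration *c* (the input, chosen by the experimenter) to the log peak
calcium response *r* (the output).  The additive model

r_ijk = μᵢ(cⱼ) + e_ik(cⱼ)

separates a cell-specific mean dose response μᵢ from replicate noise e whose
distribution is shared across cells but specific to each concentration.
Modeling choices and their consequences:

* **Log outputs.** Peak heights vary over ~two orders of magnitude; the
  residual distribution is far closer to location-scale in log space, and
  the additive-noise channel makes capacity invariant to a common shift of
  all μᵢ (verified as a property test).
* **Scaled-t noise.** Pooled log residuals are symmetric but heavy-tailed.
  Each concentration gets a zero-location scaled Student t with scale σⱼ > 0
  and degrees of freedom νⱼ ∈ [0.5, 200], fitted by maximum likelihood over
  (log σ, log ν) with L-BFGS-B from three ν starting points (2, 5, 30); the
  bounds and multi-start are this package's choices.  The fit is
  deterministic, and a diagnostic report compares it against a Gaussian fit
  (log-likelihood difference, excess kurtosis, QQ table).
* **Residual definition.** e_ik = r_ijk − mean_k(r_ijk) within each
  (cell, concentration) group, using post-QC replicate counts.  Subtracting
  the group mean deflates the variance by (K−1)/K at K replicates; this is
  deliberately **not** corrected, so σⱼ describes the residuals as defined
  rather than the latent noise.  Groups with fewer than 2 replicates are
  dropped.

## Capacity estimation

Capacity is max over discrete input distributions of I(c; r).  The
conditional densities are discretized on a shared output grid and the
maximization performed by Blahut–Arimoto, whose per-iterate sandwich
I(p) ≤ C ≤ maxⱼ D(P(r|cⱼ) ‖ P_p(r)) certifies convergence; iteration stops
when the gap falls below 10⁻⁴ bits (or reports non-convergence).

* **Output quadrature.** Trapezoid rule on a grid spanning
  [min μ − 8σ·q₀.₉₉₉(ν), max μ + 8σ·q₀.₉₉₉(ν)].  The default grid is
  adaptive: a uniform core with at least 10 points per smallest σ across
  [min μ − 8σ, max μ + 8σ], plus 400 quadratically-coarsening points through
  each heavy tail, where the t density is smooth and slowly varying.  A
  uniform grid of any fixed size cannot both resolve small σ and cover
  ν ≈ 3 tails; the adaptive grid reproduces a dense uniform reference to
  < 10⁻⁴ bits at a fraction of the cost.  Every conditional must integrate
  to 1 within 10⁻⁴ on the grid (hard error otherwise), and rows are
  renormalized before use.
* **Acceleration.** Plain Blahut–Arimoto needs >10⁴ iterations on fine input
  grids because adjacent support points are nearly tied.  The default solver
  warms up with plain iterations, restricts to the support points carrying
  mass > 10⁻⁶, solves that small problem with an adaptively over-relaxed
  update (exponent γ grown ×1.5 on progress, any I-decreasing step rejected
  and retried with γ/4, so the iteration stays monotone), then re-certifies
  on the **full** support via the KKT condition; violating points are added
  back and the cycle repeats.  The reported gap is always the full-support
  certificate.  `accelerate=False` gives the textbook monotone iteration.
* **Lower bound vs interpolated.** The lower-bound estimate restricts the
  input support to the tested concentrations (ceiling log₂ N).  The
  interpolated estimate builds the support as the union of a uniform
  M-point grid (default M = 101) on the log₁₀-concentration axis and the
  tested knots, with μ, σ and ν each piecewise-linear in log₁₀ c between
  knots and no extrapolation outside [c₁, c_N].  Including the knots makes
  the tested support an exact subset, so interpolated ≥ lower bound holds
  by construction.  ν is interpolated like σ.  Sensitivity to M is small:
  M ∈ {51, 101, 201} agree within 0.02 bits (tested).  The interpolation
  axis is log₁₀ concentration, the dose–response convention.
* **EC50.** Min–max-normalize μᵢ and report the concentration where the
  piecewise-linear normalized profile first crosses 0.5 from below,
  interpolated in log₁₀ c.  Flat or decreasing profiles get no EC50 but are
  retained for capacity estimation.

## Peak extraction from traces

Raw input is one Fura-2 340/380 ratio series per cell at 1 frame/s, with
x = N·K scheduled pulses.  Stages:

1. **Background.** The slowly rising baseline is estimated by grey opening
   (rolling minimum then rolling maximum, window 151 s > one pulse period)
   plus light uniform smoothing, and subtracted.  Opening reconstructs
   monotone drift exactly while erasing transients narrower than the window.
2. **Detection and alignment.** Prominent maxima (prominence above
   max(8× frame-noise, 5% of the trace maximum)) are matched to the pulse
   schedule — or to a peak-time template from a reference trace — by a
   robust global time offset (best-count candidate search, then median
   residual refinement; at least two anchoring peaks required).  Every pulse
   receives a record: the local maximum of the corrected trace within ±15 s
   of its projected time, flagged `extrapolated` when no independently
   detected peak is nearby (typically the early low-dose pulses).
3. **Reference selection.** The interactive "pick the most representative
   trace" step is automated deterministically: most independently detected
   peaks, then highest median prominence, then lowest cell id; a manual
   override remains (`--reference`).
4. **Artifacts.** Within each (cell, concentration) group of ≥3 replicates,
   log heights deviating from the group median by more than 5× the group
   MAD are flagged `artifact_removed` (hence replicate counts K < 5 for some
   groups).  The 5×MAD rule replaces by-eye removal; on very tight groups it
   can flag genuine heavy-tail replicates (~5% observed at ν ≈ 3), a
   conservative bias documented here.
5. **Log conversion.** Heights are natural-log transformed, floored at 10⁻³
   of the trace's maximum corrected amplitude so the log is defined;
   capacities are converted to bits at reporting time.

Height is measured as the baseline-subtracted local maximum in a window
around the projected pulse time; residual tail overlap from the previous
pulse (< 0.5% of its amplitude at the default 120-s period) is the dominant
systematic at high SNR (round-trip RMSE ≈ 0.01 log units).

## Adaptation (desensitization)

* **Reproducibility.** Consecutive within-cell response pairs, pooled over
  cells, on linear response strengths: Pearson r, OLS slope, and a t-test of
  slope = 1.  A constant multiplicative decay d per pulse appears directly
  as slope ≈ d in linear space; in log space the between-cell spread would
  mask it.
* **Decay regression.** Log response on pulse index with fixed effects per
  (cell, concentration) group — demeaning both variables within groups —
  which removes between-cell strength differences and, on multi-dose
  schedules, the dose–response rise that would otherwise masquerade as
  negative decay.  Reported as per-pulse decay 1 − exp(β̂) in percent with a
  95% normal CI and the implied 20-pulse drop 1 − exp(20β̂) (18.2% exactly at
  d = 0.99).  A pooled variant without intercepts is available.
* **Correction.** For each global pulse number, the median within-group
  residual across all cells is computed; the corrections are centered within
  each concentration's pulse block and subtracted.  Centering preserves all
  (cell, concentration) means — dose–response profiles and μ̂ᵢ are untouched
  — while removing the systematic pulse-to-pulse trend from the replicate
  spread; it also makes the operation exactly idempotent.  The capacity gain
  after correction comes from the tighter fitted σⱼ.  Pulse numbers with
  fewer than 3 residuals are left uncorrected with a warning.

## Synthetic data generator

The generator defines the study conditions under which everything is tested:

* design: 100, 250, 500, 750, 1500, 3000, 10000 nM; K = 5 pulses per
  concentration in ascending order; 10-s pulses, 110-s gaps (x = 35 pulses).
* μᵢ(c): four-parameter Hill curve in log response,
  baseline + span / (1 + (EC50/c)^h), with baseline ~ N(−3.0, 0.3) (a barely
  visible 0.05 ratio-unit peak), span ~ N(3.2, 0.4) (~25-fold growth),
  log₁₀ EC50 uniform over the tested range (dynamic ranges shifted along the
  concentration axis), Hill slope uniform [1, 2.5].  Monotone by
  construction.
* noise: σ = (0.35, 0.30, 0.25, 0.20, 0.15, 0.12, 0.10),
  ν = (3, 3, 4, 4, 5, 6, 8) — noisier and heavier-tailed near threshold,
  tighter at saturation.  Neither the source protocol nor published summary
  statistics fix these values; they were chosen once as a realistic
  heavy-tailed profile and are fully configurable.
* desensitization d = 0.99 per pulse, applied as (pulse − 1)·log d in log
  space; a separate generator emulates the repeated-identical-dose protocol
  (21 pulses of 250 nM) used for reproducibility and decay analysis.
* traces: linear 8-s rise, exponential decay τ = 20 s, baseline ratio 0.5,
  linear drift 5·10⁻⁵ per frame, 30-s pre-baseline and 60-s tail, 1 frame/s.
  The period must exceed the transient support (rise + 5τ) or generation
  fails.
* reproducibility: one global seed; per-cell substreams spawned
  deterministically (bit-for-bit identical datasets per seed).

Ground-truth per-cell capacities are computed by an independent route —
`scipy.stats.t` densities, trapezoid quadrature on a dense grid, and direct
maximization over the softmax-parameterized simplex with the analytic
gradient dI/da_k = p_k(D_k − I) by L-BFGS — sharing no code with the
Blahut–Arimoto path.  Two truths are stored: on the discrete tested support,
and on the interpolated-support model class (the generator's noise is only
defined at tested concentrations, so truth outside that model class is
undefined; the interpolated estimator is evaluated against the truth of its
own model class).

What the generator does **not** emulate: photobleaching, cell movement or
segmentation error, non-stationary noise within a group, correlated
residuals across pulses (beyond the deterministic decay), dose-dependent
desensitization, and cells that fail to respond at all.  Passing tests
therefore validate the estimation machinery under the stated model, not the
model's adequacy for any particular real recording.

## Numerical choices and degenerate inputs

* BA tolerance 10⁻⁴ bits (full-support certificate), max 5000 KL
  evaluations; input-distribution floor 10⁻²⁰⁰ keeps logs finite.
* Scaled-t MLE: ν ∈ [0.5, 200]; all-zero residuals yield a pinned
  near-zero scale with a warning rather than an error.
* Quadrature normalization tolerance 10⁻⁴ per conditional; grids whose mass
  falls below 0.999 raise immediately (no silent renormalization of a
  broken grid).
* Ties in reference selection break by lowest cell id; detection requires
  ≥ 2 prominent anchoring peaks; log floor 10⁻³ of max corrected amplitude.
* Population sd with n = 1 is reported as 0 with an explicit degeneracy
  flag; histogram bin width 0.1 bits.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: populations of
12–150 cells for pipeline and summary checks, 100 cells (the recovery
criterion's size) for estimator-vs-truth error, 10⁵ residuals for noise-model
recovery, 50 seeded repeats at 25 cells × 20 pulses for decay-CI coverage,
and 10⁷ Monte-Carlo samples for the mutual-information oracle.  The full
acceptance run completes in about 4 minutes on one CPU; the test suite in
about 4 minutes.

## Known limitations

* The artifact rule (5×MAD) and background estimator are pragmatic
  surrogates for originally interactive steps; on pristine low-noise groups
  the MAD rule over-flags (see above).
* The interpolated capacity is still a lower bound of the continuous-input
  capacity of the fitted model (finite grid, ceiling log₂|support|), and
  both estimates inherit bias from plugging fitted (σ, ν) and K = 5 group
  means into the channel.
* Desensitization is modeled and corrected as a deterministic per-pulse
  trend; channel-with-memory formalisms are out of scope.
* Peak height is the only output statistic; trajectory-level (dynamic)
  information measures are out of scope.
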