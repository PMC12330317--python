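# Methods

This note documents the generative model, the estimators, the statistical
stages, the default parameter values and why they were chosen, and the
limits of what the synthetic cohorts can show.

## Task and coordinate frame

The alignment task asks a participant to indicate, with their unseen right
("indicator") index finger on a touchscreen, the position of a visual cue
(V trials), of their unseen left ("target") fingertip resting on a tactile
marker (P trials), or of both presented together (VP trials). The package
uses a frame with the origin at the body midline at the near edge of the
workspace, +x to the participant's right and +y away from the body; all
positions are in mm. Five start positions (x ∈ {−60,…,60} at y = 200 mm)
and two tactile markers ((−45, 300) and (−15, 300) mm, 30 mm apart) give
ten start–target pairs so the indicator movement cannot be stereotyped.
The exact start spacing and marker coordinates are package defaults chosen
to match the workspace geometry qualitatively; no analysis depends on them
because all estimators work on target-relative endpoints (see below).

Block designs:

* **veridical block** — 40 trials (15 V, 15 P, 10 VP). One design variant
  pseudorandomises the order under a longest-run-of-2 constraint
  (rejection sampling from the seeded generator); the other uses a fixed
  repeating 8-trial unit (V,P,VP,V,P,V,P,VP — 3V+3P+2VP, five repeats).
  The repeating unit is a package choice; only the counts are
  design-constrained.
* **conflict block** — 84 trials as the repeating quartet VP,V,VP,P (21
  repeats), realising 42 VP + 21 V + 21 P in alternating order. The visual
  offset advances by exactly 70/42 mm on each VP trial (the familiar
  1.67 mm is a rounding) and is carried, not advanced, on interleaved V
  trials; the final VP trial sits at exactly 70 mm. A zero-offset variant
  of the same block serves as the matched veridical second block.
* **visual-shift control block** — 84 V-only trials with the cue ramping
  linearly to 70 mm on the last trial; the target hand stays in the lap,
  so no cue conflict ever arises.

Schedules are bit-identical across runs for a fixed seed.

## Generative observer

Parameters (per participant): sensory noise σ_P, σ_V (mm, per axis),
motor noise σ_M (isotropic, indicator hand), visual weight w_V,
recalibration rate η per VP trial, and constant baseline biases b_P0,
b_V0 (2D mm) representing idiosyncratic offsets of each modality's map.

Endpoint generation:

* P trial: `endpoint = p_target + b_P + ε_P + ε_M`
* V trial: `endpoint = v_cue − b_V + ε_V + ε_M`
* VP trial: `endpoint = w_V·(v_cue − b_V + ε_V) + (1−w_V)·(p_target + b_P + ε_P) + ε_M`

with ε_X ~ N(0, σ_X²·I). The signs make a positive b_P,y an overshoot of
P targets and a positive b_V,y an undershoot of V targets — the
behavioural signature of recalibration toward a forward-shifted cue.

Recalibration (VP trials only):

    c   = (v̂ − p̂) − (habitual baseline discrepancy)
    b_P ← b_P + η·w_V·c
    b_V ← b_V + η·(1−w_V)·c

The conflict driving recalibration is measured **relative to the
observer's habitual cross-modal discrepancy** (−b_V0 − b_P0): an observer
whose maps have always disagreed by a constant offset does not experience
that offset as a conflict. Without this reference the model would erode
its own baseline biases during veridical blocks, contradicting the stable
idiosyncratic biases that make cue weighting measurable in the first
place. The error-proportional form makes the lower-weighted modality
recalibrate more, accumulates at total rate η regardless of the split,
and — because the imposed offset ramps while the update lags — yields
partial compensation: with η = 0.08 the terminal total recalibration is
≈ 46–52 mm of the 70 mm conflict, matching the magnitudes typical of this
paradigm. The bias state restarts from the baseline biases at the start
of each block, so each block's terminal bias (relative to baseline) is
that block's generative ground truth.

### Default parameters and their anchors

| parameter | default | anchor |
| --- | --- | --- |
| σ_P | 8 mm (lognormal, log-SD 0.2) | P-endpoint 2D variance ≈ (2−π/2)(σ_P²+σ_M²) ≈ 55 mm², inside the 50–60 mm² range typical of veridical blocks |
| σ_M | = σ_P | encodes the correction assumption that the indicator hand contributes half of the P-endpoint variance |
| σ_V | 10 mm (lognormal, log-SD 0.2) | V-endpoint variance ≈ 70–90 mm² |
| w_V | min-variance value + N(0, 0.15), clipped to [0.05, 0.95] | implied mean 64/164 ≈ 0.39; measured block weighting ≈ 0.4–0.5. The extra spread represents attentional/strategic weighting factors beyond the noise ratio |
| η | 0.08 (N, SD 0.02, clipped [0.01, 0.30]) | total recalibration ≈ 46 mm of 70 |
| b_P0, b_V0 | N(0, 10 mm) per axis | idiosyncratic modality biases large enough to separate the V and P endpoint clouds |

The population split between weighting spread and learning-rate spread is
deliberate: weighting spread trades proprioceptive against visual
recalibration across participants, while η spread moves both together.
With weighting dominating, the simulated Δy_V–Δy_P correlation is
reliably negative (≈ −0.25 at n = 100), reproducing the inverse relation
characteristic of cue-conflict cohorts. The weight is materialised at
draw time, so later changes to σ_P (e.g. cTBS effects) alter noise but
not the integration weight — matching the empirical observation that
inhibitory S1 stimulation raises proprioceptive variance without
measurably changing cue weighting.

### Group (cTBS) effects

For the three-group design the stimulation effect is a pair of
multipliers applied after the first veridical block: S1 default
σ_P × 1.3 and η × 1.4, M1 and Sham × 1.0. The direction (S1 raises
proprioceptive variance and recalibration) is the anchored fact; the
magnitudes are declared defaults. Note that a 1.3 σ_P multiplier implies
a mean P-variance shift of (1.3²−1)·(2−π/2)·σ_P² ≈ 19 mm² against a
per-participant noise floor of ≈ 0.48·σ_P² ≈ 31 mm² (the sampling SD of a
15-trial variance-of-distances estimate, doubled for the pre/post
difference) — a one-way ANOVA at 27 per group therefore detects it in
only ≈ 55–65 % of replicate cohorts, not with high power. This is a
property of the design (15 unimodal trials per block), not of the
implementation.

### Synthetic SAI

SAI is simulated as 20 conditioned + 20 unconditioned MEP traces per
timepoint (pre/post), damped-sinusoid waveforms (onset 20 ms, decay
12 ms, period 15 ms) at 5 000 samples/s, unconditioned peak-to-peak
≈ 1 mV (the test-stimulus titration target). The post/pre change is
coupled linearly to the participant's **estimated** conflict-block
proprioceptive recalibration:

    ΔSAI = 105.94 + 1.80·Δy_P + 0·Δy_V + N(0, 15)   (conflict session)
    ΔSAI = 105.94 + N(0, 15)                         (veridical session)

in % units. Coupling to the behaviourally estimated (not latent)
recalibration is deliberate: the regression stage operates on estimated
recalibration, and coupling to the latent bias would attenuate every
recovered slope by the endpoint measurement-noise ratio, conflating the
generative coupling with an estimator property. Conditioned trace
amplitudes are rescaled after per-trace jitter (lognormal, 15 %) so the
realised ratio-of-means hits the target exactly before baseline EMG noise
(default 5 µV RMS) is added; at zero noise the quantification pipeline
therefore recovers the generative ΔSAI to numerical precision. Baseline
noise is kept at the clean end of the realistic 5–20 µV post-bandpass
range because the max-minus-min operator rectifies baseline noise into a
small positive amplitude bias that compresses ΔSAI toward 100 (≈ 2–3 % at
5 µV, ≈ 10 % at 20 µV) — a known limitation of peak-to-peak
quantification, documented here rather than corrected.

### Tactile staircase

The grating-orientation test is simulated over the dome set {0.35, 0.5,
0.75, 1.0, 1.2, 1.5, 2, 3, 4, 5} mm starting at 3 mm: six consecutive
correct orientation reports step down, any error steps up, and the
observed threshold is the smallest width passed (an observer who never
passes is scored at the largest dome). The response model rises from
chance (0.5, two-alternative report) to 1 − lapse around the true
threshold with a spread of 0.25 × threshold. The first dome width is
taken as 0.35 mm (the value consistent with the rest of the
geometric-like series).

## Estimators

All estimators operate on **target-relative endpoints** (endpoint minus
that trial's proprioceptive target, or visual cue on V trials) because
start and target positions alternate by design; raw clouds are bimodal.
The conflict dimension y is the exception where the printed first-4/last-4
formulas apply directly (both markers share a y-coordinate, so raw and
relative y agree):

* `recalibration_p`: mean(last 4) − mean(first 4) of P-trial y-endpoints,
  minus the true shift (0).
* `recalibration_v`: total shift − (mean(last 4) − mean(first 4)) of
  V-trial y-endpoints, with the **printed constant** total (70 mm for a
  conflict or shift block). Because the first four V trials already carry
  a small offset and the last four sit below 70, the realised first-4 →
  last-4 cue shift is 56.7 mm in a conflict block (66.7 mm in the control
  block), so the convention contributes a positive offset of a few mm to
  Δy_V relative to the latent bias. An exact-offset variant (pass the
  per-trial offsets) is available but not the default.
* x-dimension recalibration uses target-relative x with zero true shift.
* `per_trial_wv` / `block_wv`: W_v from the VP endpoint's distances to the
  centroids of the 4 nearest V and 4 nearest P trials (nearest by trial
  index, ties to the earlier trial). A trial is invalid when the two
  centroids are closer than 0.5 × the pooled spread (the mean of the two
  clouds' centroid-distance SDs — the package's concrete reading of the
  "< 0.5 SD apart" exclusion) or when both distances vanish; the block
  mean is undefined below 3 valid trials, mirroring the exclusion of
  participants with overlapping unimodal clouds.
* `endpoint_variance_2d`: sample variance (n−1) of the 2D distances from
  the endpoint centroid; translation- and rotation-invariant by
  construction. `corrected_variances` subtracts 0.5 × P-variance from
  each modality's estimate; a negative corrected visual variance is
  reported with a flag, never clamped, so downstream regressions see the
  raw arithmetic.

Estimator noise floors worth knowing: a first-4/last-4 recalibration
estimate carries SD √(2(σ_X²+σ_M²)/4) ≈ 8–9 mm, and W_v from 4-trial
centroids is biased toward 0.5 (at the defaults, generative weights 0.2 /
0.5 / 0.8 are recovered as ≈ 0.33 / 0.50 / 0.68 — monotone but
compressed). Parameter-recovery tests target the unbiased point w_V = 0.5
and the monotone ordering, not the tails.

## Statistical stages

* **Multilevel SAI model**: ΔSAI on four predictors — {veridical,
  conflict} session × {proprioceptive, visual} recalibration — plus
  intercept, participant random intercept, REML (statsmodels MixedLM).
  Inference uses the residual-df convention df = n_obs − 5 with Wald 95 %
  CIs (for the two-session design, df = 44 − 5 = 39). VIF per predictor
  is 1/(1−R²_j) from regressing it on the other three; exact linear
  dependence raises an explicit collinearity error instead of a huge VIF.
  If the REML fit fails or the random-intercept variance collapses to the
  boundary, the fixed-effects OLS fit is reported with `converged=False`.
  The ML-vs-REML and CI-method choices are not pinned by the designs this
  reproduces; REML with Wald CIs is the declared default.
* **Predictor residuals**: residuals of one recalibration predictor after
  regressing out the other, paired with ΔSAI, for partial scatter plots.
* **2×2 within ANOVA** (session × time): computed through the exact
  identity F(1, n−1) = t² of the corresponding difference-score contrast;
  degenerate zero-variance contrasts report F = 0 (identically zero
  effect) or F = ∞ (constant non-zero effect).
* **Group comparisons**: one-way ANOVA with η² and Tukey-HSD pairwise
  comparisons gated on a significant omnibus (no further corrections
  anywhere, matching the design's conventions), or Kruskal–Wallis with
  tie correction where distributional assumptions fail (the change in
  visual variance, by convention).
* Pearson correlations (df = n−2) and two-tailed one-sample t tests with
  Cohen's d; α = 0.05 throughout.

## What the synthetic cohorts do and do not show

The generator emulates: modality-specific biases and noise, gradual
imperceptible conflict, trial-by-trial recalibration with the inverse
modality split, group-level cTBS effects on proprioceptive variance and
recalibration rate, and SAI changes linearly coupled to proprioceptive
recalibration in conflict sessions only. Passing tests therefore show
that the estimators and inference stages recover known ground truth under
these dynamics and noise levels.

They do **not** show robustness to phenomena the generator omits:
proprioceptive drift beyond the bias walk, endpoint outliers, attention
or fatigue drift within a session, non-Gaussian or anisotropic endpoint
noise, between-session carry-over, biophysical MEP variability beyond
amplitude jitter, or any real-data artefact handling (the pipeline
performs no outlier rejection, matching the analysed designs). Tuning
parameters are surfaced in `RunConfig` (variance denominator, W_v
validity threshold and exclusion criterion, MEP search window 15–60 ms —
the window itself is a package default, not a design constant).

## Numerical and reproducibility notes

* One master seed drives everything; per-participant and per-trial
  streams derive via `SeedSequence` spawning, so cohorts are reproducible
  bit for bit and participants are independent of cohort size changes
  only in the aggregate (adding participants re-uses no earlier stream).
* The offset ramp is computed as `k · 70/42` (multiply first) so the last
  VP trial is exactly 70 mm in floating point; the carried offset is
  capped at 70 mm.
* Degenerate inputs raise typed errors (`ScheduleError`,
  `InsufficientDataError`, `SaiError`, `InferenceError`,
  `CollinearityError`, `ParseError`) rather than propagating NaNs, except
  where a quantity is legitimately undefined (block W_v with too few
  valid trials) and is reported as missing with its diagnostic count.
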