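# Methods

This note documents the models, procedures, calibration constants and
numerical choices behind `rdksim`, and what the simulations do and do not
establish.

## Stimulus model

An RDK frame is a set of `n_dots` point dots in a borderless aperture
(degrees of visual angle, origin at the centre, +x rightward). Per frame
transition:

- **signal dots** (count = round-half-away-from-zero of
  `n_dots × coherence/100`; the rounding rule is fixed so coherence
  accounting is exact in tests) translate by `speed × frame_duration`
  along the stimulus direction and wrap modularly at the aperture edge
  (for a circular aperture they re-enter diametrically opposite);
- **noise dots** take a random-direction step of the *same* magnitude
  ("Brownian" rule, `random_walk`, reflected at the edge) or are placed
  uniformly anew (`random_reposition`). The random-walk reading is the
  default; both are available because displacement-matched noise and
  position noise are both common conventions.
- every dot carries an **age**; at age = lifetime − 1 it is regenerated
  at a uniform random location with age 0. Initial ages are staggered
  uniformly over {0, …, lifetime − 1} so expiries are spread from the
  first transition (steady state). Under the default
  `random_per_lifetime` rule, signal flags are re-drawn among regenerated
  dots so the signal count is conserved exactly; `fixed_identity` keeps
  flags with dots for sensitivity analyses.

Two stimulus recipes are built in. The density × frames design uses a
6° × 6° square aperture, 10.5°/s dots, 16.67 ms frames, two-frame dot
lifetime, 100 or 400 dots, five or eight frames, **densities reported
under a circular convention** (area π(6/2)² = 28.27 deg², giving exactly
the published 14.15 and 3.54 dots/deg² for 400/100 dots; the literal
square-area convention is also available). The priming design uses
300 dots in 13.35° × 13.35°, three-frame lifetime, a nominal 16 ms frame
(96/32/160 ms for prime/blank/test with 6/2/10 frames imply 16 ms; a
120 Hz display cannot produce exactly that, and the simulation works in
nominal milliseconds, not refresh ticks). The published density figure
for this stimulus (3.83 dots/deg²) is not reproducible from 300 dots in
that aperture under any convention; it is treated as metadata and never
asserted. Durations are reported as `round(n_frames × frame_duration)`
(five frames → 83 ms; sources that print 84 ms have used a ceiling).

Primes are RDKs of the same geometry: 100% coherent in the same or the
opposite direction as the test, or `static` (no displacement at all —
consecutive frames are identical, ages frozen). The blank ISI does not
participate in dot-age bookkeeping; the test starts from a fresh
steady-state field.

## Observers

**Descriptive (psychometric) layer.** A trial is modelled
detect-then-guess: the observer detects the coherent direction with
probability `q(c) = (1 − 2λ)(1 − exp(−k (c/α)^β))` and reports it;
otherwise it guesses, choosing "left" with probability `bias_left`.
Averaged over balanced directions this yields the 2AFC psychometric
function `P(c) = ½ + q(c)/2`, rising from the guess floor 0.5 to the
lapse ceiling 1 − λ. The constant `k = −ln(2(1 − 0.5^{1/3})) ≈ 0.885`
anchors α to the three-down/one-up convergence point:
`P(α) = 0.5^{1/3} ≈ 0.794` at λ = 0. Defaults: β = 3, λ = 0.01,
`bias_left` = 0.5 (all configurable). The detect-then-guess form (rather
than "correct with probability P, else error") is what makes the
catch-trial bias probe behave like its empirical counterpart: at
near-zero coherence responses are pure guesses, so the proportion of
"left" responses estimates `bias_left` directly.

**Mechanistic (undersampling) layer.** The frame-reading observer gets
dot correspondence for free (the hypothesis under study concerns
sampling capacity, not motion correspondence): for each transition, each
dot alive on both sides votes the sign of its (minimal-image-unwrapped)
horizontal displacement with probability `p_sample`; votes are pooled
over `integration_frames` transitions (default: all), Gaussian internal
noise (SD `internal_noise_sd`) is added, and the response is the sign of
the total (uniform guess at exactly zero). Defaults
(`p_sample` 0.12 control / 0.06 dyslexia-like, noise SD 50, all
transitions) come from the vote-statistics calculation
μ = p·c·n·s·T, σ ≈ √(p·n·s·T + σ_int²) with s = (lifetime−1)/lifetime
survivors per transition: they place high-density thresholds in a
measurable 25–45% range while low-density thresholds approach the
staircase cap, so temporal recruitment (lower thresholds with more
frames) is clearly expressed at high density and attenuated at low
density — the qualitative pattern the mechanistic layer is meant to
exhibit. Reducing `p_sample` raises thresholds monotonically.

The two layers are deliberately not unified: the descriptive layer
*encodes* group differences (larger α, larger same-prime shift), the
mechanistic layer *generates* them from a capacity parameter. The
pipeline never claims to infer mechanism from the descriptive fit.

## Cohorts and calibration

Between-subject thresholds are log-normal with specified arithmetic
group mean and SD (SD 0 collapses to the mean). Calibration constants:

| quantity | control | dyslexia | source |
|---|---|---|---|
| α mean, density×frames design | 32.74 | 47.09 | published marginal means |
| α SD (same design) | 11.5 | 11.2 | inverted from published t-based 95% CIs (n = 22/21) |
| α mean/SD, priming design | 16 / 5 | 24 / 6 | calibration choice (baselines not published numerically) |
| same-prime shift (points) | +7.87 | +12.63 | published difference scores |
| opposite-prime shift (points) | −2.03 | −2.76 | published difference scores ("enhanced" = threshold reduced) |

Prime shifts are **additive coherence points** (the dependent variable's
natural unit), not multiplicative percent change, and are fixed per
group; the published difference-score SDs are metadata only, so
simulated difference-score spread reflects staircase measurement noise
alone. For the density × frames design the published cell means are not
available; per-condition offsets are calibrated so cell means average to
the group marginal mean, the density main effect splits symmetrically
(±5 points), recruitment is confined to high density (5f − 8f = 6.1 /
7.5 points for control/dyslexia) and absent at low density. This is
calibration, not estimation.

## Staircase

Three-down/one-up with halving/doubling (symmetric octave steps in log
coherence), start 50% (density×frames design, 8 reversals) or 25%
(priming design, 6 reversals), clamped to [0.1, 100]% — doubling past
the cap clamps and still counts toward reversal logic. A reversal logs
the **pre-step** coherence at the flip; the block threshold is the
geometric mean of all logged reversals (`discard_first_k` available,
default 0), blocks combine by geometric mean, and a hard cap of 400
trials flags (never raises on) non-convergent blocks. Catch trials run
at 1% coherence, one per five-trial window at a uniformly drawn slot,
constrained so consecutive catch indices differ by at most five — hence
*every* five consecutive trials contain one; catch responses never touch
the staircase state. Response bias = % "left" among catch responses.

Note the pre-step vs "midpoint" (√(pre×post)) reversal-value conventions
produce *identical* block estimates here: with alternating reversals the
√factor terms cancel in the geometric mean.

## Known estimator properties and limitations

- **Ladder quantisation.** Halve/double steps restrict tested coherences
  to `start × 2^k`. The geometric-mean-of-reversals estimate is
  accurate near rungs but systematically compresses thresholds lying
  high between rungs (up to ≈ −10% relative around 1.5 × start). In
  particular, an additive +12.63-point shift applied to a 24% baseline
  (→ 36.6%, mid-rung between 25 and 50) is measured as ≈ +10.3 points on
  average. This is intrinsic to the procedure, affects empirical use of
  the same staircase equally, and is surfaced (not hidden) by the
  end-to-end recovery tests.
- **Precision.** Single-block estimates have relative SD ≈ 10–18%
  (β = 3); two-block combination gives median absolute relative error
  ≈ 11% across α ∈ [15, 60], with rank correlation ≈ 0.9 between true
  and estimated thresholds over a cohort.
- **Convergence.** Mean accuracy over the final 20 non-catch trials of
  500 simulated blocks is ≈ 79.2%, matching the p³ = ½ equilibrium
  (79.4%) of the rule.

**What the synthetic data do not emulate:** learning, fatigue or
sequential dependencies across trials; lapse-rate heterogeneity;
eye movements, display luminance/contrast or refresh quantisation;
attentional dynamics of prime-test sequences (prime effects enter as
additive threshold shifts, or not at all for the mechanistic path, which
would be dominated by a 100%-coherent prime if fed the full composite
sequence). Passing tests therefore validate the procedure's arithmetic
and statistical behaviour, and the internal consistency of the
calibrated pipeline — not the empirical claims about human observers.

## Problem sizes used in the test and acceptance runs

Chosen as the package's own defaults: 500 blocks for convergence
accuracy, 200 simulated participants for threshold recovery, 100 paired
simulations per cell for the mechanistic recruitment comparison, and 40
replicated cohorts of 10 per group for the priming-recovery check
(a single cohort's group-mean difference score has Monte-Carlo SE
≈ 1.5–2 points; replication isolates the systematic component).
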