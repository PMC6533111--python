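# Methods

## The task and its generative process

The estimation task asks a participant to report, on an integer scale of
10–25 litres, the amount of fuel in a motorbike tank, given (i) cued prior
information — the usual fuel amount μ̄ ∈ {15, 20} L and the usual accuracy
of the gauges (low vs high *expected variability*) — and (ii) two noisy
gauge readings g₁, g₂.  The simulator reproduces the design's statistics
exactly:

* true fuel μ ~ N(μ̄, 3²);
* g₁, g₂ ~ N(μ, σ²) independently, with σ = 4 L on low- and σ = 7 L on
  high-expected-variability trials;
* μ, g₁, g₂ rounded to the nearest integer (halves away from zero — all
  quantities are positive, so this is ordinary round-half-up of an
  instrument reading) and clipped to [10, 25]; clipped draws are kept, not
  redrawn.  Raw pre-rounding draws are retained in the trial table so the
  generative SDs can be validated directly.

Trials come in blocks of 5 sharing the same prior cue; each 120-trial
session holds a balanced multiset of the 4 (expected value × expected
variability) conditions in seeded pseudo-random order, and the default
experiment is 4 sessions (480 trials, 120 per condition).  Session streams
are sub-seeded deterministically from the master seed, so a configuration
reproduces its tables bit-for-bit.

Nominal trial onsets are spaced 10 s apart (configurable) purely so event
export is well-formed; the design specifies no inter-trial timing.
Reaction times are nuisance plumbing: 2·LogNormal(0, 0.3) seconds.

## The observer model

Derived per trial from the gauge readings: the observation mean
μ_g = (g₁+g₂)/2, the observed variability v_g = |g₁−g₂|, and the
prediction error PE = |μ̄ − μ_g|.  v_g is z-scored over the subject's full
trial set (population SD, so the z-scores have mean exactly 0 and SD
exactly 1), giving v_g′.

The observer's point estimate is a weighted average

μ̂ = w·μ_g + (1−w)·μ̄,  w = 1/(1 + exp(v̄ + a_g·v_g′)),

with v̄ = v̄_L or v̄_H by expected-variability condition, and the overt
response is Gaussian around it,

R ~ N(μ̂, (ω̄ + b_g·v_g′)²),  ω̄ = ω̄_L or ω̄_H.

Free parameters of the full model: v̄_L, v̄_H, a_g, ω̄_L, ω̄_H, b_g.  Four
reduced variants tie v̄_L=v̄_H, fix a_g=0, tie ω̄_L=ω̄_H, or fix b_g=0;
a baseline model draws R from a fixed N(m, s²) ignoring trial structure.
All observer variants share one likelihood via parameter-tying maps.
The qualitative predictions are v̄_H > v̄_L, a_g > 0, ω̄_H > ω̄_L,
b_g > 0: less reliable observations pull the estimate toward the prior and
make responding more stochastic.

A normative reference, w* = (n/σ_o²)/(n/σ_o² + 1/σ_p²) for the mean of
n = 2 readings, anchors the sigmoid's expected ordering: with prior SD 3
and gauge SDs 4/7, w* ≈ 0.53 (low) vs 0.27 (high), i.e. a lower weight on
less reliable gauges.  It is a validation baseline only, not part of the
fitted model.

### Numerical choices

* The logistic is evaluated as `expit(-exponent)`: branch-free, no
  overflow; it saturates to exactly 0/1 beyond |exponent| ≈ 37, which is
  irrelevant at fitted parameter scales.
* The likelihood is the **continuous** Gaussian density evaluated at the
  integer response — no truncation at 10/25 and no integer binning.  This
  is a deliberate modelling choice; it is a good approximation while the
  response SD stays well above the rounding quantum (≳ 0.5 L) and
  responses rarely hit the scale ends, and a poor one for near-deterministic
  observers (see Limitations).
* SD-positivity (ω̄ + b_g·v_g′ > 0 on every trial of the data being
  fitted) is enforced by rejection: the public likelihood returns +inf for
  violating parameter vectors.  Inside the optimizer the objective instead
  returns a large finite penalty (1e10) with a slope back toward the
  feasible region, so line searches do not stall on infinities.

## Fitting and model comparison

Per subject and variant, the NLL is minimised by multi-start bounded
Powell search (default 20 starts drawn from fixed uniform boxes:
v̄ ∈ [−4, 4], a_g ∈ [−2, 2], ω̄ ∈ [0.2, 6], b_g ∈ [−2, 2], m ∈ [10, 25],
s ∈ [0.2, 8]; optimizer bounds are wider), followed by a tight
Nelder–Mead polish of the winning start (Powell alone can stall a few
tenths of a nat short of the optimum on this likelihood, which is enough
to blur parameter-recovery correlations).  Ties between starts break
toward the lowest start index; results are bit-reproducible given (data,
seed, settings).

Comparison uses BIC = k·ln(n) + 2·NLL computed per subject with that
subject's trial count and summed across subjects, plus McFadden's
pseudo-r² = 1 − NLL_model/NLL_baseline on the summed NLLs, and a count of
per-subject BIC winners (ties toward fewer parameters).  Split-half
reliability randomly halves each subject's trials (unstratified by
default; a degenerate no-split mode exists for identity checks), refits
each half with v_g re-z-scored within the half, and correlates the two
half-estimates across subjects per parameter.

An exhaustive grid-search oracle over the variant's free parameters
(capped at 10⁶ points) provides an optimizer-independent check on small
instances; it lives in the library but is used only by tests.

## Synthetic cohorts

`generate_cohort` simulates independent subjects (default 33, the study's
cohort size) with per-subject parameters from a documented sampler:
Gaussians centred on the predicted pattern (v̄_L: −0.1 ± 0.5, v̄_H:
1.0 ± 0.5, a_g: 0.5 ± 0.25, ω̄_L: 1.5 ± 0.4 L, ω̄_H: 2.5 ± 0.6 L, b_g:
0.4 ± 0.2 L), truncated at ±2 SD and floored so ω̄ > 0.  The v̄ centres
correspond roughly to the normative weights above.  Truncation reflects
that empirical per-subject parameter clouds are bounded, and it excludes
near-deterministic observers (w → 1 with sub-litre noise) for whom the
continuous-density likelihood is a knowingly poor description of rounded,
clipped button presses — for such tail draws the global MLE can sit in a
different parameter regime, which is a property of the modelling
approximation, not of the fitting machinery.  Sampled parameter sets that
violate SD-positivity on a subject's trials are resampled and counted.

What the generator does *not* emulate: learning or drift across the
session, previous-trial (sequential) effects, lapses/attentional slips,
motor noise in the cursor interface, and any deviation of real humans
from the observer family itself.  Passing recovery tests therefore shows
the pipeline identifies the model's parameters from data the model
generated at realistic sizes — not that human data obey the model.

## Validation performed by the test suite

* Generative SDs (3/4/7 L) recovered from ≥20,000 pre-rounding draws per
  condition within 3 Monte-Carlo standard errors; exact design constants
  (480 trials, blocks of 5 with constant cue, perfect balance).
* Published model-comparison arithmetic: pseudo-r² from the printed summed
  NLLs reproduces .2141 (full) and .2120 (a_g-ablated) exactly at 4
  decimals; baseline pseudo-r² is 0 identically.
* Parameter recovery: 33 subjects × 480 trials; recovered-vs-true Pearson
  r ≥ 0.7 for all six parameters (observed ≈ 0.79–0.98).
* Directional prediction tests all significant on that cohort; on an
  ablated cohort (all four effects removed) no contrast is significant in
  the predicted direction and all contrast magnitudes are < 0.2 — the
  null check is directional because the hypotheses are directional, and a
  two-tailed excursion opposite to the prediction (which one omega
  contrast shows on the fixed cohort seed, within ~6% of the generated
  effect size) is a null outcome for a positive prediction.
* Model recovery: the generating (full) variant attains the lowest summed
  BIC in ≥ 70% of 20 seeded repetitions at 5 subjects × 480 trials with 8
  optimizer starts — a scale chosen to keep the whole suite comfortably
  under a half hour on one CPU while leaving the per-repetition inference
  problem at full trial count.
* Optimizer vs grid oracle agreement on small instances; the algebraic
  identities (weighted-average ≡ delta-rule form of μ̂; PE_w = |w·(μ_g−μ̄)|
  ≤ PE) on randomized inputs; GLM-1 centring contracts.

## GLM event export

Stick regressors are exported as zero-duration events; HRF convolution
and estimation are downstream concerns.  GLM-1 centres PE and RT within
condition but leaves v_g raw: the conditions differ in mean v_g by
design, so demeaning within condition would make equal "centred v_g"
correspond to different raw disagreement across conditions and bias the
high-vs-low contrast.  GLM-2's modulator v̄ + a_g·v_g′ (the linear part
of the prior weight 1−w) uses group-mean fitted parameters applied to all
subjects and is exported uncentred for the same reason — it differs
between conditions by construction; the event-table metadata records the
centring state of every modulator either way, and a self-check recomputes
it from the emitted values.  The feedback regressor carries the centred
outcome PE |feedback − R|.  No serial orthogonalization is applied.
Equal-count modulator binning (stable rank, ties by trial order) supports
display-style GLMs.

## Known limitations

* The continuous response likelihood ignores rounding and clipping of
  responses; fitted ω̄ absorbs the rounding variance (~1/12 L²) and edge
  effects, and the approximation degrades sharply for response SDs near
  or below 0.5 L.
* The sigmoid weight is a descriptive link, not a derived posterior; the
  normative precision-ratio weight is used only to anchor expected
  orderings.
* Split-half fitting at 240 trials per half is noticeably noisier than
  full-data fitting; reliability r values from small demonstration
  cohorts carry wide confidence intervals.
* No hierarchical pooling across subjects and no cross-validation-based
  model comparison; per-subject point estimates with BIC mirror the
  analysis approach this package implements.
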