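# Methods

## Blink detection

Blinks on frontal EEG are slow (~300 ms), large, roughly triangular
deflections; saccades are small and fast.  The detector works per channel
on the 1–20 Hz band (4th-order Butterworth, applied forward–backward so the
effective filter is zero-phase and peak latencies are preserved).  Candidate
events are maximal runs above mean + 1.5 SD of the filtered channel
(statistics over the whole segment, so the threshold is invariant to DC
offsets), kept when they last more than 50 ms; runs closer than 50 ms are
pruned keeping the larger peak, which enforces the minimum inter-blink
interval by construction.  A constant channel (SD = 0) produces no
candidates rather than an error.

Two quality scores decide acceptance:

* **tent correlation** — Pearson correlation between the event segment and
  the two-piece linear template anchored at its onset, peak and offset
  samples.  Correlation is affine-invariant, so anchoring at the observed
  endpoint values is equivalent to the best-fitting tent of that shape.  An
  exact triangle scores 1.0; events must exceed 0.90.
* **pAVR** — 100 × (peak amplitude above the local baseline) / (maximum
  rising-limb velocity, units/s).  The baseline is the mean of the 100 ms
  flanking windows.  The velocity is estimated as the least-squares slope
  of the rising limb between 20 % and 95 % of the amplitude: for a
  piecewise-linear event this equals the true slope exactly, and the
  regression makes the estimate robust to sample-to-sample noise that would
  dominate a raw first difference.  For a triangle with rise time t_r the
  score is 100·t_r (seconds), so the acceptance floor of 3 rejects events
  rising faster than ~30 ms — saccades — while blinks with ~120 ms rises
  score ~12.  The exact normalization of this ratio is a design choice of
  this package (published descriptions fix only the comparison direction:
  low values are saccades); both thresholds are exposed as parameters.

The per-minute rate is taken from the single best channel — most accepted
blinks, ties broken by higher median tent correlation — matching the
practice of picking the one channel that sees blinks most cleanly rather
than merging channels with different gains.

## Synthetic EEG

Simulated recordings are additive: per-channel-scaled tents (default rise
120 ms, fall 180 ms, amplitude 100 units — physiologically plausible blink
kinematics), saccade surrogates (20 ms ramps to 0.4× blink amplitude with a
150 ms plateau, giving exactly the high velocity-to-amplitude profile the
pAVR criterion must reject), and white Gaussian noise (default SD 10, i.e.
amplitude SNR 10).  A frontal gradient (Fpz 1.0 → FC3/FC4 0.45) makes
channel selection non-trivial.  The tent is piecewise linear rather than
Gaussian so the tent-correlation criterion has an exact-match case.  The
generator deliberately omits real EEG rhythms (alpha/beta), slow drifts and
eye-movement physics: passing tests demonstrate that the detector
implements its stated criteria and recovers known events under white noise,
not that it matches any particular toolbox on recorded EEG.

Configs are rejected when blinks would overlap (separation must exceed
50 ms plus rise+fall) or when fs < 100 Hz cannot represent 50 ms events.
Every generator is a pure function of its config, including the seed.

## Participant and response simulation

Participants follow the structural model X→M→Y with quadratic X paths
(X sEBR, M flexibility, Y originality).  Defaults: X ~ Normal(10.76, 6.05)
truncated above 0.5 blinks/min, so the mean ∓ 1 SD evaluation points fall
at 4.71/10.76/16.81; a₁ = 0.134, a₂ = −0.004 put the inverted-U vertex of
the a-path at ≈16.8 blinks/min (the high evaluation point), b = 0.4,
c₁ = 0.05, c₂ = −0.0015 keep a weaker direct path, σ_M = 0.6, σ_Y = 0.4
give latent scores spanning realistic flexibility (~2–4 categories) and
originality (~2.5–4 on the 1–5 scale).  With these values the
instantaneous indirect effect is positive at the low/moderate points and
≈0 at the high point — the regime the analysis is designed to detect.

AUT responses: per object a participant produces a Poisson number of ideas
around a participant-level propensity (default mean 4.6/object, ~23 ideas
per participant, ~1700 in a 73-person cohort); the number of distinct
categories drawn from the per-object codebook tracks latent flexibility;
response strings get Zipf-distributed identifiers within category so
statistical infrequency varies across the sample.  Rater scores are a
shared idea quality (participant's latent originality + idea noise) plus
independent rater noise, clipped to [1, 5].  The rater noise is calibrated
from the ICC(2,k) closed form s_q²/(s_q² + s_e²/k) using the *realised*
between-idea quality SD, so the computed ICC lands on the target (default
0.88) regardless of the participant model.  Scores are kept continuous:
rounding to integers would add uniform noise (variance 1/12 per rater) and
bias the calibration downward by ~0.05.  Clipping introduces a small
remaining downward bias, accepted and covered by the ±0.05 round-trip
tolerance.

## AUT scoring decisions

Response equivalence is exact string match after normalization
(lower-casing, punctuation stripping, removal of a configurable
filler-phrase list, leading-article removal, rule-based singular/plural
unification, iterated to a fixed point so the transform is idempotent).
Curators extend the phrase/plural lists in config rather than editing code,
keeping matching reproducible.  The per-participant frequency-based score
pools the participant's responses across objects (rather than averaging
object means); with five objects of similar response counts the two differ
negligibly.  Judge consensus after large rating discrepancies is modelled
as an optional override column, not an algorithm.  The ICC variant is
ICC(2,k) — two-way random effects, absolute agreement, average measures —
computed by `pingouin` and labelled in the output to avoid silent variant
mismatch; with two fixed-role judges averaged per idea this is the variant
that describes the reliability of the mean rating actually used.

## Regression and power

The hierarchical fit reports raw-unit estimates, standardized betas, SEs,
t, two-sided p, per-step R² and ΔR² (non-negative by nesting), and flags
observations with internally studentized residuals beyond ±3.  The robust
companion is an MM-type estimator: median regression (LAD) start, residual
MAD × 1.4826 as a fixed scale, then IRLS with Tukey's bisquare at
c = 4.685 (95 % efficiency under Gaussian errors); standard errors use the
M-estimator sandwich form and the R² analogue is weighted by the final
bisquare weights and labelled as such.  On clean data the robust and OLS
estimates agree to well under 1 %; under 5 % gross contamination the
robust slope moves by far less than the OLS slope (both are asserted in
tests).  A constant outcome returns zero slopes; non-convergence of the
IRLS raises with diagnostics rather than returning a half-iterated fit.

Sample-size planning uses the noncentral F distribution: power =
P(F' > F_crit) with noncentrality λ = f²·N and denominator df = N − p − 1,
scanned over integer N.  Testing a single coefficient among three
predictors (numerator df = 1) at f² = 0.15, α = .05, power = .80 gives
N = 55; the omnibus test of all three predictors (numerator df = 3) gives
N = 77.  Both readings are callable; df = 1 is the default.

## Mediation

Both structural equations are fit by OLS; under the linear a-path spec a₂
is exactly zero by construction, in which case θ(x) = a₁·b for every x
(the classical product of coefficients).  Evaluation points default to
mean ∓ 1 SD (n−1 SD) of the observed predictor; an explicit triple can be
passed.  Confidence intervals are percentile intervals from a
case-resampling bootstrap over participants (default 5000 resamples),
chosen over BCa for transparency and because the percentile interval is
the conventional presentation for this effect; resampling cases rather
than residuals respects the individual-level data structure.  The
bootstrap refits are vectorised batched normal-equation solves, so 5000
resamples cost milliseconds; a singular resample (possible only in
degenerate samples) is redrawn and counted.  All stochastic outputs are
bit-reproducible under the spec seed.  An optional centering flag squares
the mean-centred predictor; θ evaluated at original-scale points is
invariant to this, which the tests assert.

Calibration, checked by simulation in the test suite: under a null b = 0
(n = 200, 500 replicates, 1000 resamples) the moderate-point 95 % CI
excludes zero at the nominal 5 % ± 2.5 rate; the nominal 95 % interval
covers the generating θ at 95 % ± 3 (200 replicates); and at n = 73 with
the default inverted-U population the low/moderate-significant,
high-null CI pattern obtains in the majority of replicates.

## Problem sizes and limitations

The shipped analyses use a 73-participant cohort, 3-minute recordings at
256 Hz, ~1700 ideas, and bootstrap/replicate counts of 1000–5000; these
sizes make every documented calibration check computable in minutes on one
CPU while leaving the estimators' asymptotics visible.  Known limitations:
the detector is validated against its own signal model, not recorded EEG;
frequency-based originality is nearly degenerate when most simulated
response strings are unique (its variance shrinks, as it does in small
real samples); mediation here is associational — nothing in the machinery
licenses causal claims beyond the model's assumptions.
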