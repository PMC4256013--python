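# Methods

## Task and protocols

Every trial presents two tones (50 ms each in the original setting —
timing is not modelled) and the observer reports which was higher in
frequency.  Five stimulus-arrangement rules are implemented:

- **reference-lower** — one tone is a constant 1000 Hz reference, the
  other sits `d`% above it; the reference's interval is a fair coin.
- **reference** — as above, but the comparison is above or below the
  reference with equal probability, independently of its interval.
- **reference-first** — reference always first, comparison above/below.
- **reference-higher** — comparison always below, interval a fair coin.
- **no-reference** — a base tone is drawn uniformly from 800–1200 Hz,
  the other tone sits `d`% above or below it, and the base's interval is
  a fair coin.

Frequencies are handled internally as natural logarithms (the base of
the logarithm only rescales model weights) and converted to Hz at the
generation and I/O boundaries.

## Adaptive staircase

The frequency difference `d` follows a transformed 3-down-1-up track:
three consecutive correct responses lower `d` by one step, every error
raises it by one step.  The track starts at 20% and the step sizes run
4.5, 2, 1, 0.5, 0.1%, advancing after every fourth reversal (a change in
movement direction; the first movement sets direction without counting)
and taking effect on the following movement.  Reversals accumulate
across step levels.  Such a track converges where p_correct³ = ½, i.e.
at 100·0.5^(1/3) ≈ 79.4% correct, and the block JND is the mean % difference
over the final 20 of the 80 trials.

Two bounds are imposed that the procedure's usual description leaves
open: a floor of 0.1% (the smallest step), preventing zero or negative
differences, and a ceiling of 80%, keeping all stimuli positive in
designs where the comparison can sit below the reference.  The ceiling
binds only for observers at or below chance; any observer with a finite
psychometric slope is held far beneath it.

## Observer models

All models map a trial to P("first higher") through the probit link.
The history-sensitive decision variable is

    D(t) = a₀x₁(t) + Σₖ₌₁..K aₖ x₁(t−k) + c·m(t) − x₂(t)

with m(t) the running mean of the first-tone logs of the *completed*
trials of the block (the current trial's first tone is excluded: the
prior exists before the observation it biases).  The memory-trace model
is P = Φ(D/σ) with the weights fixed and σ the single fitted parameter;
the naive model is Φ((x₁−x₂)/σ); the response-bias model is
Φ((x₁−x₂)/σ + β), with the bias applied inside the probit argument on
the same scale as the normalised evidence.

**Default weights.**  K = 3 lags; weight on the second tone fixed at −1;
a total contraction fraction γ = 0.35 is moved from the current first
tone onto its history (a₀ = 1 − γ), half of it onto the running-mean
trace (c = 0.175) and half spread over the three lags with geometric
decay 0.6 (a₁..a₃ ≈ 0.089, 0.054, 0.032).  The weights sum to zero with
the −1, so the models are invariant to a common shift of all
log-frequencies.  These defaults are package configuration — chosen once
to give contraction of realistic strength and direction — not estimates
from any dataset; analyses that depend on the precise weight profile
(e.g. exact split percentages, model-comparison win rates) should be
read as properties of this default observer.

**Early trials.**  A lag or trace term with no completed trial behind it
takes the value of the current x₁ (self-anchoring).  This keeps the
weight sum at zero on every trial — otherwise a missing term of weight
`a` would shift the probit argument by `a`·x₁ ≈ 6.9·a log-units, an
artifact several times σ — and makes trial 1 exactly history-free.

**Default noise.**  σ = 0.04 log-units, set so a history-free observer
tracked by the staircase lands at a JND near
100·Φ⁻¹(0.794)·σ ≈ 3.3%, inside the 3–4% range typical of naive
listeners on this task.

## Fitting and model comparison

Each block is fitted independently by maximum likelihood.  σ is
optimised as log σ (positivity by construction); starting points are
drawn from Normal(0, 10) in the fitted space (log σ, and β where
present), 100 per fit by default, each refined with Powell's
derivative-free method, keeping the best optimum.  Per-trial
probabilities are clipped to [1e−12, 1 − 1e−12] before logging so
degenerate parameter proposals keep finite likelihoods.  With a seeded
generator a fit is bit-reproducible, and the first start of a larger
multistart coincides with that of a smaller one drawn from the same
stream.

Models with equal parameter counts are compared per block by
log-likelihood, unequal counts by BIC = k·ln n − 2·lnL (the extra
parameter pays ln 80 ≈ 4.38 nats); exact ties score half a win to each
side.  The comparison report includes per-block BIC differences, a
paired t-test on the comparison criterion, and — when the caller
supplies per-block interval-bias magnitudes — Pearson and Spearman
correlations of BIC difference against bias magnitude, with constant
inputs flagged rather than propagated as NaN.

## Bias statistics

Trials are pooled within participant (across that participant's blocks)
before computing percentages; population statistics (mean ± SEM, paired
two-sided t-tests, Cohen's d = mean(diff)/SD(diff)) are across
participants.  A participant missing one side of a split is excluded
from that split and logged; ties in "fraction of participants better"
count one half.  No multiple-comparison correction is applied.  The
splits: reference interval (Ref1/Ref2, optionally excluding each block's
first 30 trials to remove the staircase's descent), higher tone,
Bias+/Bias−, Repeat/Alternate, plus the "first higher" response rate.

**Bias classification.**  Trial t is Bias+ iff (m(t) − x₁)(x₁ − x₂) > 0 —
contraction of the remembered first tone toward the running mean
enlarges the perceived difference in the correct direction — Bias− iff
negative, neutral at equality; trial 1 is neutral.  The running mean is
used, consistent with the memory-trace model's trace term.  Note that
with this choice the Bias± labels are nearly independent of the
Repeat/Alternate labels even in the reference-lower design; a trace
dominated by the immediately preceding trial would instead align Bias+
with Ref2-repeats there.

**Subset JNDs and the ratio r.**  Interleaved staircase subsets share
the same tracked differences, so the last-20 rule cannot separate them.
Subset JNDs (for r = JND_Ref1 / JND_Ref2) therefore come from a
one-parameter probit psychometric fit P(correct|d) = Φ(d/s) over that
subset's (unsigned % difference, correctness) pairs, with
JND = s·Φ⁻¹(0.794).  The fit pins chance at d = 0 and cannot represent a
shifted point of subjective equality, which the reference-lower design
induces; r is therefore a directional summary (r > 1: worse Ref1
acuity), not an absolute threshold estimate.

## Synthetic experiments

A simulated block closes the loop staircase → stimuli → observer
probability (memory built from the block's own past first tones) →
sampled response → staircase and memory update.  Memory does not carry
across blocks.  Experiment defaults mirror the two study designs: 49
participants × 2 blocks (reference-lower) and 152 × 1 (reference), 80
trials per block.  Per-block generators derive from a master seed via
seed sequences spawned on (participant, block), recorded in a manifest,
so datasets regenerate bit-identically.  A closed-loop comparison
utility fits σ per recorded block, resimulates each participant with
their fitted noise (full staircase re-run by default; a replay mode
redraws responses on the recorded stimulus sequence), and computes the
same splits on both sets.

The generator emulates the designs' stimulus statistics and response
stochasticity only.  It does not model lapses, attention or learning
across a session, audio rendering, or inter-individual weight
differences (σ can vary per participant; the contraction weights are
shared).  Passing tests on synthetic data therefore certify the
pipeline's internal consistency and the mechanism's qualitative
behaviour, not quantitative agreement with any particular human cohort —
in particular, simulated split percentages differ from recorded ones by
a few points because the default weights are not fitted to any cohort.

## Problem sizes and numerical choices

The test suite simulates 49×2 and 60–200×1 block sets for the split
analyses, 150 participants per protocol for the bias-direction and
dissociation checks, and 12–50 blocks per noise level for parameter
recovery, with 10–25 multistarts in fitting tests; the acceptance script
uses the full study-sized designs and 100 multistarts.  These sizes give
sub-point standard errors on the reported percentages while keeping a
complete run in the minutes range.  Staircase convergence is measured on
trials after the 30th, once the track has left its supra-threshold 20%
start; the raw block average, which includes the easy descent trials,
runs 1–3 points above the asymptote by construction.

Known limitations, beyond those noted above: the contraction weights are
configuration, so quantities tied to their exact values (win rates, r
medians, split magnitudes) are directional rather than calibrated; and
deposited-data decoding assumes the documented MAT layout (s1/s2/c
matrices of shape blocks × trials plus an optional participant vector
discovered by shape and logged by name).
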