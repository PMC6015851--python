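# Methods

## The measurement model

A *contest* is one pair-session: a 5-trial block whose winner is the
rat taking the majority of trials.  Trials per pair is configurable but
must be odd so a strict majority always exists.  Within a cage-session,
each trial win is worth two points; a rat meets its three cage-mates,
so scores range 0–30 and the cage total is exactly 60 (conservation:
2 × 30 trials).  Scores order the four rats into ranks 1–4.

**Tie policy.**  The protocol defines only the two-way rule: equal
scorers are ordered by their own block's winner.  Multi-way and cyclic
ties need a total, deterministic extension; ours is, in order,
(1) head-to-head session wins within the tied set, when those are all
distinct (the two-way rule is the special case), (2) total trial wins
in the session, (3) rat id.  Every fallback use is recorded in
`SessionRanking.tiebreaks_applied`, and the whole policy is verified in
the tests against an independent brute-force implementation that
enumerates all 24 orderings and selects the unique one consistent with
the rules.

## Variability metrics

For a rank trajectory r₁…rₙ (n = 10 sessions by default):

* **normalized variance** = sample variance (n−1 divisor) ÷ the maximum
  sample variance attainable by any length-n sequence with entries in
  the rank range, × 100.  An extremal sequence places every entry at an
  endpoint of the range (moving an interior value to the farther
  endpoint cannot decrease the sum of squares), so the maximum is
  max over k of k(n−k)(hi−lo)²/(n(n−1)); for n = 10 and ranks 1–4 this
  is 2.5, attained by five sessions at rank 1 and five at rank 4.  The
  divisor choice matters: only the n−1 convention yields 2.5.  The
  closed form is checked against exhaustive enumeration for n ≤ 6.
* **stability** = fraction of the n−1 consecutive-session transitions
  with rank unchanged, × 100 (9 transitions = 100% at n = 10), blind to
  the size of a change.

Both are computed for the full trajectory and separately for sessions
1–5 and 6–10.  Whether a half's variance should be referred to the
half-length maximum or the full-length one is not fixed by the
protocol; the default re-normalizes per half (`renormalize="half"`),
with the alternative available, because a half should be scored against
what a 5-session sequence can do.

**Subgroups.**  Animals with late-half (sessions 6–10) stability ≥ 75%
are labelled hyper-stable, ≤ 25% hyper-unstable, otherwise
intermediate.  The bimodal split of knockout stability is an empirical
observation without a published cut-off, so the thresholds are policy,
exposed in `RunConfig.subgroup_thresholds` and reported with every
count.  Note the 25% band is strict: with only four late-half
transitions it admits at most one retention.

## Statistical conventions

* χ² goodness of fit of two win counts against an even split, **no
  continuity correction** (for counts a, b the statistic is
  (a−b)²/(a+b) on 1 df).  The uncorrected convention is anchored by the
  reconstruction of the mixed-cage win contrast: 172 vs 108 wins over
  280 contests gives χ² = 14.63 to two decimals; a Yates-corrected
  statistic would not.
* Pooled-variance Student *t* with df = n₁+n₂−2, anchored by the
  printed degrees of freedom (278 for 140+140 rank observations; 26 for
  12+16 single-line rats).  Welch is available but not the default.
  The *t* on mixed-cage average rank admits two data layouts; the
  default treats each rat-session rank as an observation
  (`rank_contrast_unit="rat_session"`, giving df = 278 at the full
  design), with per-rat means as the alternative.
* Pearson *r* with a two-sided p from the *t*-transform on n−2 df, plus
  the least-squares slope of the late measure on the early one — a
  slope below 1 (regression line shallower than 45°) signals
  regression toward instability across repeated testing.

## Phase-II analyses

A rat's **rank class** collapses its phase-I trajectory to high (ranks
1–2) or low (3–4).  The default aggregation is the final phase-I
session's rank — the rank the animal had assumed by the end of
within-cage testing — with modal and rounded-mean alternatives, since
the aggregation is not pinned down by the protocol; the choice is
logged in the outputs.  Because ranks 1–2/3–4 split every cage 2/2,
exactly 8 of a tournament's 16 pairs are high-vs-low; the main
experience contrast uses only those, and the excluded high-vs-high and
low-vs-low contests feed the conditional genotype contrasts.
Genotype cross-tabs tally cross-genotype contests only, optionally
filtered to a cage-type pairing (single-vs-single, mixed-vs-mixed,
WT-cage-vs-mixed, KO-cage-vs-mixed).  Counting is contest-level by
default (`count="contests"`), matching the session-winner semantics;
trial-level counting is available behind the same flag.

## The contest simulator

No raw records are distributed with the study design, so the pipeline
is exercised end-to-end on synthetic data with the statistical
structure the analyses assume.  Each rat carries a latent strength θ;
rat i beats rat j on a trial with probability
σ(β(θᵢ−θⱼ)) (logistic σ).  Three mechanisms act on θ:

1. **Winner/loser updating** — after each contest the session winner
   gains `delta_win` and the loser drops `delta_loss` (the session,
   not the trial, is the behavioural unit).  These increments persist,
   carry into phase II, and are what makes phase-I rank predictive of
   contests with strangers.
2. **Transient volatility** — each session a rat expresses θ plus a
   Gaussian "form of the day" whose scale is genotype-specific and,
   via a median-one lognormal multiplier, an individual trait.  Form
   is transient rather than a random walk: a random walk would erase
   the persistent structure that makes early stability predictive of
   late stability, and day-to-day consistency is treated as a stable
   characteristic of the animal.
3. **Lock-in** — with probability `p_lock_ko` a knockout adopts a
   fixed extreme strategy at study start, "bully" or "submissive"
   (equally likely; the split is balanced across the study to within
   one animal), pinned at ±`lock_magnitude` plus a persistent
   half-normal individual offset (so two same-strategy cage-mates are
   not exact ties) and immune to updating and volatility.  Locked rats
   sit immovably at the top or bottom of their cage — the hyper-stable
   knockouts — while unlocked knockouts churn.

Draw order is fixed (weights, baseline strengths, lock assignments,
then per session: forms in sorted rat order, then trials in canonical
cage/pair order), so a scenario and seed reproduce byte-identical
records.  Phase II runs from the end-of-phase-I strengths with the
same updating; `reset_theta=True` ablates the carryover.

### Default parameterization

The defaults (θ₀ = ±2.9, σ_θ = 1.9, β = 2.6, δ = 0.05, WT volatility
0.42 with trait spread 0.5, KO volatility 6.5 with spread 0.2,
p_lock = 0.30, lock magnitude 5.5; strengths in arbitrary logit units)
were chosen so that one simulated study expresses, with realistic
margins, the four qualitative phase-I phenotypes the pipeline is built
to detect:

1. wild-type dominance in mixed cages (≈70% of cross-genotype
   contests; χ² p < 0.05);
2. higher knockout rank variance in single-line cages (t p < 0.05);
3. wild-type stability as a persistent trait — positive split-half
   stability correlation;
4. bimodal knockout stability in mixed cages (≥2 hyper-stable and ≥2
   hyper-unstable animals).

Effect sizes are a modelling choice, not estimates: no raw data exist
to fit them to, and only their direction and robustness matter for
testing the pipeline.  Two power facts shape the recovery criteria.
First, a half-trajectory has only four transitions, so a rat's
half-stability is a Binomial(4, p)/4 estimate of its retention
probability p; that noise floor caps the attainable split-half
correlation, and at n = 12 single-line wild-types even an ideal trait
distribution reaches p < 0.05 in only ~80% of replicate studies.  The
recovery indicator for phenotype 3 is therefore directional (r > 0)
and computed over all 26 wild-types, pooling housings — the trait
claim holds in both — while the per-housing correlations are still
reported separately in the analysis tables.  Second, rank retention
for a churning pair cannot fall below ~½ per transition (ranks re-draw
each session; there is no anti-persistence mechanism), so
hyper-instability (≤25%, i.e. ≥3 changes in 4) is a per-animal tail
event; joint recovery of all four phenotypes runs at roughly 9 in 10
replicate studies rather than near-certainty, dominated by the
bimodality count at n = 14 mixed-cage knockouts.

### The null scenario

`null_scenario()` removes the genotype effects *and* every source of
persistent or evolving individual difference (strength spread,
updating, volatility, lock-in), making every contest an independent
fair coin.  This is the regime in which the genotype χ²'s independence
assumption holds exactly, and its type-I error is nominal (≈4.9% after
discreteness).  The distinction matters: even a genotype-exchangeable
population with persistent individual strengths overdisperses win
counts across a pair's repeated sessions and would inflate the χ² —
which is a property of applying a count test to repeated measures, not
of the generator.

### What the simulator does not emulate

* Phase-II genotype reversals (knockout dominance between single-line
  cages; the asymmetric cage-type patterns): the generator carries the
  phase-I genotype gap into phase II, so its phase-II genotype
  contrast stays wild-type-directed.  Only the prior-rank (experience)
  effect is a calibration target there.
* The printed total of 1320 phase-II contests: it is not a multiple of
  one tournament's 48 contests and the per-cohort roster is
  under-determined, so the default roster covers each cage-type
  combination once (6 tournaments, 288 contests) as a documented
  approximation.
* Latency content (retained in records, never analysed), and any
  within-session behavioural structure: trials in a block are
  exchangeable given the session's strengths.

Passing tests on simulated data show the pipeline correctly extracts
the structure this generative model encodes; they cannot show that
real tube-test data satisfy the model's assumptions (logistic contest
function, Gaussian form, session-level updating).

## Numerical and degenerate-input choices

* Logistic evaluated in the overflow-safe branch form.
* Zero pooled variance in the *t*: equal means give t = 0 (p = 1);
  unequal means raise rather than return an infinite statistic.
* Constant inputs to the correlation raise; the pipeline records such
  correlations as absent rather than failing the run.
* Missing sessions in a trajectory are explicit gaps, never
  interpolated; variability metrics refuse gapped trajectories, and
  the pipeline computes profiles only for complete ones.
* Validation is a report, not an exception: every design violation is
  collected with a machine-readable code and, for file input, a
  1-based line number.

## Problem sizes

The test suite simulates full 56-rat studies (a study takes ~0.1 s
including analysis); calibration properties use 100–1000 replicate
studies, and the ranking oracle check samples 10,000 cage-sessions.
These sizes give Monte-Carlo standard errors comfortably below the
margins being asserted.
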