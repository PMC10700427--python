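# Methods

## Observer model

Every component of the package assumes the same psychometric model: the
probability of a "yes" response (test judged larger / more clockwise /
first) to stimulus value *x* is

    P_yes(x) = lapse + (1 − 2·lapse) · Φ((x − m) / sd)

a cumulative Gaussian with mean `m` (stimulus units; the 50% point and
hence the PSE for this symmetric model), standard deviation `sd` (stimulus
units; sensitivity), and a stimulus-independent lapse rate
`lapse ∈ [0, 0.5)` that compresses both asymptotes. Quantiles invert the
model in closed form, `x_p = m + sd·Φ⁻¹((p − lapse)/(1 − 2·lapse))`, and
the JND is defined on observed response probability — `(x.75 − x.25)/2`
with the lapse included — not as the lapse-free shortcut `0.6745·sd`. The
two coincide only at `lapse = 0`; with lapses the JND is slightly wider.

Simulated observers are Bernoulli samplers of this curve. They are
stationary by default; an optional per-block multiplicative drift on `sd`
(e.g. factors 1, 0.8, 0.6 across the session's three procedure blocks)
emulates the fast sensitivity gains that appear when discrimination is
hard (peripheral stimuli, temporal judgments). What the simulator does
*not* model: fatigue and attention fluctuations, serial response
dependencies, fixation breaks, apparent-motion confounds in the
temporal-order task, and the "aberrant responder" behavior that leads to
participant exclusions in human cohorts. Passing tests therefore establish
that the procedures and analytics behave correctly for model-faithful
observers — not that human data will be as well behaved.

## Experiment configurations

Three built-in configurations mirror the designs being compared, one per
stimulus dimension:

| | size (exp 1) | orientation (exp 2) | temporal order (exp 3) |
|---|---|---|---|
| stimulus | disk diameter, dva | tilt difference, deg | SOA, frames (4.2 ms) |
| domain | 1.2:0.01:2.0 | −24:2:24 | −60:1:60 |
| reference | 1.6 | 0 | 0 |
| grid m | = domain | = domain | −40:1:40 |
| grid sd | 0.02:0.01:0.3 | 1:0.1:20 | 1:1:50 |
| grid lapse | 0:0.01:0.06 | 0:0.01:0.08 | 0:0.01:0.08 |
| CS design | 1.3:0.1:1.9 ×24 + {1.2, 2.0} ×8 = 184 | −9:3:9 ×24 + ±15 ×8 = 184 | ±{3..18 by 3} ×12 + 0 ×12 + ±{24,30} ×6 = 180 |
| staircase starts | 1.2, 1.6, 2.0 | −28, 0, 28 | −40, 0, 40 |
| staircase steps | 0.2 → 0.1 after 2 reversals | 4 → 2 after 2 reversals | 4 → 3 → 2 after reversals 2, 3 |
| staircase bounds | [1.2, 2.0] | ±24 | ±40 |

Design notes the configurations had to settle:

* The temporal-order CS design reaches exactly 180 trials by splitting the
  extreme SOAs evenly across signs (0 ×12, ±24 ×6 each, ±30 ×6 each),
  keeping the which-stimulus-leads balance of the core ±{3..18} set.
* The orientation staircase starts (±28°) lie outside its ±24° bounds;
  they are presented as given, and clamping applies from the first step.
* The orientation/size staircase step before any reversal equals the
  first-listed step of the schedule; the temporal-order track likewise
  starts at 4 frames.
* Staircase bounds for the size and temporal-order tasks are the stated
  stimulus range and the start-value extremes respectively; boundary-hit
  termination (10 pooled hits at either bound) needs explicit bounds.

## Procedures

**Bayesian adaptive engine.** Posterior over the Cartesian `(m, sd, lapse)`
grid, uniform initial mass (no informative prior). After each binary
response the posterior is multiplied by the per-cell likelihood and
renormalized (mass conserved to 1e-10 per update, asserted in tests). The
next stimulus minimizes the expected Shannon entropy (natural log,
`0·log 0 = 0`) of the posterior over the two outcomes; ties break to the
smallest stimulus value for determinism. Runs stop after 64 trials. The
per-cell yes-probabilities for every stimulus, together with `p·log p` and
`(1−p)·log(1−p)`, are precomputed once per grid so that the expected
entropy over all candidate stimuli reduces to four matrix–vector products
per trial; the largest grid (36 450 cells × 121 stimuli) runs a 64-trial
session in about a second. A run whose MAP `sd` reaches the top grid value,
or whose marginal posterior-mean `sd` comes within 5% of it, is flagged as
a ceiling run and excluded from cohort analyses — the simulated analogue of
excluding participants whose adaptive estimate pinned the grid ceiling.
Estimates used in the comparison analyses come from maximum-likelihood
fits to the 64 trials, like the other procedures; posterior summaries feed
only the ceiling flag and diagnostics.

**Constant stimuli.** The fixed multiset of (value, repetition) pairs is
shuffled uniformly with a dedicated seed and administered in one block.

**Staircase.** Three simple up-down tracks ("yes" moves the value one step
down, targeting the 50% point) start below, at, and above the presumed
threshold and are interleaved uniformly at random (own RNG stream). A
reversal is a response-category change within a track and is recorded at
the presented value. Tracks stop at 15 reversals or 10 boundary hits
(pooled across the two bounds); the whole procedure caps at 150 trials.
The conventional threshold is the mean over tracks of the mean of each
track's last five reversal values; tracks that terminate with fewer than
five reversals contribute all their reversals, with a warning. Trials can
also be binned into nine equal-count (rank-based quantile) bins for
CS-comparable summaries and plots; fits always consume raw trials.

## Fitting

Maximum likelihood under the shared model, with predicted probabilities
clipped to `[1e-9, 1 − 1e-9]` so that `lapse = 0` fits stay finite. The
optimizer is a bounded Nelder–Mead simplex (parameter and function
tolerance 1e-6) started from five deterministic points spread over the
bound box; best likelihood wins, ties to the smallest |sd| — multi-start
removes start-point luck while keeping the derivative-free character
appropriate for this noisy, kinked objective. Trials are aggregated into
per-value binomial counts inside the objective (identical likelihood,
much cheaper when stimuli repeat). Bounds default to the experiment's
adaptive-grid box, which keeps CS and staircase fits commensurate with the
adaptive grid; `lapse` is a free parameter within its grid range. By
default `sd` is constrained positive; an `allow_negative_slope` mode
widens the box to negative slopes so reverse-ordered data yield negative
`sd` (and negative JND) instead of a boundary fit. All-identical response
sets are flagged degenerate (`converged=False`) rather than raising.

## Comparison analytics

* **Outlier screen.** Rousseeuw–Croux Sn (consistency constant 1.1926,
  finite-sample factors; the canonical double-median definition with the
  high median taken over all j including the self-difference) with a
  criterion of 3 on `|value − median|/Sn`, applied per measure (PSE and
  JND separately) and unioned. Single pass, no re-screening. Note the
  estimator's ~50% breakdown point does not make it insensitive to heavy
  contamination: at 40% contamination rank inflation can grow Sn severalfold
  (it stays bounded, unlike the SD); the screen is intended for the
  occasional gross outlier, not heavy contamination.
* **Correlations.** Pearson when both margins pass Shapiro–Wilk at
  α = .05, Spearman otherwise; two-sided p-values.
* **Bland–Altman.** Bias = mean difference, limits of agreement at
  ±1.96·SD of differences, 95% CIs by the classical t approximations
  (bias ± t·SD/√n; each limit ± t·SD·√(3/n)), plus the slope of
  differences on pair means as a proportional-bias check.
* **JND transform.** Natural log; JND distributions are right-skewed and a
  Box–Cox profile on simulated JND samples supports λ ≈ 0. Non-positive
  JNDs (possible under negative-slope fits) shift the sample by
  |min| + 5% of the range before the log, with a warning — the shift is an
  explicit, logged policy because no transform of negative JNDs is neutral.
* **Learning.** One-way repeated-measures ANOVA (classical
  subjects/blocks/error partition) on per-block estimates, with t-based
  per-block CIs and uncorrected pairwise paired-t differences. This is a
  deliberate desk-scale substitute for linear mixed models with
  Satterthwaite df, Bayesian ANOVAs, and Tukey-adjusted post hocs: with
  complete, balanced within-subject data the RM-ANOVA F is the exact
  fixed-effect test the LMM approximates, and the package documents rather
  than hides the substitution.
* **Bias tests.** Classical one-sample t against the reference value.

## Cohorts and problem sizes

Default cohorts draw `m` uniformly over the central 60% of the grid's mean
domain, `sd` log-uniformly over the central half of the sd domain in log
space, and `lapse` uniformly over its grid range — strictly inside the
domain, avoiding the boundary pathologies that human studies handle by
exclusion. Procedure order cycles the six permutations
(counterbalancing); block = position of the procedure in the session.
Every observer owns a response RNG stream derived from the master seed and
observer index; procedure-level randomness (interleaving, shuffling) uses
separate derived streams, so each component is reproducible in isolation.

Validation suites use: 100 seeded observers for adaptive-procedure
recovery (64 trials each); 50 seeds per sample size for ML-consistency;
20-observer cohorts for the staircase agreement benchmark; and 50
replications of 21-observer, three-block cohorts for the learning-effect
calibration (the per-block estimator there is a single constant-stimuli
run per block, the cheapest unbiased JND estimate). These sizes are the
package's own desk-scale choices; the statistical thresholds they are
checked against (90% detection/specificity, coverage in [0.92, 0.98]) do
not depend on them.

## Numerical choices

* Probability clipping at 1e-9 inside likelihoods (finite `lapse=0` fits).
* Entropy with natural log and `0·log 0 = 0`; expected-entropy terms with
  zero outcome probability contribute zero.
* Posterior updates raise a diagnostic error if the likelihood annihilates
  the posterior (possible only with a zero-lapse grid and contradictory
  extreme responses).
* Argmin ties in stimulus selection and likelihood ties in multi-start
  fitting are broken deterministically (smallest stimulus; smallest |sd|).
* CSV round trips use `float_precision="round_trip"` so analyses
  recomputed from saved logs are bit-identical to the original run;
  reports carry a SHA-256 hash of the canonicalized configuration.

## Known limitations

* The simulator cannot reproduce human exclusion rates or aberrant
  behavior; ceiling-flag rates for well-behaved observers are near zero.
* JND agreement between procedures is intrinsically noisy at n = 20; the
  weak CS–staircase JND correlations the package reports are a property of
  the designs, not a bug, but their exact values vary across seeds.
* The temporal-order task treats 0-frame SOA responses as raw data; no
  scoring convention is imposed at simultaneity.
* Box–Cox support for the log transform is demonstrated on simulated
  samples, not asserted for arbitrary real data.
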