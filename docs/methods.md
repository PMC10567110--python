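# Methods

## The task and the staircase

The simulated task is a two-alternative dot-discrimination: two patches are
shown briefly, the participant chooses which contains more dots and rates
confidence from 1 ("guessing") to 6 ("certain"). Difficulty is the **dot
difference** between the patches, controlled in log space by a two-down
one-up (2D1U) staircase: after every incorrect response the log difference
increases by the scheduled step (easier); after two consecutive correct
responses it decreases (harder); a single correct response leaves it
unchanged. The correct-response counter is reset after every step in either
direction — the standard Levitt convention. Steps are ±0.4 log units on
trials 1–5, ±0.2 on trials 6–10, ±0.1 thereafter, indexed by session trial
number; the session is 210 trials in five equal blocks with one continuous
staircase (no block resets). The difficulty is clamped in log space to
[ln 6, ln 81] after each update and converted to integer dots by
round-half-up, so displayed differences stay in 6–81 dots. The start value
is a log difference of 4.2, i.e. round(e^4.2) = 67 dots.

The 2D1U rule converges to the difficulty at which P(correct) = √0.5 ≈
0.707. Because convergence happens on a discrete 0.1 lattice with a
reflecting ceiling, the exact stationary accuracy differs from 0.707 by a
few tenths of a percent; the test suite computes it exactly as the
stationary distribution of the induced Markov chain over
(lattice point, counter) states and checks long simulated sessions against
it. Finite 210-trial sessions that start from the easy end average slightly
above the asymptote (~0.71), which is also what the real cohort shows.

## The observer model

Observers are stationary signal-detection agents. On a trial with log
difference d and the larger patch on side s = ±1, the internal evidence is
e ~ N(s·d, σ); the choice is sign(e), hence P(correct) = Φ(d/σ), strictly
increasing in d/σ. The staircase therefore equilibrates at
d* = σ·Φ⁻¹(√0.5) ≈ 0.545·σ, which is how observers are calibrated:
`calibrated_sigma(target_log_diff)` inverts this relation.

Confidence is a type-2 criterion mechanism on the normalised absolute
evidence u = |e|/σ: the rating is 1 plus the number of criteria exceeded,
with five ordered criteria, independent Gaussian jitter per criterion per
trial (SD 0.5), and a per-person **confidence bias** that shifts all
criteria (lax shift → higher ratings). The default criteria are the
(.10, .28, .46, .64, .82) quantiles of |N(0.545, 1)| — the distribution of
u at the staircase operating point — so an unbiased observer uses the whole
scale with mean rating ≈ 3.7. Near zero bias the mean rating moves ≈ 2.08
points per criterion unit; couplings are specified in rating points and
converted internally with this constant. Response times are log-normal
(median 0.9 s, log-SD 0.4); they enter the analyses only as session means.

## The synthetic cohort

The generator emulates the three-arm, two-timepoint design with completer
arm sizes 649 (iCBT), 82 (antidepressant), 88 (control). Per participant:

- **Latent symptoms.** (AD, CIT, SW) at baseline ~ MVN(0, R) with
  correlations (AD–CIT .4, AD–SW .5, CIT–SW .3). Follow-up change ~
  MVN(arm effect, (0.8)²R). Arm mean changes for AD are −0.32 (iCBT),
  −0.61 (antidepressant), 0 (control) in latent-SD units, matching the
  standardized change magnitudes the design targets; CIT and SW improve by
  −0.20/−0.25 in the clinical arms only.
- **Confidence coupling.** Baseline bias (rating points) =
  −0.10·AD + 0.12·CIT + N(0, 0.80); change in bias = arm time effect
  (+0.17 iCBT, +0.30 antidepressant, 0 control) − 0.10·ΔAD + N(0, 0.55).
  Controls are given a zero time effect: the design treats "no
  intervention" as "no expected change", the hypothesis the study could not
  reject. These defaults put the recovered standardized betas near
  −0.12 (AD) and +0.11 (CIT), the time effect near +0.2, and the
  ΔAD–Δconfidence correlation inside the n=649 sampling band of −0.12.
- **Perception.** σ = 6.7 with person-level log-normal spread 0.08
  (equilibrium ≈ 38 dots; cohort mean dot difference ≈ 42–45 with SD ≈ 12
  and accuracy SD ≈ 0.02 across sessions). At follow-up σ shrinks by the
  practice factor 0.95 in every arm, reproducing the "task gets harder to
  hold accuracy fixed" signature without any clinical coupling. An optional
  `nonconverger_rate` inflates σ for a random subset of sessions to
  exercise the accuracy-exclusion rule; it defaults to 0 because the
  configured arm sizes are completer counts.
- **Questionnaires.** 209 items over nine instruments with their real item
  counts (depression 20, trait anxiety 20, schizotypy 43, impulsivity 30,
  OCD 18, social anxiety 24, eating 26, apathy 18, alcohol 10) and generic
  ordinal ranges. Responses invert the weighted-sum scoring rule: item =
  midpoint + span·(0.6·wᵢ·θ + N(0, 0.35)), rounded and clipped. With the
  synthetic weights (simple structure, dominant loadings U(0.3, 0.8), small
  cross-loadings) this yields latent-recovery correlations ≈ 0.95–0.98,
  comparable to the reliability of real instrument batteries. WSAS items
  are generated around a severity level tied to AD in the clinical arms
  (totals mostly ≥ 10) and a low level in controls. Two catch items carry
  mandated responses; with probability `catch_fail_rate` (default 0.083) a
  participant-timepoint is careless and misses one check (both in ~1/6 of
  careless cases). Catch failures are counted, never excluded.
- **Demographics and engagement** follow the iCBT arm's published
  marginals (gender .77/.22/.01, age N(32.2, 11²) clipped to 18–80,
  country, education, iCBT program-type mix, engagement minutes and percent
  viewed); they are generated identically across arms and carry no
  generative effect on any outcome, so arm comparisons and engagement
  interactions are true nulls.

Reproducibility: each participant draws from an independent substream
keyed by (seed, arm, index), so resizing one arm leaves every other
participant's data bit-identical; a persisted config + seed reproduces all
output files byte-for-byte.

**What the generator does not emulate.** Item-level response styles and
acquiescence, instrument-specific factor structure beyond simple loading
structure, treatment dropout and missingness (the cohort is all
completers), floor/ceiling effects in symptomatic ranges, RT dynamics, or
any causal path between symptoms and perception (σ is independent of the
latent state). Passing tests therefore demonstrate that the pipeline
recovers effects of the assumed linear-Gaussian form at the study's n, not
that the real data meet those assumptions.

## Task metrics and exclusions

Metacognitive bias = mean confidence across a session's trials; task
difficulty = mean dot difference (lower = harder); accuracy and RT are
simple means; side bias = the larger of the two choice proportions.
Exclusions use strict inequalities exactly as phrased — accuracy < 0.60 or
> 0.85, side proportion > 0.95 — so the boundary values are retained; a
`closed_bounds` flag gives the closed-interval variant. Split-half
reliability correlates mean confidence on odd- vs even-indexed trials
(1-based) across sessions, on raw ratings. Completers have a non-excluded
session and complete dimension scores at both timepoints.

## Scoring

Dimension scores are Σ item × weight over the 209 items; weights come from
a delimited file (the published factor-analysis weights are an input, never
embedded; `generate_item_weights` provides a clearly-labelled synthetic
stand-in). Centring subtracts the baseline-sample mean per dimension from
both timepoints, so change scores are centring-invariant. A flag supports
scoring z-scored items instead of raw (default raw). WSAS is the sum of
five 0–8 items; per-scale totals are plain sums over a scoring key
(default: each instrument's own items).

## Statistical pipeline

All p-values are two-tailed. Continuous regressors and outcomes are
z-scored so coefficients are standardized betas; dummy-coded categoricals
(education reference: above-undergraduate; gender reference: female; the
small "Other" gender level is kept as its own dummy) stay on the 0/1 scale
for interpretability, with a strict mode that z-scores them too. No
multiplicity adjustment is applied except Tukey for the age post-hoc.

- *Cross-sectional*: OLS of baseline confidence on AD+CIT+SW jointly
  (age, gender, education as covariates); a per-dimension mode is available
  by passing single predictors.
- *Change*: random-intercept mixed models (ML, Wald p) of the z-scored
  outcome on time (0/1). For two timepoints the time effect equals the
  paired-difference estimate — asserted against that closed form.
- *Time × covariate*: the covariate is one value per person (change score,
  baseline score, engagement, or category); the model includes main
  effects and the interaction, and rejects covariates that vary within
  person.
- *Group × time ANOVA*: Wald block tests (sum-to-zero group contrasts) on
  a random-intercept mixed model. Each F is reported with the
  observation-level denominator df (total observations − fixed parameters:
  1632 for the group×time model on 819×2 observations, 1626 with a
  change-score covariate). A plain OLS ANOVA on the long data was rejected
  during design because, with the high intraclass correlation this design
  produces, its within-person F tests are far from nominal size (null
  rejection ≈ 0–1%); the mixed-model Wald version is calibrated (≈ 5–7%
  measured over null replicates) while preserving the conventional df
  display.
- *Contingency and summary tests*: Pearson χ² without continuity
  correction; the Freeman–Halton exact test enumerates every table with
  the observed margins and sums probabilities ≤ that of the observed table
  (tolerance 1e-12), with a guard on the table-space size and a
  permutation Monte-Carlo mode for large tables; Welch's t,
  one-way ANOVA and Tukey-Kramer are computed directly from (mean, SD, n)
  summaries so published tables can be re-tested without raw data.
- *Power*: smallest n for a two-tailed test of r ≠ 0 via the Fisher-z
  normal approximation, solved in closed form then refined locally.

## Numerical choices and degenerate inputs

Round-half-up for dots (avoids banker's-rounding asymmetry at .5);
z-scoring uses ddof=1 and refuses zero-variance input; a flat ANOVA outcome
returns F=0, p=1 rather than failing in standardisation; rank-deficient
regression designs raise an error naming the most collinear pair;
enumeration p-values are capped at 1; Monte-Carlo exact tests use the
(hits+1)/(reps+1) estimator; mixed models drop participants with a single
timepoint with a warning (completer design).

## Problem sizes used by the test suite

Null type-I calibration runs 500 replicate cohorts of 40 participants per
arm with 15-trial sessions — large enough for every test statistic to be in
its asymptotic regime while keeping the suite fast; the binomial acceptance
band around 5% at 500 replicates is [0.018, 0.082] (±3.3 SE). Coupling
recovery runs one full-size default cohort (819 participants × 2 × 210
trials). Staircase convergence uses thirty 2000-trial sessions against the
exact Markov stationary distribution. The acceptance script simulates
500 + 649 full sessions (~6 s).

## Known limitations

The observation-level denominator df shown for ANOVA effects is a reporting
convention, not the effective df of the Wald statistic; at these sample
sizes the distinction is numerically irrelevant (df > 1600) but it would
matter for small cohorts. Mixed-model p-values are Wald/normal
approximations without small-sample df corrections. The Freeman–Halton
enumerator is exponential in table size by nature; use the Monte-Carlo mode
beyond a few hundred per margin. Synthetic item scales are generic, so
absolute questionnaire scores are not comparable to the real instruments —
only weighted and summed scores, which is all the analyses use.
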