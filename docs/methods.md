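# Methods

## Psychometric model and task

A responder with Weber fraction w > 0 compares numerosities n₁ < n₂ with
success probability

    p(n₁, n₂; w, λ) = (1 − λ)·Φ((n₂ − n₁) / (w·√(n₁² + n₂²))) + λ/2,

the linear-Weber ("scalar variability") form standard in the ANS literature.
The lapse rate λ defaults to 0 and is never fitted; it exists so simulations
can model inattention. The scaled difference depends only on the ratio
n₁/n₂; the implementation reduces (n₁, n₂) by their gcd before evaluating so
that same-ratio stimulus pairs give bit-identical probabilities, making the
scale-invariance property exact rather than approximate in floating point.

The comparison task uses 14 numerosity pairs (two per ratio 1:2, 2:3, 3:4,
4:5, 5:6, 6:7, 7:8) with per-ratio display durations 900–3000 ms. The
schedule is an increasing staircase: a 4-trial practice block at 1:2
(unscored), unconditional 8-trial blocks at 1:2, 2:3, 3:4, then one block
per finer ratio while no block has fallen below 6/8 correct; the first
failed conditional block is included and ends the run. Two thresholds
coexist by design: the *stop* rule is < 6/8 within a block, while the
*above-chance* label for a block uses the χ²(1) test against 50%
(statistic ≥ 3.841, which for 8 trials is exactly ≥ 7/8 correct, statistic
4.5). The "highest ratio discriminated above chance" uses the 7/8 criterion,
anchored by the explicit χ² value; overall accuracy is computed over trials
received, practice excluded. "Below chance" (an exclusion criterion) is
strict < 50% over the 24 unconditional trials; exactly 12/24 is retained —
the minimal reading of "below".

## Stimulus geometry

The two arrays of a pair share a virtual bounding rectangle (interpreted as
the "external perimeter" control: same rectangle ⇒ same perimeter), equate
total item area at constant item height, and share their minimum and maximum
item lengths so the more numerous array is not simply the one with smaller
items. Item lengths live in a configurable range [L_min, L_max] (default
0.5–2.5 height units). Feasibility requires a common total length for both
numerosities: (n₂−2)·L_min ≤ (n₁−2)·L_max; the target total is the midpoint
of the feasible intersection. The two extreme items take L_min and L_max
exactly; the n−2 interior lengths are drawn uniformly and contracted
affinely toward L_min (when the draw overshoots) or L_max (when it
undershoots), which lands every length inside the bounds and hits the target
total exactly — no retry loop is needed for length assignment. A collapsed
length range (L_min = L_max) is correctly infeasible: n₁·L ≠ n₂·L. Spatial
placement is rejection sampling of non-overlapping positions inside the
bounding box with a restart cap. Because total length is equal while counts
differ, the mean item length in the more numerous array is strictly smaller
by construction. Units are abstract; the area tolerance defaults to 10⁻⁶ of
total area (equality is exact up to float rounding).

## Weber-fraction estimation

w is estimated per child by unweighted non-linear least squares on the
proportion correct at each available ratio (all blocks the child received,
including the failed final one; same-ratio blocks pooled, licensed by exact
scale invariance). No binomial weighting is applied — fidelity to the
classical procedure over statistical efficiency. Minimization is a coarse
grid w ∈ {0.05, 0.10, …, 2.00} followed by bounded scalar refinement
(tolerance 10⁻⁷) in the bracketing interval, search bounded to
(10⁻³, 5]; the estimate is never worse than the best grid point, and when
the residual surface is flat at ceiling performance (all blocks perfect) the
estimate snaps to the lower bound. Estimates with w > 1 remain in the table
but carry an exclusion flag honored by w-based correlation analyses.
Recovery behaviour (quantified by the test suite and acceptance script):
with the study's 8-trial blocks the median estimate at true w = 0.42 is
biased by roughly 1%, shrinking below 0.5% at 100 trials per ratio.

## Symbolic measures

Give-a-number: requests 1–5 (younger children, 15 trials) plus 7 (older
children, 18 trials), three trials per request. The knower level applies the
2-of-3 criterion cumulatively: a child is an N-knower for the largest tested
N such that every tested m ≤ N was passed on ≥ 2 of 3 trials; failing at 1
is a pre-knower; passing the full tested range is the cardinal-principle
level (seven-knower when 7 was tested, five-knower otherwise — the
seven-knower level exists only for the older design). The 2-of-3 rule is the
package's operationalization of the conventional classification; it makes
knower level monotone in response quality, and a CP classification
mechanically implies a give-a-number score ≥ 2/3 of maximum. The counting
list is scored as the longest correct prefix 1, 2, 3, … capped at 60. The
symbolic battery is consumed as one bounded 0–63 aggregate; no subtest
structure is modelled (subtest content is unpublished, and the aggregate is
what the analyses use).

## Correlation machinery and the Williams test

Partial correlations residualize both targets on covariates plus intercept
via least squares (df = n − 2 − k); listwise deletion handles missingness.
The implementation is cross-checked in the tests against the
precision-matrix identity −P₁₂/√(P₁₁P₂₂) (tolerance 10⁻¹⁰) and against an
independent library implementation.

The cross-lagged analysis computes r_SA and r_AS as partial correlations
given the base covariates plus (optionally) each correlation's own
autoregressor, and r_Pred between the two wave-1 predictors under the base
covariates. Williams' t is evaluated at the effective sample size n′ = n − k
(k = partialled covariates including the autoregressor), giving
df = n − 3 − k; p-values are one-sided for r_SA > r_AS by default (a
two-sided flag exists). One approximation is inherited from the original
usage and documented rather than hidden: after each lagged correlation is
residualized against its *own* autoregressor, the two correlations no longer
share a literal third variable, which Williams' test formally assumes.
Simulation during development showed that applying Williams' t to two
no-shared-variable correlations from an exchangeable quadrivariate null with
stabilities 0.6, concurrent correlation 0.5 and equal lagged correlations
0.3 has a true one-sided size near 0.069 rather than 0.05; Steiger's pooled
Pearson–Filon Z, which is built for that setting and is exposed via
`method="steiger"`, is correctly sized there. The test suite therefore
asserts Williams' nominal size in its own setting (shared third variable)
and Steiger's in the no-overlap setting. In the full pipeline with the
package's null generator (below), the Williams-based analysis is itself
correctly sized.

Routine statistics (Pearson r, paired t, contingency chi-square, the normal
CDF, scalar minimization) are delegated to scipy; the Williams and Steiger
statistics, the psychometric model, the staircase, the fitting procedure and
the generative model are implemented here.

## Generative cohort model

Ages are a two-component uniform mixture: younger (36–46 months, probability
16/57) and older (44–57 months), matching the emulated sample's age-group
sizes; standardized age z is computed with the mixture's analytic moments.
Latents (all unit-variance by analytic rescaling):

    S1 = a_S·z + ε,             a_S = 0.45
    A1 = a_A·z + ρ·S1 + ε,      a_A = 0.25, ρ = 0.45
    S2 ∝ λ_S·S1 + β_AS·A1 + σ_S·ε,   λ_S = 0.70, σ_S = 0.55
    A2 ∝ λ_A·A1 + β_SA·S1 + σ_A·ε,   λ_A = 0.55, σ_A = 0.65

with default couplings β_SA = 0.35, β_AS = 0 — the directional structure
the analysis is meant to detect. The true Weber fraction is the lognormal
link w_t = exp(μ_t − σ_t·A_t) with (μ_t, σ_t) solved in closed form so the
population mean/SD equal the published wave summaries (0.42/0.21 at wave 1,
0.26/0.17 at wave 2); this makes rank-correlation(A, w) exactly −1 and the
calibration exact in expectation. Structural coefficients are free choices
tuned once to reproduce the qualitative correlational pattern of the
emulated design (moderate concurrent coupling, symbolic more stable than
acuity, a real age confound so age-partialling is consequential); they are
not fitted to any data.

Observables are produced by running the machinery, not by adding noise to
latents: staircase sessions at each wave give accuracy, below-chance flags
and block counts for Weber fitting; knower levels come from an
ordered-threshold model on the group-centred symbolic latent with cut points
at the normal quantiles of the published level frequencies per age group and
wave (the group-conditional latent is treated as approximately normal — a
deliberate approximation adequate for the qualitative calibration checks);
give-a-number responses are correct with probability 0.9 for requests within
the level and otherwise uniform on 1–10; counting-list and battery scores
are linear in S, rounded and truncated to instrument bounds, with means/SDs
from the published wave summaries. Covariates (non-verbal IQ, verbal and
visuospatial spans, naming) load on age and a shared general factor with
published means/SDs.

Exclusions mirror the emulated protocol: below-chance children are removed
from all analyses; fitted w > 1 flags the child for w-analyses only. Under
the calibrated defaults below-chance performance is (correctly) very rare —
the emulated sample is a *post*-exclusion sample; the qualitative check that
exclusions concentrate among the youngest children uses a deliberately
low-acuity, younger-heavy configuration emulating a pre-selection
recruitment pool.

**The null configuration.** `CohortConfig.null()` zeroes β_SA, β_AS *and*
the concurrent coupling ρ. The last is essential for exact nominal size:
with ρ > 0 and asymmetric measurement reliability (accuracy is estimated
from ≤ 56 Bernoulli trials; the battery is nearly noise-free), partialling
the *observed* autoregressor leaves residual confounding through the latent
wave-1 correlation, biasing the lagged-correlation difference even when both
cross-coupling coefficients are zero — the classic measurement-error
artifact of cross-lagged designs. With all S–A couplings zero, S ⊥ A given
age, age is observed exactly, and the test's one-sided size is nominal
(measured 0.051 over 1,000 replicate cohorts of n = 57).

## Problem sizes and determinism

The replicated experiments use 1,000 cohorts of n = 57 for the type-I check,
500 cohorts of n = 200 for directionality (detection rate 100% at
β_SA = 0.35) and its null counterpart, 10,000 simulated children for Weber
recovery, and 10,000 for calibration — sizes at which Monte-Carlo error is
small relative to every tolerance used. A single seeded generator is
threaded through all stochastic operations; replicate seeds are spawned from
one `SeedSequence`, so every result is reproducible from one integer seed.

## Known limitations

- The generator is linear-Gaussian with a lognormal w link; real cohorts
  show floor/ceiling effects, session/fatigue effects, and non-Gaussian
  skill distributions that are not modelled. Passing recovery tests shows
  the *pipeline* is sound under the stated model, not that the model is true
  of children.
- Reaction times, the counting control task, battery subtests and
  repeated-measures ANOVA summaries are out of scope.
- Williams' t applied to autoregressor-residualized correlations is an
  approximation (see above); Steiger's Z is provided, but the default
  reproduces the conventional usage.
- The knower-level threshold calibration treats the group-conditional
  symbolic latent as normal; level frequencies therefore match the published
  tables approximately, not exactly.
- With 8-trial blocks and a truncating staircase, fitted w is a noisy,
  slightly biased estimate of true w (the fits flag w > 1 in roughly the
  same numbers as the emulated study); accuracy over trials received is the
  more reliable acuity index, and the default cross-lag analyses use it.
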