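# Methods

## The decision problem

Every trial is a binary choice between a *certain reference* — a fixed
$500 gain in the monetary domain, a guaranteed "slight improvement" in the
medical domain — and a *lottery* that pays a higher-ranked outcome with
some probability and the null outcome ($0 / "no effect") otherwise.
Uncertainty comes in two forms:

* **risk** — the winning probability is displayed exactly (25%, 50%, 75%);
* **ambiguity** — part of the probability display is occluded; the
  occluded fraction A is 24%, 50% or 74% and the display midpoint is 50%.

Outcomes in both domains sit on a five-rung ordered ladder, indexed by an
ordinal value 0–4 with the reference at ordinal 1. The medical ladder
(no effect → slight → moderate → major improvement → recovery) has no
cardinal scale, which is the motivation for the ordinal-valuation model
below.

## Task layout

The default task has 98 trials, 49 per domain. Per domain: the complete
crossing of the 6 uncertainty levels with the 3 above-reference outcomes
and both winning colors (36 trials), 6 further value trials (one per
uncertainty level, outcomes cycling through the above-reference rungs,
colors seeded), and 7 reference-equal *catch* trials — lotteries whose
winning payoff merely equals the reference, so choosing them is never
advantageous — one per uncertainty level plus an extra at 50% risk. This
yields a 25/24 risk/ambiguity split (49 is odd, so an exact split is
impossible). The layout is one consistent reconstruction of the published
counts (98 / 49 / 7 / even split); those counts do not pin down a unique
crossing, and with only three above-reference outcomes and two colors no
layout can make all 42 value trials unique in (level, outcome, color) —
six combinations necessarily repeat, distinguishable only by trial id.

Construction is a pure function of a seed; the (level, outcome)
composition is seed-invariant and only color assignments move.

## Valuation and choice model

Subjective value of an option:

    SV = (P − β·A/2) · v^α

with P the winning probability (1 for the certain option), A the
ambiguity level (0 unless ambiguous), and v the outcome value. The
certain option's SV is v_ref^α. Two variants differ only in v:

* **ordinal**: v is the outcome's rank 0–4 (null outcome worth 0);
* **rating**: v is the participant's own 0–10 pleasantness rating of that
  outcome, taken raw (no normalisation before exponentiation).

Parameters, per participant × domain × phase:

| param | domain | default grid | meaning |
|---|---|---|---|
| α | (0, ∞) | starts 0.01–3.51, step 0.5 | utility curvature; α < 1 is risk averse |
| β | (−∞, ∞) | starts −2…2, step 0.5 | ambiguity attitude; β > 0 averse. Reported attitude is −β |
| γ | (0, ∞) | start magnitudes 0.01, 0.51 | softmax inverse temperature (choice noise) |

Choice follows a logistic rule, P(lottery) = 1/(1 + exp(−γ·(SV_L −
SV_C))). γ is taken positive: with the opposite sign the model would
predict less lottery choice as the lottery improves, contradicting every
monotonicity the task is built on. β = 0 makes the ambiguity weight
P − β·A/2 exactly 0.5 at every ambiguity level — the neutrality anchor
that also underlies the model-free correction below.

Numerical choices: likelihood probabilities are clipped to
[1e−9, 1 − 1e−9]; 0^α is defined as 0; the effective weight P − β·A/2 is
deliberately not clamped to [0, 1], keeping the objective smooth during
optimisation. Prediction at degenerate boundary fits (α so large that
v^α overflows) resolves the SV comparison on the log scale instead of
erroring.

## Estimation

Per unit, the Bernoulli negative log-likelihood is minimised with
Nelder–Mead (tolerances 1e−6 on parameters and objective, 2,000
evaluations per start) from every point of the start grid above
(8 × 9 × 2 = 144 starts), optimising (log α, β, log γ) so positivity
needs no penalties. The lowest NLL wins; ties break toward the earliest
grid point, making fits deterministic. Estimates with α̂ > 10, |β̂| > 4 or
γ̂ > 100 are flagged as boundary fits but not altered.

The objective is smooth and three-dimensional, so a well-spread 9-start
grid almost always reaches the same optimum as the 144-start default
(verified on sample units to ~1e−7 in NLL). Bulk analyses — recovery
sweeps, cross-validation refits — therefore use reduced grids (9 starts;
4 inside CV folds), which is a deliberate problem-size choice documented
per analysis.

## Model-free attitudes

Per participant × phase × domain, lottery-choice proportions are computed
by outcome level (collapsing uncertainty) and by uncertainty level
(collapsing outcomes). Risk attitude is the unweighted mean over the
three risk levels. Because choices under ambiguity confound risk and
ambiguity attitudes, the ambiguity score is *corrected*: proportion at
each ambiguity level minus the proportion at 50% risk (what an
ambiguity-neutral chooser would do), averaged over levels; negative means
averse. Catch trials are manipulation checks and are excluded from all
proportions — including them would mix attitude with indifference noise.
Empty cells propagate as missing, never as zero (zero is a meaningful
attitude value).

## Exclusion rules

1. duplicate worker id → participant removed entirely;
2. |age(phase 2) − age(phase 1)| > 2 years (strict) → phase-2 data
   removed (the study interval is ~9 months);
3. dominated catch lottery chosen on > 50% of catch trials (strict: 4/7
   fires, 3/7 does not) → that participant × phase × domain removed;
4. never chose the uncertain option → removed from model fitting only
   (no likelihood information), retained for model-free summaries.

Rules are idempotent and order-insensitive in the retained set.

## Model comparison

BIC = 2·NLL + 3·ln(n_trials) (natural log, k = 3), averaged over
participants. Cross-validation randomly partitions each unit's 49 trials
into 5 folds (sizes 9+10+10+10+10, seeded per unit), refits on four folds
and scores the held-out fold by the Brier-style residual
mean((P_V − c)²) against the binary choice c — a thresholded prediction
would discard the fitted γ. A variant is selected only when it wins both
criteria; otherwise the verdict is flagged discordant. Note that a
*noiseless linear* rating map makes the rating model exactly equivalent
to the ordinal one (R = cV implies R^α = c^α·V^α, absorbed by γ), so
rating-vs-ordinal separation requires rating noise or nonlinearity.

## Consistency analyses

Spearman rank correlations (average ranks for ties, two-sided t-based p,
listwise deletion with auditable drop counts) over: cross-domain cells per
phase, cross-phase (test–retest) cells per domain, for the model-free
risk proportion, corrected ambiguity proportion, and the fitted α and β;
plus model-vs-model-free agreement (α̂ vs risky proportion, β̂ vs
corrected proportion — expected negative). Model-based cells use raw β̂;
the fits table also carries −β̂ as the reported attitude, and both are
labelled to avoid sign confusion. Group-level manipulation checks verify
that mean ratings and mean choice proportions are non-decreasing in
outcome level.

## Synthetic cohort

Because each stage needs data with known ground truth, a generator
produces a two-phase cohort:

* marginals: α ~ lognormal(median 0.7, σ 0.5), β ~ normal(0.3, 0.5),
  γ ~ lognormal(median 1.5, σ 0.5) — a generally risk- and
  ambiguity-averse population with realistic choice noise;
* persistence: a Gaussian copula over the four (domain × phase) cells
  with Kronecker latent correlation; target Spearman ρ (defaults: 0.4
  cross-domain, 0.5 cross-phase, in the moderate range the two-phase
  design is meant to resolve) is converted to the latent Pearson scale
  via r = 2·sin(πρ/6), so planted rank correlations are exact in
  expectation regardless of marginals;
* choices: simulated through the ordinal model + softmax, per-unit
  seeded;
* ratings: clip(10·(ordinal/4)^q + N(0, 0.8), 0, 10) with q = 1 by
  default (linear, spanning the 0–10 scale); q < 1 produces the
  concavely distorted ratings used in the model-selection study;
* aberrant roles: catch-failers (always take the catch lottery),
  never-uncertain agents, duplicate worker ids, and implausible age gaps
  — each constructed to fire exactly one exclusion rule.

What the generator does *not* emulate: phase-2 attrition, demographic
structure beyond age, reaction times, and any dominance-awareness beyond
softmax — so typical low-γ agents occasionally trip the catch rule at a
rate comparable to real online cohorts (~15% of units), which is treated
as a feature, not a bug. Passing tests on this cohort show the pipeline
is correct and calibrated under its own generative model; they cannot
certify behavioural conclusions about human data.

## Known limitations and measured ceilings

Parameter recovery at the task's 49 trials/unit is noise-limited. With
the default cohort (γ median 1.5) the truth-vs-estimate Spearman ρ is
≈ 0.62–0.75 for α and ≈ 0.39–0.65 for β across seeds; with a low-noise
cohort (γ median 5) ρ(α) ≈ 0.91, and at 5,000 trials point estimates are
unbiased with mean absolute error < 0.05. The estimator is sound; 49
noisy binary choices simply carry limited rank information. Unbounded
optimisation can run β̂ or γ̂ to extreme values in weakly informative
units; such units are largely the ones the exclusion rules remove, and
remaining extreme fits are boundary-flagged in the output.

## Problem sizes used by the test suite

Neutrality calibration: 500 β = 0 agents. Rank recovery: 200 agents, one
domain/phase, 9-start grid. Large-n recovery: 20 replicate datasets of
5,000 trials at (α, β, γ) = (0.8, 0.6, 3.0). Model selection: 12 cohorts
of 30 agents, one domain/phase, ordinal-generated with rating exponent
0.4. Consistency calibration: 500 agents per planted ρ ∈ {0, 0.3, 0.6}.
The analysis drivers use a 120-agent cohort with all aberrant roles
planted.
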