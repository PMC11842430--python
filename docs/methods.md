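# Methods

## Task model

The Balloon Inflation Test is a 9-armed risky bandit. Option *i* (inflation
10·i %) pays `reward_i` points on success and 0 on a burst, which occurs
with probability `burst_prob_i`. The canonical configuration sets
`reward_i = 10·i` and `burst_prob_i = i/10`, reproducing the expected-value
vector [9, 16, 21, 24, 25, 24, 21, 16, 9] with its optimum at 50%. Sessions
are 60 trials. A burst pays 0 for that trial; no carry-over loss is applied.
The per-option reward SD constants (3.12 … 5.27) attached to the canonical
config are reporting constants only: they are close to, but not derivable
from, the binomial SD `reward·√(p(1−p))` of the adopted mapping, so the
package stores them verbatim and never recomputes them. Burst probabilities
are treated as fixed per option; the "balloon quality" seen by participants
is not modeled beyond the Bernoulli outcome.

Options are indexed 1..9 throughout, matching the value vector V(1)..V(9).

## Learning models

Both learners maintain a 9-vector of value estimates initialized at 0 and
update only the chosen option's value from the signed prediction error
`PE = R − V(c)`.

**Rescorla–Wagner (RW):** `V(c) ← V(c) + α·PE`, learning rate α ∈ (0,1),
inverse temperature τ.

**Lazy-Kalman / Pearce–Hall (KL):** `V(c) ← V(c) + k_t·α_t·PE` with

- Kalman gain `k_t = (S(c) + σ_ζ²) / (S(c) + σ_ζ² + σ_ε²)`, where S is the
  per-option posterior variance, σ_ζ² the innovation (diffusion) variance
  and σ_ε² the observation variance;
- posterior update `S(c) ← (1 − k_t)(S(c) + σ_ζ²)`, while every unchosen
  option diffuses, `S ← S + σ_ζ²` (the standard Kalman-bandit treatment of
  unobserved arms);
- associability `α_{t+1} = η·|PE| + (1 − η)·α_t`, with gain-bias η ∈ (0,1).
  η = 1 recovers the pure Pearce–Hall update; smaller η makes the filter
  "lazy" (slower adaptation). α₁ = 1 (maximal initial surprise), a fixed
  but configurable constant. η enters only the associability recursion, not
  the update of S.

The observation variance is the "initial variance" parameter held constant
over trials; it also initializes S for every option. This reading — one
parameter serving as both prior variance and observation variance — is the
most parsimonious consistent with the gain formula, since no separate update
rule for a time-varying observation variance exists.

Two degenerate-limit identities anchor the implementation and are asserted
in tests: with η→0 and zero innovation the KL update equals the textbook
constant-mean Kalman filter, and with zero observation variance (gain
pinned at 1) and η→0 it equals RW with learning rate α₁.

**Reward normalization.** Rewards are divided by the maximum task reward
(90 points) inside all learning computations, so |PE| ≤ 1 and the
associability stays in [0, 1]. The inverse temperature absorbs the scale
change; reported rewards are in points.

**Choice rule.** The default likelihood is categorical over the elementwise
inverse logit: `P(i) ∝ 1/(1 + e^(−τ·V(i)))`, normalized across the nine
options. τ = 0 yields uniform random choice. This rule is *not* invariant
to adding a constant to all values; a standard softmax
(`P(i) ∝ e^(τ·V(i))`, shift-invariant) is available via `rule="softmax"`.
Note that the inverse-logit rule bounds each option's unnormalized weight
in [0.5, 1) for non-negative values, which caps the probability ratio
between any two options at 2:1 — a structural ceiling on choice
determinism with consequences for identifiability (see Limitations).

## Hierarchical model and priors

Individual parameters use the non-centered parameterization
`θ_ps = link_p(μ_p + ζ_p·ν_ps)` with standard-normal deviates ν. The link
is the standard-normal CDF (probit inverse) for parameters bounded in
(0,1) — learning rate α and gain-bias η — and exp for positive parameters —
τ and the two variances. Priors: μ_α ~ N(−1,1), μ_τ ~ N(0,1),
μ_σζ² ~ N(0,1), μ_σε² ~ N(2,1), μ_η ~ N(1,1); ζ ~ Half-Normal(0,1);
ν ~ N(0,1). A centered variant (`θ_ps = link_p(φ_ps)`, φ_ps ~ N(μ_p, ζ_p))
is provided for cross-checks; both target the same posterior and a test
verifies their agreement on a toy cohort.

### Sampling design

The posterior is explored by an ensemble MCMC sampler (emcee) using an
80/20 mixture of differential-evolution and snooker moves, which handle the
correlated, moderately high-dimensional geometry (2P hyperparameters +
P×S deviates) better than stretch moves. The ensemble is initialized in a
small Gaussian ball (SD 0.05) around the MAP, found by L-BFGS with
central-difference gradients evaluated in a single batched likelihood call
per iteration. The likelihood itself is vectorized across walkers and
subjects simultaneously (one 60-step replay of arrays shaped
walkers × subjects × 9), which is what makes whole-cohort MCMC affordable
on one CPU.

`McmcConfig` defaults: 1000 warmup ensemble steps, 4 pseudo-chains × 1000
retained draws at thinning 5, fixed seed. Walkers number at least 2·ndim+2
and split evenly into pseudo-chains for split-R̂ and bulk-ESS diagnostics
(arviz) on the group-level parameters; a fit is flagged (not failed) when
any R̂ > 1.1 or ESS < 100. Runs are bit-reproducible for a fixed seed.
Unconstrained coordinates are clipped at ±30 before exponentiation to keep
the likelihood finite. Tests and examples use smaller, documented settings
(e.g. 150–500 warmup steps, 200–600 retained draws per chain) — the checks
target machinery and ranking, not publication-grade posteriors.

### Model comparison and recovery

The LOO observation unit is the subject-trial, matching the per-trial
categorical likelihood. Pointwise log-likelihoods for the retained draws
feed Pareto-smoothed importance sampling (generalized-Pareto tail fit via
arviz); the package reports elpd, its SE (√n · sd of the pointwise elpd),
LOOIC = −2·elpd (an exact identity, asserted), and per-observation Pareto-k
values, with a warning when more than 1% exceed 0.7. Model comparison
tables report ΔLOOIC against the best model with the paired SE computed
from pointwise elpd differences. Recovery reports give, per parameter, the
Pearson correlation of true values with posterior means, mean bias, RMSE,
and coverage of central 90% intervals.

## Synthetic cohorts

The generator emulates: 9-option sessions of 60 trials under either
learner; individual parameters from the hierarchy above with group
locations at the prior means (α: −1 → 0.16, τ: 0 → 1, σζ²: 0 → 1,
σε²: 2 → 7.4, η: 1 → 0.84 after transform) and group scales at the
half-normal mean √(2/π) — the prior means are the only principled default
because fitted group-level values for the original participants are not
available; SSS-V totals from N(99.63, 13.23²) truncated to the instrument
range [40, 160] and rounded; and log-normal reaction times (median 1 s,
log-SD 0.4) that exist purely so the metrics stage has an RT column — no
model consumes them. An optional `LinkSpec` imposes linear effects of
standardized SSS on unconstrained-scale parameters and generates a
continuous reward-sensitivity proxy (sign convention: more negative =
stronger feedback response, FRN-like). The link is a testing device for
the moderation pipeline, not a mechanistic claim.

What the generator does **not** emulate: EEG signals, practice trials,
post-task preference questions, non-stationary burst probabilities, or any
strategic/heuristic choice pattern (e.g. staircase-like progressions) that
real participants may show. Passing tests therefore demonstrate that the
pipeline is correct and well-calibrated on data generated by its own model
class — not that the models describe human behavior.

## Behavioral and moderation analyses

Session summaries use the sample SD (n−1); the 50%-choice count is exact.
Trajectories use 5-trial bins (12 bins per session; a partial final bin is
kept and flagged). Tertile grouping labels scores above the 66th percentile
HSS and scores at or below the 33rd percentile LSS (linear-interpolation
percentiles); in the degenerate case where the two percentiles coincide,
everyone is MSS. Because the rule depends only on the score, tied scores
never straddle groups. The Wilcoxon rank-sum test reports the rank sum of
the first sample with midranks; p-values are exact when min(n) ≤ 8 without
ties, else a continuity-corrected normal approximation; identical samples
give p = 1 by convention. The trial-order regression is a linear mixed
model of chosen inflation % on trial and group dummies with a per-subject
random intercept (ML).

The moderation analysis collapses each session into 10 ordered bins of 6
trials (choice "degree" = per-bin mean inflation %; the 10-bin choice-order
grid is deliberately distinct from the 5-trial descriptive bins) and fits

```
choice_degree ~ group + rs + group:rs + (1 | bin)
```

by ML with HSS as the reference level, the RS measure standardized to unit
SD across subjects, and Wald-type 95% CIs with normal critical values —
adequate at 400 rows. The RS measure is pluggable: a fitted or true model
parameter (innovation variance by default) or the external proxy.
Calibration under a null interaction (type-I rate within the binomial band
around 0.05 across 500 replicates) and sign recovery under an injected
interaction are part of the acceptance suite.

## Numerical choices

- Probabilities are computed in log space (`log_expit`, `logsumexp`); no
  choice probability is ever materialized as 0.
- Ties in the EV argmax resolve to the lower-risk option.
- Expected values are rounded at the 12th decimal so binary-fraction noise
  (e.g. 30 × 0.7) cannot break exact comparisons with printed utilities.
- PSIS requires a tail; below 10 draws the implementation falls back to
  plain importance sampling with zero Pareto-k.
- Empty sessions, zero-variance RS measures, rank-deficient designs,
  non-contiguous trial indices and out-of-range options raise named errors.

## Problem sizes in the test suite

Acceptance checks run at: recovery 40 subjects × 60 trials (one fit, seed
606); model selection 10 replicates × 10 subjects, both generating models
(seeds 7000+/7500+); moderation calibration 500 null + 200 alternative
replicates at 40 subjects; LOO accuracy 5 observations × 2000 draws.
Unit-level fits use 5–20 subjects with short chains. These sizes are the
package's own choices balancing statistical resolution against a
single-CPU run of the whole suite.

## Known limitations

- **Individual-level identifiability.** Under the default generative
  condition (group locations at the prior means), 60 trials carry little
  information about individual η and τ: an oracle profile-likelihood
  analysis (all other parameters held at truth) bounds the attainable
  true-vs-estimate correlation near 0.3 for τ and near 0 for η, because
  prior-mean temperatures put choice probabilities close to uniform and the
  inverse-logit rule's 2:1 probability ceiling compresses the likelihood.
  The recovery acceptance check at r ≥ 0.5 documents this gap rather than
  papering over it: it fails under these conditions, and the recovery
  report's coverage columns (≈ 0.9–1.0) show the posterior is honest about
  its uncertainty. Group-level locations, by contrast, are recovered well
  in informative regimes (tight hierarchies, longer sessions), which the
  unit suite asserts.
- The ensemble sampler's draws are correlated; ESS, not draw count, is the
  meaningful resolution measure, and tail quantities (e.g. Pareto-k) are
  noisier than under gradient-based samplers.
- The moderation model treats bins as exchangeable random intercepts; it
  does not model within-subject autocorrelation across bins.
- Reaction times are decorative; no drift-diffusion or RT likelihood is
  implemented.
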