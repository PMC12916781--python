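# Methods

## The task

`dynaprl` simulates and analyses a dynamic probabilistic reversal-learning
(dynaPRL) task: a two-lever bandit whose reward contingencies switch in
blocks. Three block types differ in the *contrast* between the levers'
reward probabilities — high contrast (HC, 0.8 vs 0.1), low contrast (LC,
0.6 vs 0.3) and no contrast (NC, 0.45 vs 0.45). Block lengths are drawn
uniformly on 15–30 trials. Transitions obey three rules:

1. an NC block is never immediately repeated;
2. the side of the higher-probability lever alternates between consecutive
   contrast blocks;
3. in contrast blocks, a scheduled transition is deferred while the
   subject's last four or more choices were all of the low-probability
   lever, so reversals do not land mid-confusion. The deferral is
   indefinite until the streak breaks (configurable off); NC blocks never
   defer since no lever is "incorrect" there.

After the twelfth trial of a contrast block, each rewarded trial
independently receives a reward-magnitude manipulation with probability
0.40 — half of those halve the nominal ~33 µL drop to 16.5 µL and half
double it to 66 µL. The scheduling is a per-trial Bernoulli draw; nothing
finer is imposed. All models treat reward as binary 0/1 regardless of
volume, because stay/shift behavior is insensitive to the volume
manipulation at these scales.

Invalid trials (no lever press) can be injected at a configurable rate
(default 0, matching their <1 % incidence in real data); they are dropped
from every analysis. The recorded `choice` on an invalid trial is a
placeholder draw from the policy.

## Models

Four trial-by-trial models share a two-action softmax policy
p(a) ∝ exp(β·V(a)):

* **standard** — Rescorla–Wagner: RPE_t = R_t − V(c_t),
  V(c_t) ← V(c_t) + α·RPE_t. Parameters (α, β).
* **avg_rpe** — the chosen value is updated by an exponentially averaged
  prediction error avgRPE_t = α·RPE_t + hW·avgRPE_{t−1}, hW ∈ [0, 0.75].
  At hW = 0 this is *exactly* the standard model (asserted to 1e−10).
  |avgRPE| serves downstream as an uncertainty proxy.
* **grs** — a global-reward-state model: a reward trace
  Rtrace_t = Rtrace_{t−1} + (R_{t−1} − Rtrace_{t−1})·α_R enters the
  prediction error as RPE_t = R_t + w_R·Rtrace_t − V(c_t), w_R ∈ [−1, 1].
  The trace is a recency-weighted estimate of environmental richness.
* **asym** — five parameters: separate learning rates for rewarded (α⁺)
  and unrewarded (α⁻) choices, and multiplicative retention of the
  *unchosen* value by γ⁺ after a win or γ⁻ after a loss (1−γ is the decay
  rate). `asym_ch` adds a choice-history (stickiness) weight φ to the
  softmax argument, the standard kernel β·V(a) + φ·1[a = previous choice].

Values start at 0 for both actions at the start of every session, carry
across block boundaries within a session, and never carry across sessions.
The auxiliary traces (avgRPE, Rtrace) start at 0 likewise. Log choice
probabilities are floored at log(1e−12) so extreme β cannot produce −∞.
Although the update equations are written with a scalar V, they are
implemented per action with only the chosen action updated (plus the
asymmetric decay of the unchosen action), consistent with the two-action
softmax.

Boundedness: standard and asymmetric values remain in [0, 1] for binary
reward (convex updates; multiplicative decay). The avgRPE model can
transiently overshoot [0, 1] at extreme (α, hW) because the averaged error
carries momentum, and the GRS model shifts the effective reward target by
w_R·Rtrace; for these two, finiteness rather than unit-interval bounds is
the guaranteed invariant.

## Fitting

Sessions are fit independently by maximum likelihood: bounded L-BFGS-B
from 10 uniform-random starts inside the bounds (nLL tolerance 1e−10);
the best restart is kept, and a fit is flagged unconverged only if every
restart's optimiser failed. β is bounded at 20 for fitting — with values
in [0, 1] the softmax is saturated far below that. nObs is the
valid-trial count; models are compared by BIC = 2·nLL + nParams·ln(nObs),
summed over sessions, with per-session ties broken toward fewer
parameters. Likelihood kernels are numba-compiled; a session of 300
trials evaluates in ~7 µs, which is what makes the recovery harnesses and
MCMC below cheap.

## Hierarchical two-group estimation

The asymmetric model's group comparison is hierarchical. Each rat r in
group g has an unconstrained parameter vector θ_r with independent
components

  θ_{r,p} ~ Normal(μ_p + s_g·δ_p, σ_p²),  s_g = ±1/2,

so δ_p > 0 means the first group label has the larger parameter.
Links: scaled logit for interval-bounded parameters, log for β.
Hyperpriors: μ_p ~ N(0, 1.5), δ_p ~ N(0, 1), σ_p ~ half-N(1). A rat's
likelihood is the product of its session likelihoods with one parameter
set per rat; sessions can instead be treated as the exchangeable unit
(`unit="session"`).

Sampling is Metropolis-within-Gibbs, written for this model:

* per-rat components: adaptive random-walk Metropolis (target acceptance
  0.44, scales adapted during warmup only), initialised from per-rat MLEs;
* (μ_p, δ_p): exact conjugate bivariate-normal draws given θ and σ;
* σ_p: univariate slice sampling on log σ;
* every second sweep, interweaved non-centered moves (ancillarity–
  sufficiency interweaving) translate μ_p or δ_p — or rescale σ_p —
  jointly with all rat-level values, accepted against the data likelihood.
  This breaks the centered parameterization's funnel, which otherwise
  leaves the hyperparameters mixing an order of magnitude slower.

Default: 2 chains × (500 warmup + 1000 draws). Convergence is flagged
when the split-chain R-hat of every hyperparameter is < 1.05 (computed
via arviz). Group differences are summarised by the directed Bayes factor
dBF = (#δ samples > 0)/(#δ samples < 0), zeros excluded; when one side is
empty the ratio is capped at the total sample count.

A calibration caveat worth stating plainly: with informative data per rat,
the posterior on δ correctly tracks the *realized* difference between the
two finite groups of sampled rats. Under a null population (δ = 0) the
realized group difference is not zero, so extreme dBF values occur at a
non-trivial rate whenever per-rat parameters are well identified. The
moderate-dBF-under-null behavior holds in measurement-noise-dominated
designs (few short sessions per rat), where the N(0, 1) prior on δ
provides genuine shrinkage; the calibration checks therefore use 5 rats
per group × 1 session × 150 trials. With rich data, a significant dBF
should be read as "these two cohorts differ", not "the populations
differ".

## Behavioral battery

Win-stay (WS) is a rewarded choice repeated on the next trial; lose-shift
(LS) a non-rewarded choice followed by the other lever ("loss" means
reward omission). Probabilities are pooled counts per rat: numerators and
denominators summed over sessions before dividing (equal to the
trial-weighted mean of per-session probabilities, asserted as a property).
Strata: phase (early = block trials 1–6, late = 7 onward), block contrast,
and action type (better/worse lever of the current block; undefined in NC
blocks, which are excluded from action-type strata). A stay/shift pair is
attributed to the context of its outcome trial (the first of the pair);
pairs never span sessions. Zero-denominator cells are flagged, not
dropped.

The perseveration curve covers 5 pre- and 12 post-reversal trials per
block transition and scores, at every relative trial, the probability of
choosing the lever that was correct *before* the reversal (an
alternative convention scoring the current block's correct lever is a
flag). In NC blocks a correct lever is designated uniformly at random,
seeded for reproducibility.

## Latent-state analyses

The weighted RPE combines the current and previous trial's standard-model
RPE: wRPE_t = k·RPE_t + (1−k)·RPE_{t−1}, scanned over
k ∈ {0.500, 0.525, …, 1.000} (21 values). For each k and rat, a binomial
logistic regression relates the z-scored wRPE to the WS (stay after win)
or LS (shift after loss) outcome; the best k maximises |β-weight|, ties
to the largest k (at an exact tie the data carry no preference, and the
largest k is the most parsimonious reading — current trial only).
Session-first trials have no predecessor and are dropped.

|avgRPE| and GRS traces are obtained by replaying each session through
its fitted avg_rpe and grs models (deterministic; replay reproduces the
fit's trace bit-for-bit). The GRS value is the reward trace Rtrace_t, not
w_R·Rtrace_t: the monotone transform leaves median splits invariant, and
the untransformed trace keeps the "perceived reward rate" interpretation
independent of the sign of w_R. Per-rat logistic correlations of WS/LS
with either z-scored predictor run on configurable subsets (typically
better-action, late-phase trials of a given contrast); z-scoring is per
rat over the analysis subset (per-session optional). Separation or
non-convergence falls back to an L2-penalized fit, flagged.

The median-split interaction computes, per rat × contrast, WS
probability in the 2×2 cells formed by splitting GRS and |avgRPE| at
their medians over the subset's win trials (ties to the low side, making
the split deterministic); counts are always reported because late-phase
loss cells are often sparse.

Per-rat correlation analyses pool sessions within rat by default (the
exchangeability question is exposed as an option, mirroring the
hierarchical fit).

## Group statistics

Cohen's d uses (n−1)-weighted pooled SD; partial eta-squared is
SS_effect/(SS_effect+SS_error). `mixed_anova` delegates to statsmodels'
random-intercept `MixedLM` (rat as random effect), reports per-term Wald
F statistics, and computes Tukey-adjusted pairwise contrasts from the
studentized-range distribution on marginal means; it is a contract over a
standard solver, not a bespoke method.

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` draws each rat's parameters once from group-specific
truncated normals (native scale) and holds them fixed across sessions.
The packaged reference distributions (`task.REFERENCE_GROUP_PARAMS`) were
calibrated once, before being frozen into tests, to reproduce the task's
qualitative signatures in simulation: empirical reward rate ordered
HC > LC > NC, reversal adaptation reaching indifference within about six
trials, win-stay far above lose-shift, and higher win sensitivity on the
better lever. Group 1 carries the win-biased asymmetry (higher α⁺/α⁻ and
stronger loss decay 1−γ⁻); group 2 the more loss-protective profile.

Simulated softmax-RL agents are more deterministic after wins than real
animals (pooled WS ≈ 0.95 here vs ≈ 0.75–0.85 in rats), because the model
class has no lapse/attention process; ceiling effects therefore compress
better-vs-worse WS differences relative to real data. The low-contrast
vs no-contrast comparisons of reward rate, GRS and |avgRPE| have small
margins (~0.01) for any agent in this class — an NC block guarantees
0.45 while LC exploitation above 0.45 depends on fast, stable
discrimination of 0.6 vs 0.3 across reversals. Passing latent-ordering
checks on simulation shows the analysis machinery recovers the
directional structure; it does not certify effect sizes in real data.

Generative calibration checks (k-scan recovery, latent-correlation signs,
median-split patterns) synthesize the binary stay/shift outcome from a
known logistic model of the latent trace and verify the analysis recovers
the planted structure; they test the analysis, not the agent.

## Problem sizes and numerical choices

Recovery harnesses use 50 draws × 500 trials (parameters uniform in
bounds, β in [1, 8] since near-zero β makes everything else
unidentifiable); model recovery 40 sessions per generating model with
hW ≥ 0.3 for the avgRPE generator (keeping it away from the nested
standard model). Hierarchical checks use 10 rats/group × 5 sessions ×
300 trials (planted δ(α⁺) = +0.15) and 10 null replicates at 5 rats/group
× 1 session × 150 trials with 2 × (300 warmup + 600 draws). Environment
fidelity uses ≥ 50 000 simulated trials with 3-binomial-SE bands. These
sizes are the package's reference scales; everything accepts larger
values.

Known limitations: single-session identifiability of the five-parameter
asymmetric model is poor over the full parameter cube (γ and β recover
weakly under uniform draws; learning rates recover well) — in practice
the hierarchical fit, which pools a rat's sessions and shrinks across
rats, is the supported route to asymmetric-parameter inference, matching
how the model is used on real data. The mixed-model wrapper reports
Wald-based tests with a simple residual-df approximation rather than
Satterthwaite/Kenward-Roger corrections.
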