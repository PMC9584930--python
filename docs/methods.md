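# Methods

## The task and the model family

`traitlearn` models a social-learning task in which a participant repeatedly
estimates how another person (a *profile*) rated themselves on personality
trait items, receives the true self-rating as feedback, and learns over a run
in which every item appears exactly once in random order.  Ratings live on an
integer Likert scale (1–8 for trait adjectives, 1–5 for IPIP statements).

Five models formalize two social knowledge structures — *reference points*
(RP: the average person of a comparison group, one mean rating per item) and
*granularity* (whether prediction errors generalize per Big-Five factor or
per item, weighted by inter-item correlations):

| model | prediction P for item *i* | learned state V | update after PE = F − P |
|---|---|---|---|
| M1 | `b1·RP(i) + b0` | none | none |
| M2 | `V(F(i))` | one value per factor | `V(F) += α·PE` |
| M3 | `γ·RP(i) + (1−γ)·V(F(i))` | one value per factor | `V(F) += α·PE` |
| M4 | `V(i)` | one value per item | `V(All) += α·PE·SIM[:, i]` |
| M5 | `γ·RP(i) + (1−γ)·V(i)` | one value per item | `V(All) += α·PE·SIM[:, i]` |

`SIM` is the signed item×item Pearson correlation matrix of trait
self-ratings; negative correlations push estimates in the opposite direction.
Variants swap the RP source (population / stereotype / own self-ratings) and
optionally split the learning rate into `α⁻` (PE < 0) and `α⁺` (PE ≥ 0).
State is initialized to the free *starting value* at the beginning of every
run and never shared across profiles; predictions and state are never clipped
to the rating scale (the recursions are linear) — rounding/capping applies
only when an agent emits discretized responses.

### Where the reference-point blend applies

The RP weighting can be read two ways: blended into the stored state at
update time, or applied when the prediction is expressed (state keeps the
pure delta-rule update).  This package implements the **query-time blend**.
The readings only differ for γ > 0, and the choice is empirically decidable:
under the state-blend reading the `(1−γ)` factor compounds across trials, so
the learning rate's imprint on behaviour vanishes for moderate-to-large γ —
a Fisher-information analysis on the 240-trial design puts the single-fit
standard error of α at 0.7–1.8 for γ ≥ 0.5, which caps the
generating-vs-recovered α correlation near 0.4 under U[0,1] draws.  The
query-time reading scales the learning signal by a single `(1−γ)` and yields
α recovery ≈ 0.8–0.88 and γ recovery ≈ 0.96–0.97 — the régime the model
family is known to operate in.  Consequence: with γ = 1 the RP models emit
the reference point from the very first trial.

## Fitting, scoring and comparison

Each model is fitted per participant by minimizing the sum of squared errors
between model predictions and responses over all runs (missing responses are
excluded from the SSE; the model still updates on the shown feedback, which
the participant saw regardless).  The optimizer is Nelder–Mead started from
parameter midpoints (α = γ = 0.5, starting value at the scale midpoint);
bounds (α, γ ∈ [0,1]; start on the scale) are enforced by projecting
parameters inside the objective.  Because projection creates flat regions
that can strand a collapsing simplex, the search restarts from the projected
solution (fresh simplex, default up to 3 restarts) until the objective stops
improving; this is deterministic and removed all observed optimizer stalls.
Convergence tolerances are 1e−6 on parameters and objective, max 2000
evaluations per pass.  M1 is solved exactly by OLS of responses on RP values
(the equivalent minimizer).  Optional multi-start (`n_starts`) exists for
robustness studies and is off by default.

Model evidence is `BIC = n·ln(SSE/n) + k·ln(n)` with `n` the scored trials
and `k` the free-parameter count (M1: 2, M2/M4: 2, M3/M5: 3; +1 with dual
learning rates).  SSE is floored at 1e−12 before the log, reachable only on
noise-free synthetic data.

Fixed-effects comparison sums BIC over participants and reports each model's
distance from the worst sum (log-group Bayes factor).  Random-effects
comparison re-implements variational Bayesian model selection over a
Dirichlet prior (concentration α₀ = 1) on model frequencies: responsibilities
`u_nk ∝ exp(lnE_nk + ψ(α_k) − ψ(Σα))` with `lnE = −BIC/2`, iterated to
`max|Δα| < 1e−6` (≤200 iterations); exceedance probabilities are Monte-Carlo
estimates (default 10⁶ seeded Dirichlet draws of the argmax frequency).
Protected exceedance probabilities are not computed.

## The synthetic experiment generator

The validation analyses need populations of raters with the statistical
structure real trait ratings have.  A rater's rating of item *i* is

    r_i = round(cap(mean_i + sd · [ s_i·(λ_i·f_F(i) + μ_i·g) + √(1−λ_i²−μ_i²)·ε_i ]))

with one standard-normal factor score `f` per Big-Five factor, one
standard-normal evaluative (halo) score `g` per rater, item noise `ε`,
valence sign `s_i` (±1), and rounding half-away-from-zero to the integer
scale.  Defaults, chosen once as field-typical values:

* **Factor loadings** λ_i ~ U[0.4, 0.8] (base 0.6): within-factor |r| ≈ 0.3–0.5.
  IPIP items (exp5) use base 0.7, spread 0.1 — they are purpose-built
  homogeneous factor markers.
* **Evaluative loadings** μ_i ~ U[0.3, 0.6] (base 0.45; 0.3 for IPIP):
  signed cross-factor correlations ≈ ±0.2, the halo structure trait ratings
  universally show.  Loading heterogeneity (congeneric items) is essential:
  with exchangeable items, item-level (fine) generalization is an exact
  scalar multiple of factor-level (coarse) generalization and the two
  granularities are unidentifiable.
* **Item means**: base 6.0 on the 1–8 scale (≈3.86 on 1–5) with per-item
  scatter SD 0.69 scale units (the spread measured reference points show);
  negative-valence items mirror across the scale midpoint (≈3.0) for the
  wide-trait and IPIP designs.  RP scatter is what makes the RP weighting γ
  identifiable — with a constant RP the blend is a reparametrization of the
  starting value.
* **Rating dispersion** sd = 1.5 scale units on 1–8 (scaled with the range),
  typical for 8-point Likert trait ratings.
* **Raters**: 800 for the trait-adjective designs, 5000 for IPIP.

Per preset: exp1/exp4 use 60 items over 5 factors (19/13/10/10/8), half
negative-valence, 4 profiles sampled from the population model; exp2
constructs profiles exactly by the published procedure (factor means 5 or 7
on two 30-item factors, per-item N(0,1) noise, rounded, capped to [1,8]);
exp3 shares exp2's layout with sampled profiles; exp4 adds a surrogate
stereotype RP (shift −0.9, jitter SD 0.3, matching the measured in-/out-group
RP gap); exp5 has 50 items, 5×10, scale 1–5, five sampled profiles each
divergent on a different factor.

What the surrogate does **not** capture: the item-level texture of real
similarity matrices (clusters, hub traits, heavy-tailed loadings), the
geometry of real selected profiles relative to the population mean, response
styles, and any semantic content.  Validation results on the surrogate
therefore bound what the code does under a known generative model — they are
not a re-analysis of the deposited behavioural data (an importer for which
is deliberately out of scope).

## Validation procedures

* **Parameter recovery**: draw α, γ ~ U[0,1] and the starting value uniform
  on the rating scale, simulate agent responses on the design's profiles
  with N(0,1) response noise (the agent's internal PE uses its noise-free
  prediction), refit the same model, and report per-parameter Pearson
  correlations over 200 replicates.  Constant parameter columns are flagged
  rather than correlated.  Stereotype variants are excluded (they simulate
  identically to the population-RP models).
* **Confusion matrix**: draw parameters U[0.2, 0.8] (unit-interval
  parameters; start again uniform on the scale), simulate from each of the
  five models, add standard-normal noise, fit all five, credit the lowest
  BIC (ties, which never occur in practice, go to the earliest model and are
  counted).  Simulated responses stay continuous; a `discretize` flag exists
  for sensitivity analysis.
* **Best-performing model**: fit each model with the profile's own feedback
  sequence as the response (prediction at trial t from history up to t−1),
  ranking strategies by task performance rather than by fit to behaviour.

## Model-free statistics

Runs with >20% missing answers are dropped, participants with >10% missing
overall are dropped entirely (both strict inequalities, both evaluated on
the raw table).  Learning is assessed as the Pearson correlation between
trial number and mean |PE| (averaged over runs within participant, then over
participants).  A per-participant GLM explains trial-wise |PE| with three
regressors — previous-trial count, previous same-factor count, and summed
|correlation| of previous items with the current item — z-scored within
participant (t statistics are invariant to this; betas are not), fitted both
singly and jointly; group inference is a one-sided one-sample t-test of the
slopes against zero in the negative direction, uncorrected.  The three
regressors are strongly positively correlated by construction; the package
reports their correlation matrix alongside.

## Problem sizes and determinism

The packaged validation studies use 100 confusion replicates per generating
model (half the published 200; the diagonal estimates' MC standard error at
p≈0.9 is ≈0.03) and the full 200 recovery replicates.  Every stochastic
procedure takes a seed and is bit-reproducible; internal streams are spawned
from a single `SeedSequence` so sub-analyses are independent but derived.

## Known limitations

* The surrogate's identifiability is genuinely below the published
  validation bounds for the constructed-profile and IPIP designs: the
  residual confusion errors are low-γ draws of the RP models, whose SSE
  advantage over the one-parameter-smaller neighbour sits at the BIC penalty
  under N(0,1) noise.  Diagnostics show the misattributed winner beats even
  the true-parameter BIC, i.e. these races are marginal in the data, not
  artifacts of the optimizer.
* With each item shown once per run, fine-granularity learning about an item
  operates only through its correlated neighbours; designs with item repeats
  would identify α much more sharply.
* The BMS implementation reports plain (not protected) exceedance
  probabilities, and the real-data loader for the deposited dataset is not
  included.
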