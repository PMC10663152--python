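# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the problem sizes the package uses, in the spirit of a model
documentation page.

## Task environment

The task is a spatially correlated multi-armed bandit on an 8×8 grid of 64
tiles. Expected rewards are one draw from a 64-dimensional zero-mean
Gaussian whose covariance is a radial-basis-function (RBF) kernel over tile
coordinates,

    k(x, x') = exp(−‖x − x'‖² / (2λ²)),

with generation length-scale λ = 4 (the "smooth" condition; λ = 1, the
"rough" condition, is supported as a parameter but not analysed). Each
environment is min-max normalized to [0, 1] once, at generation. Per round,
a maximum range is drawn uniformly from [30, 40] and the unit grid is
mapped to `5 + value × max_range`, so effective rewards span 5–45 with the
per-environment minimum exactly 5. Observed rewards add standard-normal
noise. A default set of 40 environments is shared by all simulations, and
each round ends after 25 choices preceded by one uniformly random reveal.

Distances are Euclidean on 0-based integer (col, row) coordinates. The
covariance gets 1e-8 diagonal jitter before Cholesky factorization.

## Choice models

The full model, GP-UCB, composes three parts:

1. **Gaussian-process regression** with the RBF kernel generalizes reward
   observations over the grid. The posterior mean and variance at every
   option are the exact GP conditionals with observation-noise variance
   σ²ε. With no data the prior is mean 0, variance 1.
2. **Upper-confidence-bound valuation**: q(x) = m(x) + β √v(x). β prices
   uncertainty, i.e. directed exploration.
3. **Softmax choice**: p(x) ∝ exp(q(x)/τ). τ is undirected (random)
   exploration; τ → ∞ is the uniform policy.

Three lesions remove one component each: the *generalization lesion*
replaces the GP with a Bayesian mean tracker (independent Kalman-filter
updates per option; Kalman gain G = v/(v + θ²ε), prior mean 0.5 and
variance 5 on the model scale, error variance θ²ε as its free parameter);
the *exploration-bonus lesion* fixes β = 0; the *temperature lesion* swaps
the softmax for ε-greedy (mass ε spread uniformly over 64 options, 1 − ε
on the argmax, ties split equally). Every full model has exactly three
free parameters.

**Reward scale for modelling.** Observed rewards are divided by 50 before
entering any model, mapping the 5–45 range into [0.1, 0.9], so the zero
GP prior is mildly pessimistic. σ²ε is fixed at (1/50)² — the generative
N(0, 1) noise on that scale — rather than fitted; this keeps GP-UCB at
three free parameters. Both constants are configurable in `ModelConfig`.

**Numerics.** The sequential GP maintains an incrementally updated
Cholesky factorization (each new observation costs O(t·64)), matches a
brute-force per-option implementation to machine precision, and clamps the
pivot at 1e-12. Softmax uses max-subtraction; likelihoods floor predicted
probabilities at 1e-12.

## Fitting and model selection

Models are fitted per participant by cross-validated maximum likelihood:
parameters are optimized on the natural-log scale within [−5, 5] (ε capped
at 1) by seeded differential evolution plus a Nelder-Mead polish, and each
fold is scored by the negative log likelihood of the held-out rounds.
Leave-one-round-out is the default; a `n_folds` option groups rounds into
fewer folds, which the recovery studies use (2 folds) to keep run time
proportionate. The participant-level estimate is the geometric mean of the
per-fold estimates. Out-of-sample NLL feeds the pseudo-R² against the
uniform policy, `1 − NLL/(n·ln 64)`.

Model comparison uses random-effects Bayesian model selection on the total
out-of-sample log likelihoods: a variational Dirichlet posterior over model
frequencies (α₀ = 1), exceedance probabilities by Dirichlet Monte Carlo
(1e5 samples), protected by the Bayes omnibus risk,
pxp = (1 − BOR)·xp + BOR/K.

## Synthetic cohort

The generator emulates a cross-sectional cohort of ages 5–55 in seven age
bins (5–6, 7–8, 9–10, 11–13, 14–17, 18–24, 25–55; default 40 per bin;
uniform ages within a bin). Each participant's true log-parameters follow
a piecewise-linear hinge in age — slope b1 up to a changepoint ω, slope b2
after — plus independent N(0, 0.5²) individual noise (the 0.5 log-unit SD
is this package's choice; no empirical value exists for it). Defaults:
λ rises at 0.08/yr until ω = 12.7; β falls at 0.39/yr until ω = 9.10;
τ falls at 0.59/yr until ω = 7.74; all plateau after (b2 = 0) at adult
medians λ = 0.8, β = 0.3, τ = 0.03. Participants play 10 rounds by default
on environments drawn without replacement; the initial reveal enters the
model history exactly like a choice. Experiment labels ("exp1"–"exp3") are
assigned by age bin to exercise random intercepts in regressions.

What the generator does *not* emulate: attention lapses, practice effects
across rounds, dropout, parameter covariance across the three dimensions,
or age-dependent dispersion. Passing tests therefore show that the
*pipeline* recovers the structure it assumes, not that real development
has this structure.

## Behavioural summaries

Per participant: mean reward over choices, per-trial learning and
running-maximum curves (the reveal seeds the running maximum), unique
options per round (reveal excluded), repeat/near/far proportions and mean
search distance over transitions between consecutive choices (24 per
25-choice round; near = Euclidean distance exactly 1, so diagonals are
far). The distance–reward regression models transition distance on the
previous reward (z-scored across the cohort) with fixed intercept and
slope per age group and per-participant random intercepts and slopes;
the Gaussian random effects are marginalized analytically (Woodbury,
rank 2), and the remaining parameters are sampled with emcee under
normal(0, 5) fixed-effect and half-normal(2) SD priors.

## Changepoint regression

Log parameter estimates are regressed on age with the same hinge as the
generator, continuous at ω, with a student-t likelihood (robust to
outlying estimates) and optional experiment random intercepts. Priors:
b ~ normal(0, 5); ω ~ uniform(min age, max age); σ ~ half-student-t(3, 0,
2.5); ν ~ gamma(2, 0.1); intercept SD ~ half-normal(1). Sampling is by
emcee (32–64 walkers); R̂ is computed by splitting walkers into four
pseudo-chains and is reported with every posterior; by default a violation
warns rather than raises because walker-split R̂ is a conservative,
somewhat noisy diagnostic for ensemble samplers. Candidate regressions
(intercept-only, linear, polynomials of degree 2–4 on standardized age)
share the likelihood and are ranked by PSIS-LOO.

When the changepoint sits late in the age range, b2 is weakly identified
and ω can wander; posteriors are multimodal in small cohorts. The
end-to-end analyses therefore run the regression without experiment
intercepts: the synthetic design assigns experiments by age bracket, so
intercepts would be collinear with the age trend (unlike a real multi-study
cohort with overlapping age ranges).

The similarity analysis computes Kendall's τ-b between every pair of
participants' (λ, β, τ) triples and averages within each pair of age
groups; fully tied comparisons contribute 0.

## Strategy space and stochastic optimization

Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR, linear-interpolated quartiles)
on log estimates bound each parameter's plausible range; the returned
fence is unfloored, callers may clip to the sample range. The strategy
grid is log-equally spaced, 100 points per axis at full scale (10⁶ cells,
100 simulated rounds each); the desk-scale default is 20³ with 10 rounds
per cell. Cells use independent seeded streams, so fitness is independent
of evaluation order and a checkpoint file allows resuming.

Simulated annealing proposes one uniformly random von-Neumann neighbour
(±1 along one axis, truncated at edges) and accepts any non-worsening
move; worse moves are accepted with probability exp(Δ/temp). Stochastic
hill climbing samples among all neighbours with probability
∝ exp(fitness/temp). Fitness entering both rules is min-max normalized to
[0, 1] so that temperatures of order one are meaningful; the raw 5–45
scale would make both algorithms effectively greedy at all temperatures.
Cooling schedules: fast 1/(1+i), exponential exp(−i^⅓), linear
1 − (i+1)/max_iter clamped at 1e-6. Trajectories hold n_iter states
(default 1500), state 0 being the initialization snapped to the nearest
log-space grid point (ties to the lower index); rejected proposals still
advance the iteration (and hence the temperature).

Convergence comparison: the upper 95% CI of the respective ω posterior
thresholds "converged" human estimates (age above) and algorithm values
(iteration above); an equal-size random subsample of each side feeds a
Mann-Whitney U test with a rank-biserial effect size.

## Problem sizes used by the test suite and acceptance script

Chosen to keep a single-CPU run proportionate while leaving each check
well powered: parameter recovery uses 60 agents × 10 rounds with 2-fold
cross-validation; model recovery 20 agents per generating model × 5
rounds; changepoint recovery n = 280 with 20 replicates; the end-to-end
cohort 20 participants per bin (n = 140) × 10 rounds; the landscape
ordering check a 20³ grid × 10 rounds per cell with 1500-iteration
trajectories. The full-replication grid (100³ × 100 rounds) is exposed
behind the CLI's `--full` flag.

### Scale-dependence of the cooling-schedule comparison

At desk scale the schedule comparison does not reproduce the advantage of
fast/exponential over linear cooling. With 10 simulated rounds per cell,
the frozen landscape's Monte-Carlo noise (per-cell standard error ≈ 2
reward units) exceeds the systematic fitness difference between
neighbouring cells (≈ 0.4), so the quickly-cooled algorithms — greedy
after a few dozen iterations — freeze at spurious local maxima near their
initializations, while linear cooling retains mobility for most of the
run, ratchets uphill, and ends near the optimum. The inversion persists
under raw or normalized fitness, common random numbers across cells, 40
rounds per cell, and iteration counts matched to the grid's
iterations-per-axis-point ratio. The full-scale configuration (100³ cells,
100 rounds each) has a 5× larger grid diameter and ~3× lower cell noise;
there a 1500-iteration walker under linear cooling cannot equilibrate,
which is plausibly what makes early commitment (fast/exponential cooling)
advantageous at that scale. The corresponding acceptance test asserts the
full-scale ordering at desk scale and is expected to fail; it is retained
unweakened as a documented scale artifact.

## Known limitations

- The fixed σ²ε and the /50 reward normalization are conventions; the
  underlying studies do not state them, and fitted temperatures trade off
  against the chosen scale.
- Ensemble-sampler posteriors for the hinge model can be multimodal in ω;
  the reported R̂ should be checked before interpreting CIs.
- The ε-greedy likelihood is discontinuous in the argmax; fits rely on the
  gradient-free optimizer and can be flat in λ and β when ε is large.
- Without the original participant data, printed human-data estimates
  (e.g. ω(λ) = 12.7) serve as generative defaults, not as validation
  targets.
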