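# Methods

## The stochastic logistic model

Population dynamics are a density-dependent birth–death process on
`0 ≤ n ≤ N` with birth propensity `B(n) = θ₁ n (1 − θ₂ n / N)` (clamped at
zero once `n ≥ N/θ₂`) and death propensity `D(n) = θ₃ n`. Density
dependence acts on births only; the state `n = 0` is absorbing. The mean
abundance follows the logistic equation with `r = θ₁ − θ₃` and
`K = N(θ₁ − θ₃)/(θ₁θ₂)`; in the stochastic model K is the mean of the
quasi-stationary abundance distribution rather than a hard equilibrium.

Temperature scales every rate by the Arrhenius factor
`exp(−(E_A,i/k_B)(1/T − 1/T₀))`. With one shared E_A this makes
`log r(T)` exactly linear in `1/(k_B T)` with slope `−E_A`, and `log K(T)`
linear with slope `+E_A` (K inherits the reciprocal scaling through 1/θ₂).
In the two-activation-energy variant, θ₁ and θ₃ share `E_A,r` (so the growth
rate scales with `E_A,r`) and θ₂ carries `E_A,K` (so the carrying capacity
scales with `+E_A,K`); `E_A,K` is sampled on the natural scale because real
carrying-capacity data can be flat or inverted in temperature.

Defaults mirror a typical 10-mL protist microcosm: `θ(T₀) = (1.5, 1, 0.5)`
day⁻¹ at `T₀ = 301.15 K` (28 °C), `N = 15 000`, hence `r(T₀) = 1` day⁻¹ and
`K(T₀) = 10 000`; experiments start at `n₀ = 100` individuals and run 15
days. θ₂(T₀) = 1 is implied by the triplet (r, K, N) above. The Boltzmann
constant is fixed at `8.617333262×10⁻⁵ eV K⁻¹` (CODATA). Temperatures are
Celsius at every user-facing interface and Kelvin internally.

## Simulation and observation

Sample paths are generated with the exact (event-driven) Gillespie
algorithm — populations of ≤ a few 10⁴ over 15 days are cheap to simulate
exactly, so no tau-leaping approximation is used. One continuous trajectory
is drawn per (temperature, replicate); all observations of a replicate come
from that single trajectory. The state at a sampling time is the state after
the last event at or before it (the right-continuous CTMC convention).

Counting a fraction `f` of the habitat is modelled as
`count ~ Poisson(f·n(t))`, independent across sampling times given the
trajectory, with no additional observer error. Physically the sampling is
without replacement, but the Poisson observation model is adopted exactly
as stated, including its variance implications in the corrected
likelihoods.

Design presets: temperatures 18–28 °C with 3, 6 or 11 levels; 1, 3 or 5
replicates; sampling fractions 0.001, 0.005, 0.01; sampling days
{3,6,9,12,15}, {1.5, 3, …, 15} (twice every three days; the exact half-day
grid is a package choice, exposed in the presets) or {1, …, 15}.

Reproducibility: each (temperature, replicate) series receives its own
child of the master `SeedSequence`, so datasets are bit-identical for equal
seeds and independent across series regardless of execution order.

## Likelihoods

All three observation models are Gaussian on the count scale (the
count-scale and abundance-scale forms differ only by a constant Jacobian
and give identical estimates):

* **Phenomenological** — counts iid Normal around `f · n̄(t)` with the
  deterministic logistic mean `n̄(t)` and one free standard deviation σ
  (profile-equivalent to least squares).
* **Demographic** — the mean m(t) and variance V(t) of abundance solve the
  moment (diffusion-approximation) ODEs
  `dm/dt = B(m) − D(m)`,
  `dV/dt = 2V(B′(m) − D′(m)) + B(m) + D(m)`,
  with m(0) = n₀, V(0) = 0 (the initial abundance is known); counts are
  Normal with mean `f·m(t)` and variance `f²·V(t)`. Sampling error is
  deliberately ignored — this is the model whose failure modes the
  evaluation quantifies.
* **Demographic + sampling correction** — observation variance
  `f²·V(t) + f·m(t)`, adding the Poisson variance of the counting process.

Observations within a series are treated as independent given the moment
path: the diffusion approximation supplies marginal moments only, and a
full Gaussian-process autocovariance is out of scope. Direct
(multi-temperature) likelihoods sum the per-temperature likelihood over all
series with θ(T) tied by the Arrhenius model.

Numerical choices: the moment ODEs are integrated with a fixed-step RK4
kernel (default step 0.0125 day; 0.025 day in the factorial sweeps), which
agrees with an adaptive stiff solver to better than 10⁻⁵ relative over the
whole parameter range exercised and makes a likelihood evaluation cost a
few tens of microseconds; a `lsoda` solver with configurable tolerances is
available for verification. Observation variances are floored at 10⁻⁶ to
avoid −∞ at configurations with vanishing variance. Observations at t = 0
are excluded by default (the initial condition is known there and V(0)=0).

## Inference

All free parameters are fitted on the log scale (enforcing positivity);
the two-E_A variant samples `E_A,K` linearly.

**MLE** (M1–M4): multi-start Nelder–Mead (3 starts, jittered around a crude
data-driven initializer), best log-likelihood wins, ties broken by the
smaller parameter norm. Standard errors are Wald, from the inverse
numerical Hessian; a non-positive-definite Hessian yields the status
`na-variance` with point estimates retained — this happens regularly for
the deterministic-likelihood fits and is propagated rather than hidden.

**MCMC** (M5–M10): single-chain random-walk Metropolis with a global step
size adapted every 100 iterations during burn-in toward ~30% acceptance
(frozen afterwards). Defaults: 20 000 iterations, 50% burn-in, post-burn-in
chain thinned to 1 000 retained draws; the factorial sweeps use 4 000
iterations, which chain-length experiments showed leaves the estimates
unchanged to well within Monte-Carlo noise. Priors are independent
Gaussians on the sampled scale with SD 2 natural-log units, centred on
crude initializers (growth rate from the early-time log-slope of pooled
scaled counts, carrying capacity from the mean of the last two sampling
occasions rescaled by 1/f, activation energy from an unweighted regression
of the crude per-temperature rates). A normality-test p-value of the
leading marginal is recorded with every fit, and runs with acceptance below
1% after adaptation are flagged failed.

**Indirect estimation** (M1–M8): per-temperature estimates of log r or
log K — direct parameters for the phenomenological fits, delta-method
transforms of the log-θ covariance for demographic MLE, per-draw transforms
for MCMC — are regressed on `1/(k_B T)` by weighted least squares with
weights 1/se²; E_A is −slope for r and +slope for K, with its SE from the
regression. Failed or NA-variance temperatures are excluded with a warning
provided at least three with usable SEs remain; if no usable SEs exist at
all the regression falls back to ordinary least squares. A regression whose
slope SE exceeds 2 eV — wider than the entire plausible metabolic
activation-energy range, the signature of a fit with no information about
E_A (it arises for carrying-capacity-based estimates when slow-growing cold
treatments never approach K within the horizon) — raises a `non-identified`
error, and evaluation sweeps record the run as failed rather than letting a
meaningless number dominate a mean; the cutoff is configurable (`max_se`).
The choice of T₀ only shifts the intercept, never the slope.

**Direct estimation** (M9/M10): joint posterior over
(log θ₀₁, log θ₀₂, log θ₀₃, log E_A), or the five-parameter two-E_A
layout; E_A is summarized by the posterior mean and SD of the retained
draws and the 95% interval by their 2.5/97.5 percentiles.

## Evaluation

For each (design × true E_A × method × Monte-Carlo replicate) the sweep
records the relative error `R = 100·|m(E_A) − E_A|/E_A` and the precision
`P = 100·se(E_A)/E_A`. P is normalized by the true E_A for symmetry with R;
both decrease as estimates improve. All methods in a cell see the same
simulated dataset, so comparisons are paired, and methods that differ only
in the source parameter (M5/M6, M7/M8, M3/M4, M1/M2) share one set of
per-temperature fits. Sweeps are checkpointable to CSV and resume without
recomputation.

The CART analysis regresses |R| on the four design factors with greedy
SSE-minimizing binary splits (scikit-learn's exact algorithm behind the
package's tree type): a split must reduce the root SSE by at least 1% and
leaves hold at least 5 records; leaf means are reported in percent. Each
(design × E_A × replicate) result is one record; no multiplicity
adjustment is applied because the tree is descriptive.

Problem sizes: the bundled evaluation grid spans E_A ∈ {0.2, 0.6, 1.2} eV,
all three sampling fractions, 1 or 3 replicates, 3 or 11 temperatures at
the twice-every-three-days sampling frequency, with 2 Monte-Carlo
replicates per cell (720 records) — chosen so a full sweep of all ten
methods completes in a few minutes on one CPU while leaving the method
orderings far outside Monte-Carlo noise. The full 81-design grid with six
activation energies is available (`design_grid()`, `--grid full`) and is
an overnight run at MCMC chain defaults.

## What the synthetic data do and do not show

The generator reproduces the two noise sources the inference methods
model — demographic stochasticity and Poisson sampling error — under an
exactly Arrhenius temperature dependence. It omits observer miscounting,
environmental fluctuations, non-Arrhenius (hump-shaped) thermal responses
near physiological limits, and any model misspecification of the logistic
form itself. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to ecological
reality; the known behaviour that real carrying-capacity data need not
follow the theoretical +E_A scaling is exactly why the two-E_A direct
variant exists.

## Known limitations

* The uncorrected demographic likelihood gives early, low-count
  observations near-zero model variance, so at small sampling fractions its
  estimates are strongly downward-biased (the direct uncorrected variant
  inherits this). This is the documented failure mode the sampling-error
  correction removes; the package reports it rather than papering over it.
* Posterior summaries assume approximately Gaussian marginals (checked and
  recorded per fit); strongly skewed posteriors at very sparse data are
  summarized by mean/SD regardless.
* Observation times are snapped to the RK4 grid inside the likelihoods
  (≤ 9 minutes at the default step); sub-grid timing effects are ignored.
* The exact transition-probability likelihood of the birth–death process
  (matrix exponentials) and particle-filter/ABC alternatives are out of
  scope.
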