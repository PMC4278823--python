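# thermopop

Estimating the temperature dependence of population parameters — the
activation energy of intrinsic growth rate and carrying capacity — from
abundance time series collected at several fixed temperatures, and
quantifying how experimental design and inference method determine the
quality of those estimates.

The package is aimed at experimentalists planning microcosm growth
experiments (protists, rotifers, algae, microbes) and at modellers fitting
thermal-performance relationships to such data.

## Model

Population dynamics follow a continuous-time stochastic logistic model: a
birth–death process on `0 ≤ n ≤ N` with propensities

    birth:  B(n) = θ₁ n (1 − θ₂ n / N)
    death:  D(n) = θ₃ n

where θ₁ and θ₃ are the per-capita birth and death rates (day⁻¹), θ₂ sets
the strength of density dependence on births, and N is the abundance at
which births cease. The mean abundance obeys the logistic equation with

    r = θ₁ − θ₃          (maximum growth rate)
    K = N (θ₁ − θ₃) / (θ₁ θ₂)   (carrying capacity)

Temperature enters through the Arrhenius law applied to each rate,

    θᵢ(T) = θᵢ(T₀) · exp(−(E_A,i / k_B)(1/T − 1/T₀)),

so with a shared activation energy E_A, `log r(T)` is linear in `1/(k_B T)`
with slope −E_A and `log K(T)` is linear with slope +E_A. Observation error
is Poisson: counting a fraction `f` of the habitat yields
`count ~ Poisson(f·n(t))`.

Ten estimators of E_A are provided:

| method | likelihood | scope | engine | source |
|--------|-----------|-------|--------|--------|
| M1/M2  | deterministic mean, free σ (phenomenological) | indirect | MLE | r / K |
| M3/M4  | moment ODEs (demographic noise only) | indirect | MLE | r / K |
| M5/M6  | moment ODEs | indirect | MCMC | r / K |
| M7/M8  | moment ODEs + Poisson sampling variance | indirect | MCMC | r / K |
| M9     | moment ODEs, joint over temperatures | direct | MCMC | shared E_A |
| M10    | moment ODEs + sampling variance, joint | direct | MCMC | shared E_A (or separate E_A,r and E_A,K) |

Indirect methods fit each temperature separately and regress the log
parameter on inverse thermal energy (weighted least squares); direct methods
fit all temperatures jointly with E_A an explicit parameter. The evaluation
layer sweeps a factorial design space (number of temperatures, replicates,
sampling occasions, fraction of habitat sampled) and summarizes the relative
error `R = 100·|m(E_A) − E_A|/E_A` and precision `P = 100·se(E_A)/E_A` of
each method, including a regression-tree (CART) ranking of the design
factors.

## Worked example

```python
import thermopop as tp

# simulate a 6-temperature, 3-replicate experiment at E_A = 0.6 eV,
# sampling 1% of the habitat twice every three days for 15 days
model = tp.baseline_model(0.6)                     # θ = (1.5, 1, 0.5)/d, N = 15000
design = tp.ExperimentalDesign.from_levels(6, 3, 10, 0.01)
data = tp.simulate_design(model, design, seed=1)

# indirect, sampling-corrected MCMC on growth rate (M7)
est = tp.run_method("M7", data, chain=tp.ChainConfig(seed=2))
print(f"M7:  E_A = {est.mean:.3f} +/- {est.se:.3f} eV")

# direct corrected joint fit (M10)
est = tp.run_method("M10", data, chain=tp.ChainConfig(seed=2))
print(f"M10: E_A = {est.mean:.3f} +/- {est.se:.3f} eV  ci95 = "
      f"({est.ci95[0]:.3f}, {est.ci95[1]:.3f})")
```

Output:

```
M7:  E_A = 0.581 +/- 0.026 eV
M10: E_A = 0.577 +/- 0.016 eV  ci95 = (0.547, 0.609)
```

Both methods recover the simulated activation energy of 0.6 eV within their
stated uncertainty; the direct method pools information across temperatures
and yields the tighter interval, matching its intended role.

The same functionality is available from the shell:

```bash
thermopop simulate --ea 0.6 --tempsamp 6 --reps 3 --timesamp 10 \
    --fracsamp 0.01 --seed 1 --out data.csv
thermopop fit --method M10 --data data.csv --seed 2 --out fit.json
thermopop evaluate --methods M5,M7,M9,M10 --grid reduced \
    --reps-per-cell 2 --seed 3 --out records.csv
thermopop cart --in records.csv --method M7 --out tree.json
```

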