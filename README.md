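# ppscr — point-process spatial capture–recapture

Bayesian estimation of wildlife abundance and density from spatially
referenced individual detections (camera traps are *not* the setting here —
think area searches for scat or hair DNA, where a detection can occur at
any point of the searched region). Both levels of the spatial
capture–recapture (SCR) hierarchy are modelled as point processes in
continuous space:

- **Activity centers.** Individual ACs follow an inhomogeneous Poisson
  point process over the habitat õ with a log-linear intensity on window
  covariates, log λ̃_h = β₀ + Σ β_i ξ_ih; its integral Λ̃ is the expected
  population size. Conditioned on one individual, the AC density is the
  Bernoulli point process λ̃(s)/Λ̃ — evaluated by a table lookup, with no
  per-cell categorical sampling.
- **Detections.** Given an AC s, detections over the searched region o
  form a Poisson point process with intensity b(y|θ)·exp(−‖y−s‖²/2σ²),
  where the baseline b is log-linear in detection-window covariates.
  Expected counts Λ(o|s) are closed-form Gaussian rectangle integrals —
  no detector grid, no quadrature in the likelihood.

Two fitting strategies are built in, both adaptive random-walk Metropolis
within Gibbs:

- **SCDL** (semi-complete data likelihood): never-detected individuals are
  integrated out via the marginal void probability
  p* = (1/Λ̃)∫ λ̃(s) e^{−Λ(o|s)} ds, computed by the midpoint rule; no
  data augmentation, and β₀ is estimated directly.
- **DA** (data augmentation): a super-population of size M with latent
  inclusion indicators z ~ Bernoulli(ψ); N = Σz, β₀ not estimated.

Single-detection (Bernoulli) observation models, the discretised
categorical-AC and discrete-detector baselines, an exact generative
simulator with preset study designs, and ESS/R-hat diagnostics round out
the toolkit. See `docs/methods.md` for the full model account.

## Worked example

Simulate one dataset from the 36-habitat-window design (true N = 100,
β₀ = 1, β₁ = −1, θ₀ = −1, θ₁ = 2, σ = 1) and fit it by SCDL:

```python
import ppscr
from ppscr.mcmc import ModelSpec, MCMCConfig, run_mcmc
from ppscr.diagnostics import summarize

scenario = ppscr.preset("sim3", habitat_resolution=2.0,
                        detection_resolution=1.0, seed=7)
ds = ppscr.simulate_dataset(scenario)
print(f"simulated N = {ds['N_true']}, observed n = {ds['detections'].n_observed}")

model = ModelSpec(ds["habitat"], ds["detgrid"], ds["detections"])
chains = run_mcmc(model, MCMCConfig(mode="scdl", iterations=6000,
                                    burn_in=1000, chains=2, seed=1,
                                    sigma_init=1.0))
print(summarize(chains).round(3).to_string())
```

prints

```
simulated N = 100, observed n = 52
             mean      sd    q2.5  median    q97.5      ess   rhat
parameter
beta0      -0.746   0.268  -1.343  -0.724   -0.286  151.020  1.027
beta[0]    -1.287   0.491  -2.321  -1.261   -0.400  142.142  1.018
theta0     -0.942   0.181  -1.302  -0.942   -0.591  406.118  1.014
theta[0]    1.991   0.208   1.589   1.989    2.403  577.836  1.014
sigma       0.961   0.066   0.843   0.957    1.104  217.081  1.003
u          42.341  10.224  24.000  42.000   65.000  682.165  1.006
N          94.341  10.224  76.000  94.000  117.000  682.165  1.006
p_star      0.447   0.032   0.383   0.448    0.507  302.000  1.006
```

Only 52 of the 100 individuals were ever detected, yet the abundance
posterior (mean 94.3, 95% CrI [76, 117]) recovers the truth by inferring
u ≈ 42 undetected individuals from the void probability p* ≈ 0.45. The
detection parameters (θ₀, θ₁, σ) sit within one posterior SD of their true
values. `beta0` here reflects the Poisson(Λ̃) population prior adapting to
the *realised* fixed-N dataset rather than the generating intercept — with
`n_mode="poisson"` data it is recovered directly. Swapping
`mode="da"` fits the same data by data augmentation and returns the same
abundance posterior up to Monte-Carlo error.

The same workflow is available from the shell:

```
ppscr simulate --preset sim3 --seed 7 --out run/
ppscr fit --config config.yaml
ppscr summarize --config config.yaml
```

with a YAML config naming the paths, fitting mode and MCMC settings; every
run writes a `manifest.json` (resolved config, hash, seed, version,
acceptance rates) sufficient to reproduce it exactly.

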