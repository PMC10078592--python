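# Methods

## The model

`ppscr` implements a hierarchical spatial capture–recapture (SCR) model in
which both levels of the hierarchy are spatial point processes in
continuous space.

**Activity-center (AC) distribution.** Each individual in the population
has a latent activity center s, a point summarising its home-range
location. The collection of ACs over the habitat region õ is an
inhomogeneous Poisson point process with intensity λ̃(s|β) (expected ACs
per km²). The habitat is tiled by H non-overlapping rectangular windows
within which covariates — and hence the intensity — are constant:

    log λ̃_h = β₀ + Σ_i β_i ξ_ih ,     Λ̃(õ|β) = Σ_h λ̃_h · area_h ,

so Λ̃ is the expected population size. The unnormalised Poisson
point-process log-density of an AC configuration s₁…s_N is
−Λ̃ + Σ_i log λ̃(s_i); the data-independent −log N! term is omitted
throughout, since every MCMC use is invariant to it. Conditioning the
Poisson process on its total count yields a binomial point process; for a
single individual this is a Bernoulli point process with log-density
log λ̃(s) − log Λ̃, which integrates to one over õ exactly because the
intensity is piecewise constant. This is the AC prior used for each
(observed or augmented) individual during fitting.

**Detection.** Conditional on its AC, an individual's detections over the
searched region o (a sub-region of õ; the uncovered margin is the buffer)
form a Poisson point process with intensity

    λ(y|s,θ,σ) = b(y|θ) · τ(y|s,σ) ,

where b is a piecewise-constant baseline over L detection windows
(log b_l = θ₀ + Σ_i θ_i ζ_il) and τ is the isotropic Gaussian kernel
exp(−‖y−s‖²/2σ²). The log-density of an individual's M detections is
−Λ(o|s) + Σ_j log λ(y_j|s), with Λ(o|s) = ∫_o λ(y|s) dy; with M = 0 this
exponentiates to the conditional void probability exp(−Λ(o|s)). Because b
is constant on rectangles, Λ(o|s) is a finite sum of closed-form Gaussian
rectangle integrals

    ∫_w τ dy = 2πσ² [Φ((x₂−s_x)/σ) − Φ((x₁−s_x)/σ)]
                   [Φ((y₂−s_y)/σ) − Φ((y₁−s_y)/σ)] ,

so no quadrature enters the likelihood. Variants provided: a
single-detection (Bernoulli) observation model −log Λ + log λ(y|s) for
designs where an individual can be detected at most once, its
repeated-occasion binomial product, and the discrete-detector baseline
(independent Poisson counts at cell centers) used for method comparison.

**Kernel convention.** τ is the *unnormalised* Gaussian (τ = 1 at the AC),
the SCR half-normal convention, so b_l is the detection intensity at zero
distance in detections·km⁻². The normalised-density alternative differs
only by the constant 2πσ² absorbed into θ₀; anyone comparing θ₀ values
with other software should check which convention it uses and shift by
log 2πσ² if needed.

## Fitting

### Semi-complete data likelihood (SCDL)

The ACs of the N − n never-detected individuals are integrated out through
the marginal void probability

    p* = (1/Λ̃) ∫_õ λ̃(s) exp(−Λ(o|s)) ds ,

giving the likelihood term C(N,n) p*^{N−n} Π_i P(s_i) P(y_i|s_i). Because
λ̃ is piecewise constant, p* reduces to one definite integral per habitat
window, evaluated by the midpoint rule on a regular √K×√K sub-lattice of K
nodes per window (K a perfect square; default 25 for fitting, 100 for
reporting). A total-node-budget mode (`VoidConfig(per_window=False)`) lays
a single lattice over the habitat extent instead. Without individual
heterogeneity p* is shared by all individuals; `VoidCalculator` caches it
against the parameter state (β slopes, θ₀, θ, σ — β₀ cancels) so each
state costs exactly one evaluation, and the node–detection-window kernel
integrals are additionally cached on σ, making θ updates nearly free.

**N-prior.** The default prior is N ~ Poisson(Λ̃(õ|β)), the prior induced
by the Poisson point process itself: it makes β₀ identifiable, and the
full conditional of u = N − n is exactly Poisson(Λ̃·p*), drawn in closed
form. A discrete-uniform prior on {n, …, U} is also available; under it β₀
cancels from the posterior entirely (so it is not sampled) and u moves by
an adaptive integer random-walk Metropolis step. The uniform prior is the
natural choice when comparing against data augmentation, because DA's
ψ ~ Uniform(0,1) marginalises Binomial(M, ψ) to a uniform prior on N.

### Data augmentation (DA)

The population is embedded in a super-population of fixed size
M = ⌈factor · n⌉ (factor configurable; 2 by default, matching the smallest
factor used in the efficiency comparisons). Each individual has an
inclusion indicator z_i ~ Bernoulli(ψ) and an AC; observed individuals
have z ≡ 1, and N = Σ z. β₀ is not estimated under DA (it is absorbed by
ψ); density is recovered post hoc as N times the normalised intensity
surface. ψ has a conjugate Beta(1+N, 1+M−N) Gibbs step and z a Bernoulli
full conditional with log-odds logit(ψ) − Λ(o|s_i).

### Samplers

Scalar parameters use adaptive random-walk Metropolis with per-parameter
scales (Robbins–Monro step min(0.25, t^{−0.6}) towards 44% acceptance).
ACs use a block random-walk Metropolis step: a bivariate normal proposal
on the (x, y) pair, with per-individual isotropic scales adapted towards
23.4% acceptance. All adaptation freezes at the end of burn-in. Proposals
falling outside the habitat receive a −∞ target and are rejected, which
removes any need for boundary tricks in the prior. All per-individual
quantities (window membership, Λ(o|s), detection kernel terms) are cached
and updated incrementally: θ₀ rescales Λ by e^δ, θ slopes reuse the cached
integral matrix, and the per-individual detection-location term uses the
sufficient statistics (M_i, Σ_j y_ij, Σ_j‖y_ij‖²), so only σ and AC
updates touch normal CDFs. On a regular detection lattice the rectangle
integrals are separable in x and y, reducing the CDF count per Λ
evaluation from 4L to n_x + n_y + 2 per individual.

**Initial values** (configurable): observed ACs at the centroid of the
individual's detections, augmented ACs uniform over the habitat; slope and
intercept parameters at their prior means (0); σ at half its prior upper
bound unless overridden. A non-finite initial posterior raises an error
naming the offending components. Chains are seeded as [seed, chain_index],
so identical configurations reproduce bit-identically.

**Priors** (all overridable): Normal(0, 10²) on every β and θ component,
Uniform(0, U_σ) on σ (U_σ from configuration; there is no universal
default that suits all unit systems, so set it generously above any
plausible home-range scale), Uniform(0, 1) on ψ.

### Baseline model variants

For method comparison the DA sampler also supports the discretised
baselines: `ac_model="categorical"` places each AC at a habitat-cell
centroid and Gibbs-samples the cell index from its categorical full
conditional (cost per iteration grows linearly with the number of habitat
windows — the op-counter in the run metadata makes this measurable —
whereas the point-process AC step does not); `detection_model="discrete"`
collapses each detection window to a point detector at its center with
independent Poisson counts. Both approximations bias σ upward and N
downward when cells are coarse relative to σ; the test suite checks
agreement with the continuous model only where cells are at most the
kernel scale.

## Synthetic data

The simulator draws from exactly the generative model above: ACs by
window-multinomial + uniform-within-window (fixed N) or after
N ~ Poisson(Λ̃); detections with per-window Poisson counts at the
closed-form rate b_l ∫_w τ, placed within the window by rejection sampling
against τ with the kernel value at the window point nearest the AC as the
envelope — exact, with no grid approximation. Window covariates are drawn
Uniform(−1, 1) from a dedicated sub-seed so covariates and data can be
varied independently. A truth table (all ACs, detection counts, observed
flags) is always emitted for recovery checks.

Three presets define the study designs used throughout the tests:

| preset | habitat | detection | truth |
|---|---|---|---|
| `sim1` | 10×10 km, 100 windows | 8.8×8.8 km (0.6 km buffer), 25 windows | β₀=1, θ₀=2, σ=0.2, slopes ∈ {−1,0,1}, N ~ Poisson(Λ̃) |
| `sim2` | 12×12 km, 144/36/9/4 windows | 8×8 km (2 km buffer), 64 windows | N=100, β₁=2, θ₀=θ₁=−1, σ=1 |
| `sim3` | 12×12 km, 144/36/9/4 windows | 8×8 km, 64 or 4 windows | N=100, β₀=1, β₁=−1, θ₀=−1, θ₁=2, σ=1 |

`sim2` does not need a density intercept (fixed-N Bernoulli sampling and
DA fitting both cancel it); it is set to 0. The `wolverine_like` preset is
a synthetic stand-in for a large-scale carnivore NGS survey: 40 habitat
windows of 60×60 km around 195 detection windows of 20×20 km, with
intercepts chosen so that a population of order 140 yields roughly seventy
detected individuals at σ = 5 km. Its covariates are synthetic
Uniform(−1,1) draws, not den counts, GPS search effort, snow cover or road
distance; it emulates the problem's *scale*, not its data.

What the simulator does not emulate: behavioural response to capture,
temporal occasion structure, AC movement, individual heterogeneity in
detectability, non-rectangular habitat masks, and covariate fields with
spatial autocorrelation. Passing recovery tests therefore demonstrate
self-consistency of model and fitting code under the stated designs, not
robustness to these real-data features.

## Numerical choices

- Window membership is half-open ([lower, upper) per coordinate) with the
  global upper boundary absorbed into the last row/column, so every point
  of the extent belongs to exactly one window.
- Overlap/tiling validation uses a 10⁻⁹ relative tolerance to absorb
  floating-point noise in abutting edges of non-integer resolutions.
- log C(N, n) is computed via log-gamma; p* is clamped to [0, 1]; a
  log-intensity above 700 raises (exp overflow) naming the window.
- The exact window sum is the default for Λ(o|s); windows beyond k·σ can
  optionally be skipped (`max_range_sigmas=k`), a documented approximation
  that the tests compare against the exact sum.
- Effective sample size (Geyer initial-monotone truncation) and
  rank-normalised split R-hat are computed by arviz; constant chains
  report NaN with a warning rather than failing.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to keep the default suite
practical on a single CPU while retaining power: abundance-recovery
calibration uses 30 datasets (10 per slope-sign scenario) × 11,000
iterations under DA; SCDL-vs-DA agreement uses three shared datasets ×
6,000 iterations per fit; the void-probability oracle uses 10⁶ Monte-Carlo
ACs; `scripts/acceptance.py` repeats the recovery check with 5 datasets
per scenario. All random draws derive from fixed seeds, so results are
reproducible to the bit.

## Known limitations

- SCDL assumes no individual heterogeneity (one shared p*); heterogeneous
  models would need a per-individual void probability per iteration.
- SCDL is a closed-population method here; open-population dynamics are
  out of scope.
- The categorical/discrete baselines are provided for comparison, not as
  recommended models; their bias at coarse resolutions is expected.
- Proposal adaptation freezes at burn-in; very short burn-ins can leave
  scales poorly tuned (watch the acceptance rates in the run manifest).
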