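# Methods

## Model and assumptions

The invader–resident system is a two-species competitive Lotka–Volterra
model. Stochasticity enters at the level of individual birth and death
events: species abundance is a continuous-time Markov chain on the
nonnegative integers with per-capita intrinsic birth rate λ (day⁻¹), death
rate μ (day⁻¹), and a maximum population size N at which the birth rate
reaches zero. The deterministic equilibrium ("carrying capacity") is
K = rN/λ with r = λ − μ; the separation between K and N encodes how large
demographic fluctuations are at equilibrium.

Three assumptions underlie the reduction to a tractable one-species
inference problem:

1. **Resident constancy.** Early in an introduction the resident community
   stays at its carrying capacity. With the standard design (r = 1 day⁻¹,
   K_I = K_R = 10,000, α_RI = 0.5, n₀ = 40) the deterministic resident
   trajectory never drops below 0.99 K_R within the 4-day observation
   window (we compute 0.9905 at the worst-case α_IR = 0.5); the stochastic
   `joint` simulation mode confirms the same ensemble behaviour. The
   resident's pressure is then absorbed into the invader's modified birth
   rate λ̄ = λ(1 − α K_R/N), giving the effective one-species process with
   B(n) = λ̄n(1 − n/N), D(n) = μn, r̄ = λ̄ − μ, K̄ = r̄N/λ̄.
2. **Competition acts on births only.** Competitive pressure lowers the
   invader's birth rate, not its death rate. λ̄ < 0 (possible only for
   α K_R > N, outside the standard design) is clipped to zero — a pure
   death process — and flagged; K̄ is then undefined (NaN).
3. **Diffusion regime.** N is large relative to typical abundances, so the
   transition law of the chain is well approximated by a Gaussian with
   logistic mean and a variance accumulated along the mean path (below).

The noise knob δ = (λ + μ)/2 varies demographic stochasticity without
moving the mean dynamics: λ = δ + 0.5, μ = δ − 0.5, N = 10,000 (δ + 0.5)
give r = 1 day⁻¹ and K = 10,000 individuals for every δ ∈ [0.5, 5].
δ = 0.5 is the zero-death-rate boundary (extinction impossible); δ = 5 is
roughly tenfold event-rate inflation.

A useful identity in the standard design (K_R = K_I): r̄ = r(1 − α), so the
deterministic fate of the invader flips exactly at α = 1. Outcome
classification uses strict comparisons; α = 1 is reported as the
bifurcation, with no epsilon band.

## Simulation

Trajectories are exact Gillespie samples (exponential waiting times,
propensity-proportional event choice), jitted with numba. Two resident
modes exist because the study design both fixes the resident and checks its
near-constancy: `clamped` (resident ≡ K_R, invader follows the effective
process — the default everywhere) and `joint` (both species stochastic,
with the resident's rates mirroring the invader's form symmetrically — an
extension used only for the constancy check, since the two-species
stochastic rates for the resident are not part of the effective model).

Observation is Poisson thinning: searching a fraction f of the habitat
yields Poisson(f·n) counts. The standard survey schedule is d = 10 equally
spaced observations t_i = 0.4·i over the first 4 days — about twice per
invader generation at r = 1 — with f = 0.25. The introduction size n₀ = 40
is treated as known exactly (it is the controlled release size), not
thinned. Both the schedule and f are configurable.

Seeds: every ensemble derives per-replicate 32-bit seeds from a master seed
via `numpy.random.SeedSequence`; identical master seeds give bit-identical
trajectories, observations and chains. Experiment drivers split a single
master seed into named substreams (simulation / observation / inference /
metrics) so stages can be re-run independently.

## Transition density and likelihood

For a transition from n₀ over time t, the mean follows the logistic
solution; writing a = r̄ and b = λ̄/N (so dn/dt = an − bn²),

    n(t) = n₀ e^{at} / D(t),      D(t) = 1 + (b n₀ / a)(e^{at} − 1),

with the analytic a → 0 limit D = 1 + b n₀ t. The variance is

    σ²(t) = M_t² ∫₀ᵗ [B(n_s) + D(n_s)] M_s⁻² ds,

where M_t propagates linearized fluctuations along the mean path. Because
∫₀ᵗ n_s ds has a closed form for the logistic, so does the propagator:
M_t = e^{at} / D(t)². Only the outer flux integral is numerical: composite
Simpson on a fixed 33-node grid in the fast path (relative error ≪ 1e-8
for the smooth integrands that arise here; a convergence test asserts that
doubling the grid moves σ² by < 1e-6), and grid doubling to a 1e-8
relative tolerance in the high-accuracy entry point. Two limits are exact
and serve as test oracles: pure death (λ̄ = 0) gives
σ² = n₀e^{−μt}(1 − e^{−μt}), and the linear regime (n ≪ K̄) gives
σ² = n₀ ((λ̄+μ)/r̄) e^{r̄t}(e^{r̄t} − 1). The central correctness gate
compares σ² against 10⁴-replicate Gillespie ensembles over a
(δ, α, Δt) grid at 5% relative tolerance.

The composite log-likelihood of a series of counts n_i with latent true
abundances n̄_i sums a Gaussian transition term and a Poisson observation
term per observation. Conventions fixed here:

- **Latent roles.** n̄_i is the latent true abundance (continuous,
  positive); n_i is the observed count (integer); counts are
  Poisson(f·n̄_i).
- **Conditioning.** Default is the Markov state-space form — the Gaussian
  for n̄_i is conditioned on n̄_{i−1} over Δt_i — the only internally
  consistent reading of a transition density with sampled latent states. A
  `from-origin` mode (all moments taken from n₀; latent states independent
  given θ) implements the literal reading of the printed likelihood and is
  retained for comparison; it performs strictly worse in predictive-ability
  experiments (it ignores the serial dependence of the latent path) and is
  not used by any default.
- **Variance floor.** σ² is floored at 0.25 individuals² inside the
  Gaussian density only (transition moments are reported unfloored), a
  numerical guard far below demographic scales that keeps the density
  proper at tiny Δt.
- **Extinction.** A latent path touching ≤ 0 before the last observation
  gets log-likelihood −∞ (the Gaussian diffusion is invalid at the
  absorbing boundary). Trailing zero counts are explained by the Poisson
  term with small latent values; truly absorbed series are outside the
  likelihood's domain — a known limitation.

The inference parameterization is θ = (log r, log K, log N, log K_R, α);
logs guarantee positivity. Derived rates use the identity-consistent
relations λ = rN/K, μ = λ − r (equivalently μ = λ̄(N − K̄)/N); a draw with
K > N (negative μ) is inadmissible. K_R is fixed in all scenarios.

## Priors and sampler

Four knowledge scenarios: all single-species parameters fixed to truth;
lognormal prior on K; on K and N; on K, N and r. Lognormal priors have
their median at the true value and a common log-scale SD σ ∈ [0.01, 1].
α always carries a flat prior on [0, 2], the range over which the
deterministic model exhibits its four regimes — this makes the flat prior
proper. Latent abundances carry a flat (improper) prior; the marginal
likelihood is set to 1.

The sampler is component-wise Gaussian random-walk Metropolis–Hastings:
log-scale moves for positive parameters (where the lognormal prior is
Gaussian), linear moves for α, single-site multiplicative moves for the
latent states (one sweep per parameter update, with the appropriate
Jacobian), plus a joint "ridge" move that scales α and K by a common
factor whenever K is free — this leaves r̄ = r(1 − αK_R/K) invariant and
mixes the weakly identified direction (see Identifiability). Proposal
scales adapt toward ~30% acceptance in 100-iteration windows during
burn-in only, preserving detailed balance afterwards. Defaults: 30,000
iterations, 10,000 burn-in, thinning 5, θ initialized at the prior anchors
with α = 1 (the support midpoint) and latent states at counts/f floored at
one. Chain health at defaults: post-burn-in acceptance within [0.1, 0.6]
per block and ESS(α) ≥ 200 (typically ≫ 10³ for the all-fixed scenario).
The sampler's calibration was checked by simulation: across 100 replicate
introductions (α = 0.8, δ = 1.75, all-fixed), the posterior quantile of
the true α averaged 0.47 and the nominal 90% interval covered in 90% of
replicates, with the mean posterior SD (0.119) matching the frequentist
spread of posterior means (0.124).

## Metrics

- **Predictability** at (α, δ, t): fraction of replicate stochastic
  introductions whose extant/extinct status at t matches the deterministic
  outcome. "Extinct at t" means abundance exactly 0 (absorption), not a
  threshold. At the bifurcation α = 1 the deterministic solution is scored
  as establishment (marginal persistence) and the pixel is flagged; maps
  default to 100 replicates per pixel.
- **Predictive ability**: posterior mass of α on the same side of 1 as the
  generating value, averaged over replicate introductions (mean of
  per-realization masses, not a majority vote); 30 realizations per pixel
  by default, with per-pixel derived seeds recorded so any pixel is
  re-runnable. Bifurcation pixels are excluded (no correct side exists).
- **Precision / accuracy**: replicate-averaged posterior SD of α and
  absolute error of the posterior mean.
- **Map difference**: element-wise difference on identical grids; negative
  values are meaningful (inference can out-perform raw predictability in
  the extinction half-plane, where simulated populations often have not
  yet been absorbed at small t).

## Identifiability of α under a K-only prior

With r, N and K_R fixed, the data constrain α mainly through the effective
growth rate r̄ = r(1 − α K_R/K): α and K are identified only jointly along
the ridge α ∝ K. The demographic-noise magnitude (λ̄ + μ ≈ r̄ + 2r(N/K − 1))
pins K weakly — a σ = 1 prior is compressed to a posterior SD(log K) ≈ 0.4
— and the α posterior inherits the rest of the ridge
(corr(α, log K) ≈ 0.9). Consequently the relative posterior SE of α under
a K-only prior grows with the prior width instead of saturating below 20%:
about 18% at σ = 0.01 but ≈ 56% at σ = 1 (α = 0.5, δ = 1.75, 30
realizations). The dedicated ridge move makes the sampler traverse this
direction, so the reported spread is the true posterior spread, not a
mixing artifact; samplers that fail to traverse the ridge will report
deceptively tight α posteriors in this scenario. The corresponding
acceptance test encodes the sub-20% expectation and is expected to fail;
it is kept as an honest record of the discrepancy.

## Problem sizes and experiment defaults

Map experiments default to an 11 × 10 (α, δ) grid; single-pixel
experiments (the acceptance quantities) use 30 replicate introductions
with 20,000-iteration chains (8,000 burn-in, thinning 5), which the
numba-jitted kernels complete in well under a second per fit. Module
tests use 8–12 replicates with shorter chains; the diffusion-variance
gate uses 10⁴-replicate ensembles. Monte-Carlo tolerances are stated as
3 standard errors wherever a closed-form oracle exists.

## What the generator emulates, and what it does not

The synthetic-data generator reproduces the study conditions exactly:
δ-parameterized rates, n₀ = 40 introduced into a resident at
K_R = 10,000, ten Poisson-thinned observations (f = 0.25) over four days.
It does not emulate environmental stochasticity, Allee effects, spatial
structure, time-varying search effort, or observation error other than
Poisson thinning; passing tests therefore demonstrate correctness of the
method under demographic noise and sampling error alone, not robustness
to those further realities. Communities larger than two species and
competition acting on death rates are likewise out of scope.
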