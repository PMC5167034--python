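# estabkit

Predicting whether an introduced species will establish in a resident
community — and quantifying how far demographic stochasticity and imperfect
parameter knowledge limit that prediction.

`estabkit` is for ecologists and biostatisticians who have (or can simulate)
short, noisy abundance time series from the first days after an introduction
and want a posterior probability of establishment, together with an honest
account of how demographic noise and prior uncertainty degrade it.

## The model

The resident community and the invader follow competitive Lotka–Volterra
dynamics,

    dn_I/dt = r_I n_I (1 − (n_I + α n_R) / K_I),

made stochastic as a continuous-time birth–death chain with per-capita
intrinsic birth rate λ, death rate μ (r = λ − μ) and a maximum population
size N at which births cease (K = rN/λ). During the first days of an
introduction the resident stays at its carrying capacity K_R (we verify
n_R > 0.99 K_R), so its competitive pressure folds into a modified invader
birth rate

    λ̄ = λ (1 − α K_R / N),     B(n) = λ̄ n (1 − n/N),   D(n) = μ n,

a one-species stochastic logistic process with effective growth rate
r̄ = λ̄ − μ and capacity K̄ = r̄N/λ̄. The deterministic fate flips at the
bifurcation α = 1: establishment below, extinction above.

Demographic stochasticity is controlled by a single knob δ = (λ + μ)/2:
setting λ = δ + 0.5, μ = δ − 0.5, N = 10,000 (δ + 0.5) pins the mean
dynamics (r = 1 day⁻¹, K = 10,000) while the event rate — the noise —
scales with δ.

Inference uses a diffusion (moment) approximation: the population size a
time t after being at n₀ is Gaussian with logistic mean and variance

    σ²(t) = M_t² ∫₀ᵗ [B(n_s) + D(n_s)] M_s⁻² ds,   M_t = e^{r̄t}/D(t)²,

combined with Poisson observation error (searching a fraction f of the
habitat yields Poisson(f·n) counts). A Metropolis–Hastings sampler draws
the joint posterior of θ = (log r, log K, log N, log K_R, α) and the latent
abundances under four scenarios of prior knowledge, from all single-species
parameters known exactly to lognormal priors (median at truth, log-scale
width σ) on K, N and r; α always carries a flat prior on [0, 2].

Three headline metrics:

- **predictability** — probability a stochastic realization matches the
  deterministic outcome at time t;
- **predictive ability** — posterior mass of α on the correct side of 1,
  averaged over replicate introductions;
- **precision / accuracy** — posterior SE of α, and the absolute error of
  its posterior mean.

## Worked example

Simulate one introduction of 40 individuals at α = 0.8 (deterministic
establishment, r̄ = 0.2) under moderate noise δ = 1.75, observe 10
Poisson-thinned counts (f = 0.25) over 4 days, and infer α with all
single-species parameters known:

```python
from estabkit import EstablishmentModel
from estabkit.metrics import simulate_observation_series

obs = simulate_observation_series(alpha=0.8, delta=1.75, seed=11)
print(obs.counts.tolist())
# [11, 10, 9, 9, 9, 15, 15, 13, 12, 12]

res = EstablishmentModel(obs, scenario="all_fixed", delta=1.75).fit(seed=2)
print(res.summary())
```

```
Establishment inference (Metropolis-Hastings)
==============================================
scenario:          all_fixed
prior width sigma: 0.3
draws:             4000 (iter 30000, burn 10000, thin 5)
ESS(alpha):        2103
----------------------------------------------
alpha mean (SE):   0.937 (0.125)
alpha 95% CI:      [0.678, 1.176]
P(alpha < 1):      0.688
P(alpha > 1):      0.312
----------------------------------------------
acceptance: alpha=0.30, latent=0.30
```

`P(alpha < 1) = 0.688` is this realization's predictive ability: given only
ten noisy counts, 69% of the posterior sits on the establishment side of the
bifurcation even though the species truly establishes — demographic noise
in a single short series leaves real ambiguity. Averaging this quantity over
replicate introductions (`estabkit.metrics.mean_predictive_ability`) gives
the expected fraction of correct establish/extinct calls at that (α, δ).

A command-line interface mirrors the library:

```
estabkit simulate --delta 1.75 --alpha 0.8 --reps 100 --seed 1 --out traj.csv
estabkit infer --obs obs.csv --delta 1.75 --scenario prior_k_n_r --sigma 0.3
estabkit predictability-map --t 4 --reps 100 --out map.csv
estabkit run --config experiment.yaml
```

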