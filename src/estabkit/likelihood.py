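"""Diffusion-approximation transition density and composite log-likelihood.

For the stochastic logistic invader process with birth rate
B(n) = λ̄ n (1 - n/N) and death rate D(n) = μ n, the probability of the
population size a time t after it was n₀ is approximately Gaussian
(diffusion / moment approximation, valid for large N).  Its mean follows
the logistic equation with effective rates (r̄, K̄),

    n(t) = K̄ n₀ e^{r̄t} / (K̄ + n₀ (e^{r̄t} - 1)),

and its variance is

    σ²(t) = M_t² ∫₀ᵗ [B(n_s) + D(n_s)] M_s⁻² ds,

where M_t = exp(∫₀ᵗ F'(n_s) ds) propagates fluctuations along the mean
path (F = B - D).  Along the logistic path the propagator integral has
the closed form M_t = e^{r̄t} / D(t)² with D(t) = 1 + (λ̄ n₀ / (r̄ N))
(e^{r̄t} - 1), so only the outer integral is evaluated numerically
(composite Simpson, with interval doubling to a relative tolerance of
1e-8 in the high-accuracy entry point).

A time series y = (n₁, t₁; …; n_d, t_d) of Poisson-thinned counts
(search fraction f) with latent true abundances n̄ᵢ has composite
log-likelihood

    L = Σᵢ [ log P_g(n̄ᵢ ; n̄ᵢ₋₁, Δtᵢ, θ) + log Pois(nᵢ ; f n̄ᵢ) ],

with the Gaussian transition term conditioned per interval (Markov
state-space form, the default) or, optionally, with all moments taken
from n₀ (``from-origin``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .gillespie import ObservationSeries
from .params import SpeciesParams

__all__ = [
    "InferenceParams",
    "TransitionMoments",
    "transition_moments",
    "gaussian_logdensity",
    "observation_logpmf",
    "loglikelihood",
    "VARIANCE_FLOOR",
]

#: Variance floor (individuals²) keeping the Gaussian proper for tiny Δt.
VARIANCE_FLOOR = 0.25

#: Simpson node count of the fast fixed-grid path (shared with the sampler).
SIMPSON_NODES = 33

_EXP_CLIP = 300.0


@dataclass(frozen=True)
class InferenceParams:
    """Inference parameter vector θ = (log r, log K, log N, log K_R, α).

    The log parameterization guarantees positivity of the single-species
    parameters; all process-4 rates derive from it:

        λ = r N / K,   μ = λ - r,   λ̄ = λ (1 - α K_R / N),
        r̄ = λ̄ - μ,    K̄ = r̄ N / λ̄.

    (Equivalently μ = λ̄ (N - K̄)/N, the identity-consistent form.)
    A parameter vector with K > N (negative μ) is inadmissible.
    """

    log_r: float
    log_K: float
    log_N: float
    log_K_R: float
    alpha: float

    @classmethod
    def from_truth(
        cls, invader: SpeciesParams, resident_K: float, alpha: float
    ) -> "InferenceParams":
        return cls(
            log_r=math.log(invader.growth_rate),
            log_K=math.log(invader.carrying_capacity),
            log_N=math.log(invader.max_pop),
            log_K_R=math.log(resident_K),
            alpha=alpha,
        )

    @property
    def r(self) -> float:
        return math.exp(self.log_r)

    @property
    def K(self) -> float:
        return math.exp(self.log_K)

    @property
    def N(self) -> float:
        return math.exp(self.log_N)

    @property
    def K_R(self) -> float:
        return math.exp(self.log_K_R)

    def rates(self) -> tuple[float, float]:
        """Derived (λ̄, μ); λ̄ clipped at 0, μ < 0 raises."""
        lam = self.r * self.N / self.K
        mu = lam - self.r
        if mu < 0:
            raise ValueError("K > N implies a negative death rate")
        lam_bar = max(lam * (1.0 - self.alpha * self.K_R / self.N), 0.0)
        return lam_bar, mu


@dataclass(frozen=True)
class TransitionMoments:
    """Gaussian transition moments over one interval."""

    mean: float
    var: float
    dt: float
    n_from: float


def _moments_grid(n_from, dt, lam_bar, mu, N, nodes):
    """Vectorized mean/variance over arrays of (n_from, dt); fixed Simpson grid.

    Closed-form logistic mean and propagator; only the flux integral is
    numerical.  Shapes: n_from, dt broadcast to (m,); returns (mean, var)
    arrays of shape (m,).
    """
    n_from = np.atleast_1d(np.asarray(n_from, dtype=float))
    dt = np.broadcast_to(np.asarray(dt, dtype=float), n_from.shape).astype(float)
    a = lam_bar - mu  # effective growth rate r̄
    b = lam_bar / N
    s = np.linspace(0.0, 1.0, nodes)[None, :] * dt[:, None]  # (m, nodes)
    at = np.clip(a * s, -_EXP_CLIP, _EXP_CLIP)
    E = np.exp(at)
    if abs(a) > 1e-12:
        D = 1.0 + (b / a) * n_from[:, None] * (E - 1.0)
        n_s = n_from[:, None] * E / D
    else:
        D = 1.0 + b * n_from[:, None] * s
        n_s = n_from[:, None] / D
        E = np.ones_like(D)
    birth = np.clip(lam_bar * n_s * (1.0 - n_s / N), 0.0, None)
    flux = birth + mu * n_s
    # (M_t / M_s)² = (E_t/E_s)² (D_s/D_t)⁴ with M = E / D²
    Et = E[:, -1:]
    Dt = D[:, -1:]
    ratio2 = (Et / E) ** 2 * (D / Dt) ** 4
    integrand = flux * ratio2
    h = dt / (nodes - 1)
    w = np.ones(nodes)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    var = (h / 3.0) * (integrand * w[None, :]).sum(axis=1)
    mean = n_s[:, -1]
    return mean, var


def transition_moments(
    n_from: float, dt: float, theta: InferenceParams, rtol: float = 1e-8
) -> TransitionMoments:
    """High-accuracy Gaussian transition moments from ``n_from`` over ``dt``.

    The Simpson grid is doubled until the variance changes by less than
    ``rtol`` relative (Richardson-style convergence check).  The r̄ = 0
    case is handled by the analytic limit of the logistic solution.
    """
    if n_from <= 0:
        raise ValueError("n_from must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam_bar, mu = theta.rates()
    nodes = SIMPSON_NODES
    mean, var = _moments_grid(n_from, dt, lam_bar, mu, theta.N, nodes)
    for _ in range(10):
        nodes = 2 * nodes - 1
        mean2, var2 = _moments_grid(n_from, dt, lam_bar, mu, theta.N, nodes)
        if abs(var2[0] - var[0]) <= rtol * max(abs(var2[0]), 1e-300):
            var = var2
            mean = mean2
            break
        mean, var = mean2, var2
    return TransitionMoments(mean=float(mean[0]), var=float(var[0]), dt=dt, n_from=n_from)


def gaussian_logdensity(x: float, moments: TransitionMoments) -> float:
    """Gaussian transition log-density with the floored variance."""
    if not (np.isfinite(x) and np.isfinite(moments.mean) and np.isfinite(moments.var)):
        raise ValueError("non-finite inputs to the Gaussian transition density")
    var = max(moments.var, VARIANCE_FLOOR)
    return -0.5 * math.log(2.0 * math.pi * var) - 0.5 * (x - moments.mean) ** 2 / var


def observation_logpmf(n_obs: int, n_true: float, f: float) -> float:
    """Poisson sampling log-pmf: count ~ Poisson(f · n_true)."""
    if n_obs < 0 or n_obs != int(n_obs):
        raise ValueError("observed count must be a nonnegative integer")
    if not (0.0 < f <= 1.0):
        raise ValueError(f"search fraction must be in (0, 1], got {f}")
    if n_true < 0:
        raise ValueError("true abundance must be nonnegative")
    m = f * n_true
    if m == 0.0:
        return 0.0 if n_obs == 0 else -math.inf
    return n_obs * math.log(m) - m - float(gammaln(n_obs + 1))


def loglikelihood(
    obs: ObservationSeries,
    latent,
    theta: InferenceParams,
    mode: str = "markov",
) -> float:
    """Composite log-likelihood of a Poisson-thinned observation series.

    ``latent`` holds the true abundances n̄₁..n̄_d at the observation
    times (n̄₀ = the known introduction size).  A latent value ≤ 0 makes
    the Gaussian diffusion invalid at the absorbing boundary and returns
    -inf, signalling proposal rejection.

    ``mode="markov"`` (default) conditions each Gaussian transition on the
    previous latent state; ``mode="from-origin"`` takes all moments from
    n₀ (latent states conditionally independent given θ).
    """
    latent = np.asarray(latent, dtype=float)
    if latent.shape != (obs.d,):
        raise ValueError(f"latent must have length d = {obs.d}")
    if np.any(latent <= 0):
        return -math.inf
    if mode not in ("markov", "from-origin"):
        raise ValueError(f"unknown conditioning mode {mode!r}")
    try:
        lam_bar, mu = theta.rates()
    except ValueError:
        return -math.inf

    times = np.concatenate(([0.0], obs.times))
    states = np.concatenate(([float(obs.n0)], latent))
    if mode == "markov":
        n_from = states[:-1]
        dt = np.diff(times)
    else:
        n_from = np.full(obs.d, float(obs.n0))
        dt = obs.times
    mean, var = _moments_grid(n_from, dt, lam_bar, mu, theta.N, SIMPSON_NODES)
    var = np.maximum(var, VARIANCE_FLOOR)
    trans = -0.5 * np.log(2.0 * math.pi * var) - 0.5 * (latent - mean) ** 2 / var
    m = obs.f * latent
    counts = np.asarray(obs.counts, dtype=float)
    obs_ll = counts * np.log(m) - m - gammaln(counts + 1.0)
    total = float(trans.sum() + obs_ll.sum())
    return total if np.isfinite(total) else -math.inf
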