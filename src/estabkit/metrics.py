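"""Predictability, predictive ability, precision and accuracy.

*Predictability* is the probability that a stochastic realization of the
introduction shows, at evaluation time t, the same extant/extinct status
as the deterministic Lotka–Volterra outcome for that interaction strength
(establishment for α < 1, extinction for α > 1).  "Extinct at t" means
the population is exactly 0 at t — absorption in the birth–death chain.

*Predictive ability* is the posterior probability mass of the inferred
interaction strength lying on the same side of the bifurcation (α = 1)
as the generating value, averaged over replicate introductions — i.e.
the expected fraction of correct establish/extinct calls made from the
inferred α.

*Precision* and *accuracy* of the α estimate are the posterior standard
error and the absolute error of the posterior mean, averaged over
replicate fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .gillespie import (
    ObservationSeries,
    default_observation_times,
    ensemble,
    observe,
    spawn_seeds,
)
from .likelihood import InferenceParams
from .mcmc import PosteriorSample, Scenario, build_priors, mh_sample, posterior_summary
from .params import (
    CompetitionSetup,
    DeterministicOutcome,
    deterministic_outcome,
    species_params_from_delta,
)

__all__ = [
    "GridSpec",
    "MetricMap",
    "predictability",
    "predictability_map",
    "predictive_ability",
    "predictive_ability_map",
    "precision_accuracy",
    "map_difference",
    "simulate_observation_series",
    "replicate_posteriors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """(α, δ) grid and replicate counts for map experiments."""

    alphas: np.ndarray = field(
        default_factory=lambda: np.round(np.linspace(0.5, 1.5, 11), 10)
    )
    deltas: np.ndarray = field(
        default_factory=lambda: np.round(np.linspace(0.5, 5.0, 10), 10)
    )
    times: tuple = (4.0,)
    n_reps_predictability: int = 100
    n_reps_inference: int = 30

    def __post_init__(self) -> None:
        for name in ("alphas", "deltas"):
            g = np.asarray(getattr(self, name), dtype=float)
            if np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} grid must be strictly increasing")
        if self.n_reps_predictability < 1 or self.n_reps_inference < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass(frozen=True)
class MetricMap:
    """Matrix of a metric over the (α, δ) grid, with run metadata."""

    alphas: np.ndarray
    deltas: np.ndarray
    values: np.ndarray  # shape (len(alphas), len(deltas))
    time: float
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        """Long-format DataFrame (alpha, delta, t, value)."""
        import pandas as pd

        a, d = np.meshgrid(self.alphas, self.deltas, indexing="ij")
        return pd.DataFrame(
            {
                "alpha": a.ravel(),
                "delta": d.ravel(),
                "t": self.time,
                "value": self.values.ravel(),
            }
        )


def predictability(
    alpha: float,
    delta: float,
    t: float,
    n_reps: int = 100,
    n0: int = 40,
    seed: int = 0,
) -> float:
    """Fraction of stochastic replicates matching the deterministic outcome.

    At α = 1 (bifurcation) the replicate is scored against establishment,
    the deterministic solution's marginal persistence.
    """
    setup = CompetitionSetup.from_delta(delta, alpha_IR=alpha, n0_invader=n0)
    eff = setup.effective_invader()
    summ = ensemble(eff, n0, [t], n_reps, master_seed=seed)
    p_ext = float(summ.extinct_fraction[0])
    outcome = deterministic_outcome(alpha)
    if outcome is DeterministicOutcome.EXTINCT:
        return p_ext
    return 1.0 - p_ext


def predictability_map(grid: GridSpec, seed: int = 0, t: float | None = None) -> MetricMap:
    """Predictability at every (α, δ) pixel, per-pixel derived seeds."""
    t = grid.times[0] if t is None else t
    ss = np.random.SeedSequence(seed)
    pixel_seeds = ss.generate_state(len(grid.alphas) * len(grid.deltas))
    vals = np.empty((len(grid.alphas), len(grid.deltas)))
    k = 0
    for i, a in enumerate(grid.alphas):
        for j, d in enumerate(grid.deltas):
            vals[i, j] = predictability(
                a, d, t, n_reps=grid.n_reps_predictability, seed=int(pixel_seeds[k])
            )
            k += 1
    return MetricMap(
        alphas=np.asarray(grid.alphas, dtype=float),
        deltas=np.asarray(grid.deltas, dtype=float),
        values=vals,
        time=t,
        metadata={"seed": seed, "n_reps": grid.n_reps_predictability},
    )


def predictive_ability(posterior: PosteriorSample, true_alpha: float) -> float:
    """Posterior mass of α on the same side of 1 as the generating value."""
    if true_alpha == 1.0:
        raise ValueError("predictive ability is undefined at the bifurcation alpha = 1")
    s = posterior_summary(posterior)
    return s["mass_below_1"] if true_alpha < 1.0 else s["mass_above_1"]


def simulate_observation_series(
    alpha: float,
    delta: float,
    seed: int,
    n0: int = 40,
    d: int = 10,
    t_end: float = 4.0,
    f: float = 0.25,
) -> ObservationSeries:
    """One clamped-resident introduction observed on the standard schedule."""
    setup = CompetitionSetup.from_delta(delta, alpha_IR=alpha, n0_invader=n0)
    eff = setup.effective_invader()
    times = default_observation_times(d, t_end)
    sim_seed, obs_seed = spawn_seeds(seed, 2)
    summ = ensemble(eff, n0, times, 1, master_seed=int(sim_seed))
    latent = summ.mean  # single replicate: the sampled path itself
    counts = observe(latent, f, int(obs_seed))
    return ObservationSeries(times=times, latent=latent, counts=counts, f=f, n0=n0)


def replicate_posteriors(
    alpha: float,
    delta: float,
    scenario: Scenario | str,
    sigma: float = 0.3,
    n_realizations: int = 30,
    seed: int = 0,
    n0: int = 40,
    d: int = 10,
    t_end: float = 4.0,
    f: float = 0.25,
    n_iter: int = 20_000,
    n_burn: int = 8_000,
    thin: int = 5,
) -> list[PosteriorSample]:
    """Simulate-and-fit replicate introductions at one (α, δ) pixel."""
    sp = species_params_from_delta(delta)
    anchors = InferenceParams.from_truth(sp, resident_K=10_000.0, alpha=alpha)
    priors = build_priors(scenario, sigma, anchors)
    rep_seeds = spawn_seeds(seed, 2 * n_realizations).reshape(n_realizations, 2)
    out = []
    for k in range(n_realizations):
        obs = simulate_observation_series(
            alpha, delta, int(rep_seeds[k, 0]), n0=n0, d=d, t_end=t_end, f=f
        )
        try:
            out.append(
                mh_sample(
                    obs, priors, n_iter=n_iter, n_burn=n_burn, thin=thin,
                    seed=int(rep_seeds[k, 1]),
                )
            )
        except RuntimeError as exc:  # degenerate chain: log, never silently drop
            logger.warning(
                "inference failed at alpha=%g delta=%g replicate %d: %s",
                alpha, delta, k, exc,
            )
    return out


def mean_predictive_ability(
    alpha: float,
    delta: float,
    scenario: Scenario | str,
    sigma: float = 0.3,
    n_realizations: int = 30,
    seed: int = 0,
    **kwargs,
) -> float:
    """Mean over replicate introductions of the per-fit predictive ability."""
    posts = replicate_posteriors(
        alpha, delta, scenario, sigma, n_realizations, seed, **kwargs
    )
    if not posts:
        return math.nan
    return float(np.mean([predictive_ability(p, alpha) for p in posts]))


def predictive_ability_map(
    grid: GridSpec,
    scenario: Scenario | str,
    sigma: float = 0.3,
    seed: int = 0,
    **kwargs,
) -> MetricMap:
    """Mean predictive ability per (α, δ) pixel (bifurcation pixels NaN).

    Each pixel simulates ``grid.n_reps_inference`` introductions, runs the
    sampler under ``scenario`` and averages the per-realization posterior
    mass on the correct side of α = 1.
    """
    ss = np.random.SeedSequence(seed)
    pixel_seeds = ss.generate_state(len(grid.alphas) * len(grid.deltas))
    vals = np.full((len(grid.alphas), len(grid.deltas)), np.nan)
    k = 0
    for i, a in enumerate(grid.alphas):
        for j, d in enumerate(grid.deltas):
            if a != 1.0:  # no correct side exists at the bifurcation
                vals[i, j] = mean_predictive_ability(
                    a, d, scenario, sigma,
                    n_realizations=grid.n_reps_inference,
                    seed=int(pixel_seeds[k]),
                    **kwargs,
                )
            k += 1
    return MetricMap(
        alphas=np.asarray(grid.alphas, dtype=float),
        deltas=np.asarray(grid.deltas, dtype=float),
        values=vals,
        time=kwargs.get("t_end", 4.0),
        metadata={
            "seed": seed,
            "scenario": str(scenario),
            "sigma": sigma,
            "n_reps": grid.n_reps_inference,
        },
    )


def precision_accuracy(
    posteriors: list[PosteriorSample], true_alpha: float
) -> tuple[float, float]:
    """Replicate-averaged (posterior SE of α, |posterior mean − truth|)."""
    if not posteriors:
        raise ValueError("need at least one posterior sample")
    ses = []
    errs = []
    for p in posteriors:
        s = posterior_summary(p)
        ses.append(s["se_alpha"])
        errs.append(abs(s["mean_alpha"] - true_alpha))
    return float(np.mean(ses)), float(np.mean(errs))


def map_difference(a: MetricMap, b: MetricMap) -> MetricMap:
    """Element-wise difference of two maps on identical grids."""
    if not (
        np.array_equal(a.alphas, b.alphas) and np.array_equal(a.deltas, b.deltas)
    ):
        raise ValueError("maps are defined on different (alpha, delta) grids")
    return MetricMap(
        alphas=a.alphas,
        deltas=a.deltas,
        values=a.values - b.values,
        time=a.time,
        metadata={"difference_of": (a.metadata, b.metadata)},
    )
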