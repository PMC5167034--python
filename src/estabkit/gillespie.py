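"""Exact stochastic simulation of the invader birth–death process.

The invader follows a stochastic logistic birth–death chain with
propensities

    B(n) = λ̄ n (1 - n/N)   (clipped at 0),      D(n) = μ n,

simulated exactly with the Gillespie algorithm (exponential waiting times,
propensity-proportional event choice).  Two resident modes are provided:

``clamped``
    the resident sits at its carrying capacity K_R and its pressure is
    absorbed into λ̄ — the default for all map and inference experiments;
``joint``
    both species are simulated stochastically with symmetric competitive
    rates — used to check that the resident indeed stays near K_R.

Observation is modelled as a Poisson-thinned count: searching a fraction
``f`` of the habitat yields Poisson(f · n) individuals.

Inner loops are numba-jitted; per-replicate seeds are spawned
deterministically from a master seed so ensembles are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import CompetitionSetup, EffectiveParams

__all__ = [
    "EventTrajectory",
    "ObservationSeries",
    "EnsembleSummary",
    "simulate_invader",
    "simulate_pair",
    "sample_at_times",
    "observe",
    "ensemble",
    "default_observation_times",
    "spawn_seeds",
]

DEFAULT_SEARCH_FRACTION = 0.25


def default_observation_times(d: int = 10, t_end: float = 4.0) -> np.ndarray:
    """The standard survey schedule: d equally spaced times in (0, t_end].

    The default d = 10 over the first 4 days corresponds to sampling twice
    per invader generation (r = 1 day⁻¹); the introduction size n₀ is
    treated as known at t = 0 and is not part of the schedule.
    """
    return np.linspace(t_end / d, t_end, d)


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate 32-bit seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint32)


@dataclass(frozen=True)
class EventTrajectory:
    """Continuous-time piecewise-constant population path(s).

    ``times[0] = 0`` holds the initial state; subsequent entries are event
    times.  ``pops`` has shape (n_events + 1, n_species).  ``absorbed`` is
    True when the invader (species 0) hit zero before ``t_end``.
    """

    times: np.ndarray
    pops: np.ndarray
    t_end: float
    absorbed: bool

    @property
    def n_species(self) -> int:
        return self.pops.shape[1]


@dataclass(frozen=True)
class ObservationSeries:
    """Discretely sampled, Poisson-thinned observations of one introduction."""

    times: np.ndarray
    latent: np.ndarray
    counts: np.ndarray
    f: float = DEFAULT_SEARCH_FRACTION
    n0: int = 40

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0) or (len(t) and t[0] <= 0):
            raise ValueError("observation times must be strictly increasing and > 0")
        if not (0.0 < self.f <= 1.0):
            raise ValueError(f"search fraction must be in (0, 1], got {self.f}")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("observed counts must be nonnegative")

    @property
    def d(self) -> int:
        """Number of observation events."""
        return len(self.times)


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-time moments and extinction fraction over replicate simulations."""

    times: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    extinct_fraction: np.ndarray
    n_reps: int
    values: np.ndarray | None = None  # (n_reps, n_times) sampled sizes, on request


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sim_events_kernel(lam_bar, mu, N, n0, t_end, seed, out_t, out_n):
    """Full event record; returns (n_events, absorbed, overflow)."""
    np.random.seed(seed)
    t = 0.0
    n = n0
    k = 0
    cap = out_t.shape[0]
    absorbed = n == 0
    while n > 0:
        b = lam_bar * n * (1.0 - n / N)
        if b < 0.0:
            b = 0.0
        d = mu * n
        tot = b + d
        if tot <= 0.0:
            break
        t += np.random.exponential(1.0 / tot)
        if t > t_end:
            break
        if np.random.random() * tot < b:
            n += 1
        else:
            n -= 1
        if k >= cap:
            return k, absorbed, True
        out_t[k] = t
        out_n[k] = n
        k += 1
        if n == 0:
            absorbed = True
    return k, absorbed, False


@njit(cache=True)
def _sim_sampled_kernel(lam_bar, mu, N, n0, times, seed, out):
    """Population size at each requested time; returns absorbed flag."""
    np.random.seed(seed)
    t = 0.0
    n = n0
    idx = 0
    m = times.shape[0]
    while True:
        b = lam_bar * n * (1.0 - n / N)
        if b < 0.0:
            b = 0.0
        d = mu * n
        tot = b + d
        if tot <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / tot)
        while idx < m and times[idx] < t_next:
            out[idx] = n
            idx += 1
        if idx >= m:
            break
        t = t_next
        if np.random.random() * tot < b:
            n += 1
        else:
            n -= 1
    return n == 0


@njit(cache=True)
def _ensemble_kernel(lam_bar, mu, N, n0, times, seeds, out):
    for r in range(seeds.shape[0]):
        _sim_sampled_kernel(lam_bar, mu, N, n0, times, seeds[r], out[r])


@njit(cache=True)
def _sim_pair_kernel(
    lamI, muI, NI, lamR, muR, NR, aIR, aRI, n0I, n0R, t_end, seed, out_t, out_nI, out_nR
):
    """Joint two-species Gillespie; returns (n_events, absorbed, overflow)."""
    np.random.seed(seed)
    t = 0.0
    nI = n0I
    nR = n0R
    k = 0
    cap = out_t.shape[0]
    absorbed = nI == 0
    while True:
        bI = lamI * nI * (1.0 - (nI + aIR * nR) / NI)
        if bI < 0.0:
            bI = 0.0
        dI = muI * nI
        bR = lamR * nR * (1.0 - (nR + aRI * nI) / NR)
        if bR < 0.0:
            bR = 0.0
        dR = muR * nR
        tot = bI + dI + bR + dR
        if tot <= 0.0:
            break
        t += np.random.exponential(1.0 / tot)
        if t > t_end:
            break
        u = np.random.random() * tot
        if u < bI:
            nI += 1
        elif u < bI + dI:
            nI -= 1
        elif u < bI + dI + bR:
            nR += 1
        else:
            nR -= 1
        if k >= cap:
            return k, absorbed, True
        out_t[k] = t
        out_nI[k] = nI
        out_nR[k] = nR
        k += 1
        if nI == 0:
            absorbed = True
    return k, absorbed, False


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _seed32(seed: int) -> int:
    return int(np.uint32(seed))


def simulate_invader(
    eff: EffectiveParams, n0: int, t_end: float, seed: int
) -> EventTrajectory:
    """Exact sample of the one-species invader birth–death chain.

    Event lists are stored in full; once the invader hits zero the
    trajectory is absorbed and no further events occur.
    """
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    cap = 4096
    while True:
        out_t = np.empty(cap)
        out_n = np.empty(cap, dtype=np.int64)
        k, absorbed, overflow = _sim_events_kernel(
            eff.eff_birth, eff.death_rate, eff.max_pop, n0, t_end, _seed32(seed),
            out_t, out_n,
        )
        if not overflow:
            break
        cap *= 4  # re-run with the same seed: identical path, larger buffer
    times = np.concatenate(([0.0], out_t[:k]))
    pops = np.concatenate(([n0], out_n[:k])).reshape(-1, 1)
    return EventTrajectory(times=times, pops=pops, t_end=float(t_end), absorbed=bool(absorbed))


def simulate_pair(
    setup: CompetitionSetup, t_end: float, seed: int, mode: str = "clamped"
) -> EventTrajectory:
    """Exact simulation of invader and resident.

    In ``clamped`` mode the resident is held at K_R and the invader follows
    the effective one-species process (identical paths to
    :func:`simulate_invader` for the same seed); ``joint`` simulates both
    species stochastically with symmetric competitive birth rates.
    """
    if mode == "clamped":
        eff = setup.effective_invader()
        traj = simulate_invader(eff, setup.n0_invader, t_end, seed)
        nR = np.full((len(traj.times), 1), float(setup.resident.carrying_capacity))
        return EventTrajectory(
            times=traj.times,
            pops=np.hstack([traj.pops.astype(float), nR]),
            t_end=traj.t_end,
            absorbed=traj.absorbed,
        )
    if mode != "joint":
        raise ValueError(f"unknown resident mode {mode!r}")
    cap = 1 << 16
    while True:
        out_t = np.empty(cap)
        out_nI = np.empty(cap, dtype=np.int64)
        out_nR = np.empty(cap, dtype=np.int64)
        k, absorbed, overflow = _sim_pair_kernel(
            setup.invader.birth_rate, setup.invader.death_rate, setup.invader.max_pop,
            setup.resident.birth_rate, setup.resident.death_rate, setup.resident.max_pop,
            setup.alpha_IR, setup.alpha_RI,
            setup.n0_invader, setup.n0_resident, t_end, _seed32(seed),
            out_t, out_nI, out_nR,
        )
        if not overflow:
            break
        cap *= 4
    times = np.concatenate(([0.0], out_t[:k]))
    pops = np.column_stack(
        [
            np.concatenate(([setup.n0_invader], out_nI[:k])),
            np.concatenate(([setup.n0_resident], out_nR[:k])),
        ]
    ).astype(float)
    return EventTrajectory(times=times, pops=pops, t_end=float(t_end), absorbed=bool(absorbed))


def sample_at_times(traj: EventTrajectory, times, species: int = 0) -> np.ndarray:
    """Right-continuous piecewise-constant lookup of a trajectory.

    Returns the population size after the last event at or before each
    requested time; times beyond the trajectory's horizon are an error.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0) or np.any(times > traj.t_end):
        raise ValueError("sample times must lie within [0, t_end]")
    idx = np.searchsorted(traj.times, times, side="right") - 1
    return traj.pops[idx, species]


def observe(latent, f: float, seed: int) -> np.ndarray:
    """Poisson-thinned counts: each draw ~ Poisson(f · latent size)."""
    if not (0.0 < f <= 1.0):
        raise ValueError(f"search fraction must be in (0, 1], got {f}")
    latent = np.asarray(latent, dtype=float)
    if np.any(latent < 0):
        raise ValueError("latent sizes must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(f * latent)


def ensemble(
    eff: EffectiveParams,
    n0: int,
    times,
    n_reps: int,
    master_seed: int,
    return_values: bool = False,
) -> EnsembleSummary:
    """Replicate ensemble of the invader chain sampled on a time grid.

    Per-replicate seeds are spawned deterministically from ``master_seed``.
    Extinction fraction at each time is the fraction of replicates whose
    population is exactly zero (absorption makes it non-decreasing).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    times = np.asarray(times, dtype=float)
    seeds = spawn_seeds(master_seed, n_reps)
    out = np.empty((n_reps, len(times)), dtype=np.int64)
    _ensemble_kernel(
        eff.eff_birth, eff.death_rate, eff.max_pop, int(n0), times, seeds, out
    )
    mean = out.mean(axis=0)
    var = out.var(axis=0, ddof=1) if n_reps > 1 else np.zeros(len(times))
    return EnsembleSummary(
        times=times,
        mean=mean,
        var=var,
        extinct_fraction=(out == 0).mean(axis=0),
        n_reps=n_reps,
        values=out if return_values else None,
    )


def observe_trajectory(
    traj: EventTrajectory,
    times=None,
    f: float = DEFAULT_SEARCH_FRACTION,
    seed: int = 0,
    n0: int | None = None,
) -> ObservationSeries:
    """Sample a trajectory on a survey schedule and Poisson-thin the counts."""
    if times is None:
        times = default_observation_times()
    latent = sample_at_times(traj, times)
    counts = observe(latent, f, seed)
    return ObservationSeries(
        times=np.asarray(times, dtype=float),
        latent=np.asarray(latent, dtype=float),
        counts=counts,
        f=f,
        n0=int(traj.pops[0, 0]) if n0 is None else n0,
    )
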