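"""Model parameters, the δ noise parameterization and deterministic solutions.

The two-species competitive Lotka–Volterra model

    dn_i/dt = r_i n_i (1 - (n_i + α_ij n_j) / K_i)

is made stochastic as a birth–death process in which species ``i`` has
per-capita intrinsic birth rate λ, death rate μ, and a maximum population
size N at which births cease.  The deterministic equilibrium (carrying
capacity) is K = r N / λ with r = λ - μ, so K < N whenever μ > 0 and the
gap between K and N sets the size of demographic fluctuations.

Demographic stochasticity is controlled by a single knob δ = (λ + μ)/2:
with λ = δ + 0.5, μ = δ - 0.5 and N = 10,000 (δ + 0.5) the mean dynamics
are pinned (r = 1 day⁻¹, K = 10,000 individuals for every δ) while the
event rate — and hence the noise — grows with δ.

During the early phase of an introduction the resident community sits at
its carrying capacity K_R, and its competitive pressure is absorbed into
a modified invader birth rate

    λ̄ = λ (1 - α K_R / N),

turning the invader into a one-species stochastic logistic process with
effective growth rate r̄ = λ̄ - μ and capacity K̄ = r̄ N / λ̄.  The
deterministic fate of the invader flips at α = 1: establishment below,
extinction above.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesParams",
    "EffectiveParams",
    "CompetitionSetup",
    "DeterministicOutcome",
    "species_params_from_delta",
    "effective_params",
    "logistic_mean",
    "lv_deterministic",
    "deterministic_outcome",
]

#: Baseline used throughout: N = _N_SCALE * λ, which fixes K = _N_SCALE.
_N_SCALE = 10_000.0

DELTA_MIN = 0.5


@dataclass(frozen=True)
class SpeciesParams:
    """Intrinsic rates and sizes of one species.

    Parameters
    ----------
    birth_rate : float
        Per-capita intrinsic birth rate λ (day⁻¹), > 0.
    death_rate : float
        Per-capita intrinsic death rate μ (day⁻¹), ≥ 0.
    max_pop : float
        Maximum population size N (individuals): births cease at n = N.
    """

    birth_rate: float
    death_rate: float
    max_pop: float

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise ValueError(f"birth rate must be positive, got {self.birth_rate}")
        if self.death_rate < 0:
            raise ValueError(f"death rate must be nonnegative, got {self.death_rate}")
        if self.max_pop <= 0:
            raise ValueError(f"max population must be positive, got {self.max_pop}")

    @property
    def growth_rate(self) -> float:
        """Intrinsic growth rate r = λ - μ (day⁻¹)."""
        return self.birth_rate - self.death_rate

    @property
    def carrying_capacity(self) -> float:
        """Deterministic equilibrium K = r N / λ (individuals)."""
        return self.growth_rate * self.max_pop / self.birth_rate


@dataclass(frozen=True)
class EffectiveParams:
    """Invader rates after absorbing resident competition at density K_R.

    ``eff_birth`` is λ̄ = λ (1 - α K_R / N), clipped at zero (a birth rate
    cannot be negative); ``clipped`` records whether clipping fired.  When
    λ̄ = 0 the process is pure death and the effective carrying capacity is
    undefined (NaN).
    """

    eff_birth: float
    death_rate: float
    max_pop: float
    clipped: bool = False

    @property
    def eff_growth(self) -> float:
        """Effective growth rate r̄ = λ̄ - μ (day⁻¹)."""
        return self.eff_birth - self.death_rate

    @property
    def eff_carrying_capacity(self) -> float:
        """Effective carrying capacity K̄ = r̄ N / λ̄; NaN when λ̄ = 0."""
        if self.eff_birth == 0.0:
            return math.nan
        return self.eff_growth * self.max_pop / self.eff_birth


class DeterministicOutcome(enum.Enum):
    """Fate of the invader in the deterministic two-species model."""

    ESTABLISH = "establish"
    EXTINCT = "extinct"
    BIFURCATION = "bifurcation"


def species_params_from_delta(delta: float) -> SpeciesParams:
    """Build species parameters from the demographic-noise coefficient δ.

    λ = δ + 0.5, μ = δ - 0.5 and N = 10,000 (δ + 0.5), so that r = 1 day⁻¹
    and K = 10,000 individuals regardless of δ while the event rate (and
    hence demographic stochasticity) scales with δ.

    Parameters
    ----------
    delta : float
        Noise coefficient, ≥ 0.5 (smaller values would imply μ < 0).
    """
    if delta < DELTA_MIN:
        raise ValueError(
            f"delta must be >= {DELTA_MIN} (death rate delta - 0.5 must be "
            f"nonnegative), got {delta}"
        )
    lam = delta + 0.5
    return SpeciesParams(birth_rate=lam, death_rate=delta - 0.5, max_pop=_N_SCALE * lam)


def effective_params(
    invader: SpeciesParams, alpha: float, resident_K: float
) -> EffectiveParams:
    """Reduce the two-species competition to a one-species invader process.

    With the resident clamped at its carrying capacity ``resident_K``, the
    invader birth rate becomes λ̄ = λ (1 - α K_R / N).  For α K_R > N this
    would be negative; it is clipped to 0 and flagged.
    """
    if resident_K <= 0:
        raise ValueError(f"resident carrying capacity must be positive, got {resident_K}")
    if alpha < 0:
        raise ValueError(f"interaction strength must be nonnegative, got {alpha}")
    lam_bar = invader.birth_rate * (1.0 - alpha * resident_K / invader.max_pop)
    clipped = lam_bar < 0.0
    if clipped:
        lam_bar = 0.0
    return EffectiveParams(
        eff_birth=lam_bar,
        death_rate=invader.death_rate,
        max_pop=invader.max_pop,
        clipped=clipped,
    )


def logistic_mean(t, n0: float, r: float, K: float):
    """Solution n(t) of the logistic equation dn/dt = r n (1 - n/K).

    Evaluated in the overflow-safe form

        n(t) = n0 / (e^{-rt} (1 - n0/K) + n0/K)

    which is exact for r != 0 and decays correctly for r < 0.  At r = 0 the
    K-parameterized logistic is constant (the density-dependent term r n²/K
    vanishes with r for fixed K).  Accepts scalar or array ``t``.
    """
    if K <= 0:
        raise ValueError(f"carrying capacity must be positive, got {K}")
    if n0 < 0:
        raise ValueError(f"initial size must be nonnegative, got {n0}")
    t = np.asarray(t, dtype=float)
    if n0 == 0.0:
        out = np.zeros_like(t)
        return out if out.ndim else float(out)
    x = n0 / K
    # exponent clipped far outside the double range that matters: e^{-700}
    # underflows harmlessly, larger values would overflow to inf.
    expo = np.clip(-r * t, -700.0, 700.0)
    out = n0 / (np.exp(expo) * (1.0 - x) + x)
    return out if out.ndim else float(out)


def deterministic_outcome(alpha: float) -> DeterministicOutcome:
    """Classify the deterministic fate of the invader at interaction α.

    Establishment for α < 1, extinction for α > 1, and the structurally
    unstable bifurcation exactly at α = 1 (strict comparisons, no epsilon
    band).
    """
    if alpha < 0:
        raise ValueError(f"interaction strength must be nonnegative, got {alpha}")
    if alpha < 1.0:
        return DeterministicOutcome.ESTABLISH
    if alpha > 1.0:
        return DeterministicOutcome.EXTINCT
    return DeterministicOutcome.BIFURCATION


@dataclass(frozen=True)
class CompetitionSetup:
    """Full two-species configuration of an introduction experiment.

    Defaults are the standard simulation design: α_RI = 0.5, invader
    introduced at n₀ = 40 individuals into a resident community at its
    carrying capacity (10,000 individuals).
    """

    alpha_IR: float
    invader: SpeciesParams
    resident: SpeciesParams
    alpha_RI: float = 0.5
    n0_invader: int = 40
    n0_resident: int = 10_000

    def __post_init__(self) -> None:
        if self.alpha_IR < 0 or self.alpha_RI < 0:
            raise ValueError("interaction coefficients must be nonnegative")
        for name in ("n0_invader", "n0_resident"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @classmethod
    def from_delta(
        cls,
        delta: float,
        alpha_IR: float,
        alpha_RI: float = 0.5,
        n0_invader: int = 40,
        n0_resident: int = 10_000,
    ) -> "CompetitionSetup":
        sp = species_params_from_delta(delta)
        return cls(
            alpha_IR=alpha_IR,
            invader=sp,
            resident=sp,
            alpha_RI=alpha_RI,
            n0_invader=n0_invader,
            n0_resident=n0_resident,
        )

    def effective_invader(self) -> EffectiveParams:
        """Effective one-species invader parameters (resident at K_R)."""
        return effective_params(
            self.invader, self.alpha_IR, self.resident.carrying_capacity
        )

    def to_config(self) -> dict:
        """Flat key-value serialization (inverse of :func:`setup_from_config`)."""
        return {
            "lambda_I": self.invader.birth_rate,
            "mu_I": self.invader.death_rate,
            "N_I": self.invader.max_pop,
            "lambda_R": self.resident.birth_rate,
            "mu_R": self.resident.death_rate,
            "N_R": self.resident.max_pop,
            "alpha_IR": self.alpha_IR,
            "alpha_RI": self.alpha_RI,
            "n0_invader": self.n0_invader,
            "n0_resident": self.n0_resident,
        }


def setup_from_config(cfg: dict) -> CompetitionSetup:
    """Build a :class:`CompetitionSetup` from a flat key-value mapping.

    Accepts either the ``delta`` shorthand (plus ``alpha_IR`` etc., all
    other keys defaulted from the standard design) or the explicit
    per-species rates written by :meth:`CompetitionSetup.to_config`.
    """
    if "delta" in cfg:
        setup = CompetitionSetup.from_delta(
            float(cfg["delta"]),
            alpha_IR=float(cfg.get("alpha_IR", 0.5)),
            alpha_RI=float(cfg.get("alpha_RI", 0.5)),
            n0_invader=int(cfg.get("n0_invader", 40)),
            n0_resident=int(cfg.get("n0_resident", 10_000)),
        )
        if "K_R_override" in cfg:
            # rescale the resident's maximum population so its carrying
            # capacity K = rN/lambda equals the requested value
            KR = float(cfg["K_R_override"])
            res = setup.resident
            new_res = SpeciesParams(
                birth_rate=res.birth_rate,
                death_rate=res.death_rate,
                max_pop=KR * res.birth_rate / res.growth_rate,
            )
            setup = CompetitionSetup(
                alpha_IR=setup.alpha_IR,
                invader=setup.invader,
                resident=new_res,
                alpha_RI=setup.alpha_RI,
                n0_invader=setup.n0_invader,
                n0_resident=setup.n0_resident,
            )
        return setup
    inv = SpeciesParams(float(cfg["lambda_I"]), float(cfg["mu_I"]), float(cfg["N_I"]))
    res = SpeciesParams(float(cfg["lambda_R"]), float(cfg["mu_R"]), float(cfg["N_R"]))
    return CompetitionSetup(
        alpha_IR=float(cfg["alpha_IR"]),
        invader=inv,
        resident=res,
        alpha_RI=float(cfg.get("alpha_RI", 0.5)),
        n0_invader=int(cfg.get("n0_invader", 40)),
        n0_resident=int(cfg.get("n0_resident", 10_000)),
    )


def lv_deterministic(setup: CompetitionSetup, t_grid) -> "pandas.DataFrame":  # noqa: F821
    """Integrate the deterministic two-species Lotka–Volterra competition ODE.

    Returns a DataFrame with columns ``t``, ``n_I``, ``n_R`` on the
    requested time grid, integrated with tight tolerances (rtol 1e-10).
    Extinction (n = 0) is absorbing by construction of the equations.
    """
    import pandas as pd

    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] != 0.0:
        raise ValueError("t_grid must be strictly increasing and start at 0")

    rI = setup.invader.growth_rate
    KI = setup.invader.carrying_capacity
    rR = setup.resident.growth_rate
    KR = setup.resident.carrying_capacity
    aIR, aRI = setup.alpha_IR, setup.alpha_RI

    def rhs(_t, y):
        nI, nR = y
        return (
            rI * nI * (1.0 - (nI + aIR * nR) / KI),
            rR * nR * (1.0 - (nR + aRI * nI) / KR),
        )

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [float(setup.n0_invader), float(setup.n0_resident)],
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-10,
        atol=1e-8,
    )
    if not sol.success:
        raise RuntimeError(f"Lotka-Volterra integration failed: {sol.message}")
    nI = np.clip(sol.y[0], 0.0, None)
    nR = np.clip(sol.y[1], 0.0, None)
    return pd.DataFrame({"t": t_grid, "n_I": nI, "n_R": nR})
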