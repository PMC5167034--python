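"""Model/Results interface for establishment inference.

`EstablishmentModel` bundles an observation series with a prior
specification; `fit()` runs the Metropolis–Hastings sampler and returns
an `EstablishmentResults` carrying the posterior draws, their summaries
and diagnostics, in the spirit of statsmodels' model/results pairs::

    model = EstablishmentModel(obs, scenario="all_fixed", delta=1.75)
    res = model.fit(seed=1)
    print(res.summary())
    res.predictive_ability(true_alpha=0.8)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gillespie import ObservationSeries
from .likelihood import InferenceParams
from .mcmc import (
    DEFAULT_N_BURN,
    DEFAULT_N_ITER,
    DEFAULT_THIN,
    PosteriorSample,
    PriorSpec,
    Scenario,
    build_priors,
    mh_sample,
    posterior_summary,
)
from .params import species_params_from_delta

__all__ = ["EstablishmentModel", "EstablishmentResults"]


class EstablishmentModel:
    """Bayesian establishment model for one introduction time series.

    Parameters
    ----------
    obs : ObservationSeries
        Poisson-thinned counts at the survey times, with search fraction f
        and known introduction size n₀.
    scenario : Scenario or str
        Degree of prior knowledge of the single-species parameters.
    sigma : float
        Log-scale width of the lognormal priors (ignored for ALL_FIXED).
    delta : float, optional
        Shorthand anchoring the single-species parameters at the standard
        δ-parameterization truth (resident K_R = 10,000).
    anchors : InferenceParams, optional
        Explicit anchor values; overrides ``delta``.
    """

    def __init__(
        self,
        obs: ObservationSeries,
        scenario: Scenario | str = Scenario.ALL_FIXED,
        sigma: float = 0.3,
        delta: float | None = None,
        anchors: InferenceParams | None = None,
    ):
        if anchors is None:
            if delta is None:
                raise ValueError("provide either delta or explicit anchors")
            sp = species_params_from_delta(delta)
            anchors = InferenceParams.from_truth(sp, resident_K=10_000.0, alpha=1.0)
        self.obs = obs
        self.priors: PriorSpec = build_priors(scenario, sigma, anchors)

    @classmethod
    def from_dataframe(
        cls,
        df,
        f: float = 0.25,
        n0: int = 40,
        time_col: str = "time",
        count_col: str = "observed_count",
        **kwargs,
    ) -> "EstablishmentModel":
        """Build from a DataFrame with observation times and counts."""
        obs = ObservationSeries(
            times=np.asarray(df[time_col], dtype=float),
            latent=np.full(len(df), np.nan),
            counts=np.asarray(df[count_col], dtype=int),
            f=f,
            n0=n0,
        )
        return cls(obs, **kwargs)

    def fit(
        self,
        n_iter: int = DEFAULT_N_ITER,
        n_burn: int = DEFAULT_N_BURN,
        thin: int = DEFAULT_THIN,
        seed: int = 0,
        init: InferenceParams | None = None,
    ) -> "EstablishmentResults":
        sample = mh_sample(
            self.obs, self.priors, init=init,
            n_iter=n_iter, n_burn=n_burn, thin=thin, seed=seed,
        )
        return EstablishmentResults(self, sample)


@dataclass
class EstablishmentResults:
    """Posterior estimates, uncertainties and diagnostics of one fit."""

    model: EstablishmentModel
    sample: PosteriorSample

    def __post_init__(self) -> None:
        self._summary = posterior_summary(self.sample)

    @property
    def mean_alpha(self) -> float:
        return self._summary["mean_alpha"]

    @property
    def se_alpha(self) -> float:
        return self._summary["se_alpha"]

    @property
    def ci95(self) -> tuple[float, float]:
        return self._summary["ci95"]

    @property
    def mass_below_1(self) -> float:
        return self._summary["mass_below_1"]

    @property
    def mass_above_1(self) -> float:
        return self._summary["mass_above_1"]

    def predictive_ability(self, true_alpha: float) -> float:
        """Posterior mass of α on the same side of the bifurcation as truth."""
        from .metrics import predictive_ability

        return predictive_ability(self.sample, true_alpha)

    def summary(self) -> str:
        s = self._summary
        sam = self.sample
        lines = [
            "Establishment inference (Metropolis-Hastings)",
            "=" * 46,
            f"scenario:          {sam.scenario.value}",
            f"prior width sigma: {sam.sigma:g}",
            f"draws:             {sam.n_draws} "
            f"(iter {sam.n_iter}, burn {sam.n_burn}, thin {sam.thin})",
            f"ESS(alpha):        {s['ess_alpha']:.0f}",
            "-" * 46,
            f"alpha mean (SE):   {s['mean_alpha']:.3f} ({s['se_alpha']:.3f})",
            f"alpha 95% CI:      [{s['ci95'][0]:.3f}, {s['ci95'][1]:.3f}]",
            f"P(alpha < 1):      {s['mass_below_1']:.3f}",
            f"P(alpha > 1):      {s['mass_above_1']:.3f}",
            "-" * 46,
            "acceptance: "
            + ", ".join(
                f"{k}={v:.2f}" for k, v in sam.acceptance.items() if np.isfinite(v)
            ),
        ]
        return "\n".join(lines)

    def plot_posterior(self, ax=None, bins: int = 40):
        """Histogram of the α posterior with the bifurcation line at α = 1."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.sample.alpha, bins=bins, density=True, alpha=0.7)
        ax.axvline(1.0, color="k", ls="--", label="bifurcation")
        ax.set_xlabel(r"interaction strength $\alpha$")
        ax.set_ylabel("posterior density")
        ax.legend()
        return ax
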