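"""Configuration, file I/O and scripted experiment drivers.

Everything is plain text: long-format CSV for trajectories and maps,
flat YAML for configuration, JSON for scalar summaries and the run
manifest.  A single master seed is split into named substreams (one per
pipeline stage) so any stage can be re-run independently and every
stochastic output is bit-reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gillespie import (
    ObservationSeries,
    default_observation_times,
    ensemble,
)
from .metrics import (
    GridSpec,
    mean_predictive_ability,
    precision_accuracy,
    predictability_map,
    replicate_posteriors,
)
from .params import CompetitionSetup

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "run_experiment",
    "read_observations",
    "write_observations",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"  # 10 significant digits in all CSV output


@dataclass
class ExperimentConfig:
    """Complete, serializable description of one experiment run.

    Defaults reproduce the standard study design: introduction of n₀ = 40
    individuals into a resident community at K_R = 10,000, ten equally
    spaced observations over the first 4 days with search fraction 0.25.
    """

    experiment: str = "figure1"
    delta: float = 1.0
    alpha: float = 0.5
    alpha_RI: float = 0.5
    n0_invader: int = 40
    n0_resident: int = 10_000
    t_end: float = 4.0
    d: int = 10
    f: float = 0.25
    scenario: str = "all_fixed"
    sigma: float = 0.3
    n_reps: int = 100
    n_realizations: int = 30
    n_iter: int = 20_000
    n_burn: int = 8_000
    thin: int = 5
    master_seed: int = 0
    out_dir: str = "results"
    # grid experiments
    alphas: list = field(default_factory=lambda: [0.5, 1.0, 1.5])
    deltas: list = field(default_factory=lambda: [1.0, 4.0])
    sigmas: list = field(default_factory=lambda: [0.01, 0.1, 0.3, 1.0])
    times: list = field(default_factory=lambda: [4.0])

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Named substream seed derived from the master seed."""
        h = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little")


@dataclass
class RunManifest:
    """Record of one run: config snapshot, seeds, timings, output checksums."""

    config: dict
    status: str = "running"
    stage_seeds: dict = field(default_factory=dict)
    stage_runtimes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add_output(self, path) -> None:
        p = Path(path)
        self.outputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def write_observations(series: ObservationSeries, path) -> None:
    """CSV with header time,observed_count[,latent_count]; f/n0 in sidecar JSON."""
    path = Path(path)
    df = pd.DataFrame({"time": series.times, "observed_count": series.counts})
    if np.all(np.isfinite(series.latent)):
        df["latent_count"] = series.latent
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"f": series.f, "n0": series.n0}))


def read_observations(path) -> ObservationSeries:
    """Inverse of :func:`write_observations`; validates monotone times."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time", "observed_count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    # file line numbers: header is line 1, first data row line 2
    bad = np.flatnonzero(~np.isfinite(df["time"].to_numpy(dtype=float)))
    if len(bad):
        raise ValueError(f"{path}: malformed time at line {bad[0] + 2}")
    t = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise ValueError(f"{path}: observation times not increasing at line {i}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    latent = (
        df["latent_count"].to_numpy(dtype=float)
        if "latent_count" in df.columns
        else np.full(len(df), np.nan)
    )
    return ObservationSeries(
        times=t,
        latent=latent,
        counts=df["observed_count"].to_numpy(dtype=int),
        f=float(meta.get("f", 0.25)),
        n0=int(meta.get("n0", 40)),
    )


def _run_figure1(cfg: ExperimentConfig, out: Path, manifest: RunManifest) -> None:
    """Replicate ensembles at each (δ, α): per-time mean/var/extinction CSVs."""
    seed = cfg.stage_seed("simulation")
    manifest.stage_seeds["simulation"] = seed
    times = np.linspace(0.0, cfg.t_end, max(int(cfg.t_end * 10), 2))
    rows = []
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(len(cfg.deltas) * len(cfg.alphas))
    k = 0
    for delta in cfg.deltas:
        for alpha in cfg.alphas:
            setup = CompetitionSetup.from_delta(
                delta, alpha_IR=alpha, n0_invader=cfg.n0_invader
            )
            summ = ensemble(
                setup.effective_invader(), cfg.n0_invader, times, cfg.n_reps,
                master_seed=int(sub[k]),
            )
            k += 1
            for i, t in enumerate(times):
                rows.append(
                    {
                        "delta": delta, "alpha": alpha, "t": t,
                        "mean": summ.mean[i], "var": summ.var[i],
                        "extinct_fraction": summ.extinct_fraction[i],
                        "n_reps": cfg.n_reps,
                    }
                )
    p = out / "ensembles.csv"
    pd.DataFrame(rows).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add_output(p)


def _run_predictability_map(cfg: ExperimentConfig, out: Path, manifest: RunManifest) -> None:
    seed = cfg.stage_seed("metrics")
    manifest.stage_seeds["metrics"] = seed
    grid = GridSpec(
        alphas=np.asarray(cfg.alphas, dtype=float),
        deltas=np.asarray(cfg.deltas, dtype=float),
        n_reps_predictability=cfg.n_reps,
    )
    frames = []
    for t in cfg.times:
        m = predictability_map(grid, seed=seed, t=t)
        df = m.to_frame()
        df["n_reps"] = cfg.n_reps
        df["seed"] = seed
        frames.append(df)
    p = out / "predictability_map.csv"
    pd.concat(frames).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add_output(p)


def _run_predictive_pixel(cfg: ExperimentConfig, out: Path, manifest: RunManifest) -> None:
    """Mean predictive ability at a single (α, δ) pixel."""
    seed = cfg.stage_seed("inference")
    manifest.stage_seeds["inference"] = seed
    value = mean_predictive_ability(
        cfg.alpha, cfg.delta, cfg.scenario, cfg.sigma,
        n_realizations=cfg.n_realizations, seed=seed,
        d=cfg.d, t_end=cfg.t_end, f=cfg.f,
        n_iter=cfg.n_iter, n_burn=cfg.n_burn, thin=cfg.thin,
    )
    p = out / "predictive_ability.json"
    p.write_text(
        json.dumps(
            {
                "alpha": cfg.alpha, "delta": cfg.delta, "scenario": cfg.scenario,
                "sigma": cfg.sigma, "n_realizations": cfg.n_realizations,
                "mean_predictive_ability": value,
            },
            indent=2,
        )
    )
    manifest.add_output(p)


def _run_precision_sweep(cfg: ExperimentConfig, out: Path, manifest: RunManifest) -> None:
    """Precision/accuracy of α across prior widths for one scenario."""
    seed = cfg.stage_seed("inference")
    manifest.stage_seeds["inference"] = seed
    rows = []
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(len(cfg.sigmas))
    for s, sub_seed in zip(cfg.sigmas, sub):
        posts = replicate_posteriors(
            cfg.alpha, cfg.delta, cfg.scenario, s,
            n_realizations=cfg.n_realizations, seed=int(sub_seed),
            d=cfg.d, t_end=cfg.t_end, f=cfg.f,
            n_iter=cfg.n_iter, n_burn=cfg.n_burn, thin=cfg.thin,
        )
        se, err = precision_accuracy(posts, cfg.alpha)
        rows.append(
            {
                "sigma": s, "alpha": cfg.alpha, "delta": cfg.delta,
                "scenario": cfg.scenario, "precision_se": se,
                "log10_precision": np.log10(se) if se > 0 else -np.inf,
                "accuracy_abs_error": err, "n_realizations": cfg.n_realizations,
                "seed": int(sub_seed),
            }
        )
    p = out / "precision_sweep.csv"
    pd.DataFrame(rows).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add_output(p)


_EXPERIMENTS = {
    "figure1": _run_figure1,
    "predictability_map": _run_predictability_map,
    "predictive_pixel": _run_predictive_pixel,
    "precision_sweep": _run_precision_sweep,
}


def run_experiment(cfg: ExperimentConfig) -> RunManifest:
    """Run a named experiment end to end, writing outputs and a manifest."""
    if cfg.experiment not in _EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; "
            f"choose from {sorted(_EXPERIMENTS)}"
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg))
    manifest_path = out / "manifest.json"
    t0 = _time.perf_counter()
    try:
        logger.info("running experiment %s", cfg.experiment)
        _EXPERIMENTS[cfg.experiment](cfg, out, manifest)
        manifest.status = "ok"
    except Exception:
        manifest.status = "failed"
        manifest.write(manifest_path)
        raise
    finally:
        manifest.stage_runtimes[cfg.experiment] = _time.perf_counter() - t0
    cfg_path = out / "config.yaml"
    cfg.to_yaml(cfg_path)
    manifest.add_output(cfg_path)
    manifest.write(manifest_path)
    return manifest
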