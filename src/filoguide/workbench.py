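"""Experiment drivers, configuration and fixture generation.

The drivers reproduce the in-silico experiments end-to-end: cohorts of
independent neurites on a period-1 nanograting scored for alignment and
tortuosity over time, the swallowtail beam-splitting assay, the analytic
model fit, and the FE interface-stress sweep.  Every run writes a manifest
(config snapshot + seed + version) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grating import Grating
from .guidance import GuidanceParams, fit_epsilon, mean_beta
from .metrics import alignment_angle, angular_histogram, tortuosity
from .simulate import (SimParams, TurningRule, _advance, _spawn_neurite,
                       neurite_rngs, simulate_swallowtail)

__all__ = ["ExperimentConfig", "load_config", "save_config", "run_cohort",
           "run_experiment", "generate_fixtures", "PERIOD1"]

#: The reference period-1 nanograting: 500 nm ridges and grooves, 250 nm deep.
PERIOD1 = Grating(ridge_width=0.5, groove_width=0.5, ridge_depth=0.25)

EXPERIMENTS = ("period1_alignment", "tortuosity", "swallowtail",
               "alignment_fit", "fe_sweep")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun one experiment deterministically."""

    experiment: str = "period1_alignment"
    n: int = 61
    duration_h: float = 60.0
    observation_times_h: tuple[float, ...] = (6, 12, 18, 24, 30, 36, 42, 48,
                                              54, 60)
    seed: int = 0
    ridge_width_nm: float = 500.0
    groove_width_nm: float = 500.0
    ridge_depth_nm: float = 250.0
    phi_deg: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)
    output_dir: str = "results"
    sim: dict = field(default_factory=dict)        # SimParams overrides
    guidance: dict = field(default_factory=dict)   # GuidanceParams overrides
    fe: dict = field(default_factory=dict)         # sweep settings

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"expected one of {EXPERIMENTS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def grating(self) -> Grating:
        return Grating(self.ridge_width_nm / 1000.0,
                       self.groove_width_nm / 1000.0,
                       self.ridge_depth_nm / 1000.0)

    def sim_params(self) -> SimParams:
        guidance = GuidanceParams(**self.guidance) if self.guidance \
            else GuidanceParams()
        return replace(SimParams(guidance=guidance, seed=self.seed),
                       **self.sim)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("observation_times_h", "phi_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path) -> ExperimentConfig:
    """Read an experiment config from TOML (preferred) or YAML."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return ExperimentConfig.from_dict(data)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def run_cohort(n: int, surface, params: SimParams, duration: float,
               observation_times=(), soma_span_periods: int = 200
               ) -> tuple[pd.DataFrame, list]:
    """Grow ``n`` independent neurites and score them at sample times.

    Somata are scattered laterally over many grating periods (the lateral
    registration of cells to the pattern is random), one independent RNG
    stream per neurite plus one for placement.  Returns the per-time
    metrics table (neurite_id, t_h, tortuosity, alignment_deg) and the
    final neurites.
    """
    rngs = neurite_rngs(params.seed, n + 1)
    placer, rngs = rngs[0], rngs[1:]
    grating = surface if isinstance(surface, Grating) else surface.trunk
    span = soma_span_periods * grating.period
    axis = grating.main_direction
    neurites = []
    for i, rng in enumerate(rngs):
        soma = np.array([0.0, 0.0]) + grating.across_direction * \
            float(placer.uniform(-span / 2, span / 2)) + axis * (20.0 * i)
        neurites.append(_spawn_neurite(tuple(soma), surface, params, rng))
    obs = sorted(set(observation_times) | {duration})
    rows = []
    n_steps = round(duration / params.dt)
    next_obs = 0
    for k in range(1, n_steps + 1):
        for neu in neurites:
            _advance(neu, surface, params)
        t = k * params.dt
        while next_obs < len(obs) and obs[next_obs] <= t + 1e-9:
            for i, neu in enumerate(neurites):
                pts = neu.path_points()
                rows.append((i, obs[next_obs], tortuosity(pts),
                             alignment_angle(pts, axis)))
            next_obs += 1
    table = pd.DataFrame(rows, columns=["neurite_id", "t_h", "tortuosity",
                                        "alignment_deg"])
    return table, neurites


def _summary_alignment(table: pd.DataFrame, duration: float) -> dict:
    final = table[np.isclose(table["t_h"], duration)]
    angles = final["alignment_deg"].to_numpy()
    hist = angular_histogram(angles, 10.0)
    per_time = (table.groupby("t_h")["alignment_deg"]
                .agg(["mean", "std", "count"]).reset_index())
    return {
        "n": int(final["neurite_id"].nunique()),
        "alignment_mean_deg": float(angles.mean()),
        "alignment_sd_deg": float(angles.std(ddof=1)),
        "histogram_10deg_bins_pct": [float(x) for x in hist],
        "fraction_within_10deg_pct": float(100.0 * (angles < 10.0).mean()),
        "fraction_within_20deg_pct": float(100.0 * (angles < 20.0).mean()),
        "alignment_time_course": per_time.to_dict(orient="list"),
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one named experiment; write outputs + manifest; return summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.sim_params()
    summary: dict = {"experiment": config.experiment, "seed": config.seed}

    if config.experiment in ("period1_alignment", "tortuosity"):
        duration = config.duration_h
        table, _ = run_cohort(config.n, config.grating, params, duration,
                              config.observation_times_h)
        table.to_csv(out / "metrics.csv", index=False)
        if config.experiment == "period1_alignment":
            summary.update(_summary_alignment(table, duration))
        final = table[np.isclose(table["t_h"], duration)]
        tor = final["tortuosity"].to_numpy()
        summary.update({
            "n": int(len(tor)),
            "tortuosity_mean": float(tor.mean()),
            "tortuosity_sd": float(tor.std(ddof=1)),
        })
    elif config.experiment == "swallowtail":
        fractions = {}
        for phi in config.phi_deg:
            res = simulate_swallowtail(config.n, phi, params,
                                       duration=config.duration_h)
            fractions[phi] = {
                "turning_fraction_pct": 100.0 * res.turning_fraction,
                "n_reached": res["n_reached"],
            }
        summary["turning"] = fractions
    elif config.experiment == "alignment_fit":
        obs_file = out / "alignment_observations.csv"
        if not obs_file.exists():
            generate_fixtures("alignment_observations",
                              {"epsilon": GuidanceParams().epsilon},
                              config.seed, out)
        df = pd.read_csv(obs_file)
        fit = fit_epsilon(np.column_stack([
            df["ridge_width_nm"] / 1000.0, df["ridge_depth_nm"] / 1000.0,
            df["mean_beta_deg"]]))
        summary.update({"epsilon": fit.epsilon, "r_squared": fit.r_squared,
                        "sse_deg2": fit.sse})
    elif config.experiment == "fe_sweep":
        from .fe import sweep_surface
        lengths = config.fe.get("lengths_frac", [0.001, 0.1, 0.5, 1.0, 2.0])
        orients = config.fe.get("orientations_deg", [-10.0, 0.0, 10.0])
        table = sweep_surface(lengths, orients,
                              target_edge=config.fe.get("target_edge", 0.06))
        table.to_csv(out / "fe_sweep.csv", index=False)
        summary["n_solves"] = int(len(table))

    manifest = {"version": __version__, "config": config.to_dict()}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def generate_fixtures(kind: str, params: dict, seed: int, out_dir) -> Path:
    """Synthetic datasets for tests and worked examples.

    ``alignment_observations``: (ridge width, depth, mean alignment) rows
    generated from the analytic model at a known epsilon, optionally with
    Gaussian noise, for fit-recovery checks.  ``trajectories``: canonical
    paths (straight, right angle, semicircle) with known metric values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "alignment_observations":
        eps = params.get("epsilon", GuidanceParams().epsilon)
        noise = params.get("noise_sd_deg", 0.0)
        gp = GuidanceParams(epsilon=eps)
        rows = []
        for rw_nm in params.get("ridge_widths_nm", (500, 1000, 1500, 2000)):
            for rd_nm in params.get("ridge_depths_nm", (250, 350)):
                beta = mean_beta(Grating(rw_nm / 1e3, 0.5, rd_nm / 1e3), gp)
                beta = float(np.clip(beta + rng.normal(0.0, noise)
                                     if noise else beta, 1e-6, 90 - 1e-6))
                rows.append((rw_nm, rd_nm, beta))
        df = pd.DataFrame(rows, columns=["ridge_width_nm", "ridge_depth_nm",
                                         "mean_beta_deg"])
        path = out / "alignment_observations.csv"
        df.to_csv(path, index=False)
        return path
    if kind == "trajectories":
        t = np.linspace(0.0, np.pi, 73)
        paths = {
            "straight": np.column_stack([np.linspace(0, 10, 11),
                                         np.zeros(11)]),
            "right_angle": np.array([[0, 0], [1, 0], [1, 1]], dtype=float),
            "semicircle": np.column_stack([np.cos(np.pi - t), np.sin(t)]),
        }
        for name, pts in paths.items():
            pd.DataFrame(pts, columns=["x_um", "y_um"]).to_csv(
                out / f"trajectory_{name}.csv", index=False)
        return out
    raise ValueError(f"unknown fixture kind {kind!r}")
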