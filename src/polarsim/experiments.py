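"""Config-driven reproduction of the package's simulation experiments.

Every study condition is a registered, one-command experiment returning
a long-format :class:`pandas.DataFrame` (columns: experiment,
condition, replicate, seed, metric, value) plus the config hash that
reproduces it.  The registry covers the generic-model noise panels
(``fig1B``, ``fig1E``, ``fig2B``), the settling-time architecture
comparison (``fig3AB``), and the yeast Monte Carlo panels (``fig3C``,
``fig4A``, ``fig5A``); ``snr_sweep`` exposes the generic (sigma x
slope) cross-product driver.

Experiment identifiers follow the figure panels of the underlying
study; full-scale defaults (k_x = 200, 20-40 replicates) can be scaled
down for desk runs via :class:`ExperimentConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import GridKind, make_grid
from .inputs import BatchedInputProcess, GradientSpec, NoiseSpec
from .generic import make_preset, simulate_generic
from .yeast import YeastParams, apply_mutant, scale_gprotein_speed, simulate_yeast
from . import metrics as M

_REGISTRY: dict[str, Callable] = {}


def register(name: str):
    def deco(fn):
        _REGISTRY[name] = fn
        return fn
    return deco


def list_experiments() -> list[str]:
    return sorted(_REGISTRY)


@dataclass(frozen=True)
class ExperimentConfig:
    """Run parameters shared by all registered experiments.

    ``n_reps`` and ``grid_n`` default to desk-scale values; the
    full-scale study conditions are ``grid_n=200`` for 1-D stationary
    statistics and 20-40 replicates for Monte Carlo panels.
    """

    experiment: str
    seed: int = 0
    n_reps: int = 5
    grid_n: int = 200
    yeast_grid_n: int = 60
    dt: float = 0.01
    overrides: dict = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(
            {"experiment": self.experiment, "seed": self.seed,
             "n_reps": self.n_reps, "grid_n": self.grid_n,
             "yeast_grid_n": self.yeast_grid_n, "dt": self.dt,
             "overrides": {k: repr(v) for k, v in sorted(self.overrides.items())}},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute a registered experiment and return its results table."""
    try:
        fn = _REGISTRY[config.experiment]
    except KeyError:
        raise ValueError(f"unknown experiment {config.experiment!r}; "
                         f"known: {list_experiments()}")
    rows = fn(config)
    table = pd.DataFrame(rows)
    table.insert(0, "experiment", config.experiment)
    table["config_hash"] = config.hash()
    return table


def summarize(table: pd.DataFrame) -> dict:
    """Mean +- SEM per (condition, metric) from a long results table."""
    out = {}
    for (cond, metric), grp in table.groupby(["condition", "metric"]):
        v = grp["value"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        s = M.MonteCarloSummary(v, seeds=list(grp["seed"]))
        out[f"{cond}/{metric}"] = {"mean": s.mean, "sem": s.sem,
                                   "n": s.n_replicates}
    return out


# ---------------------------------------------------------------------------
# generic-model experiments
# ---------------------------------------------------------------------------

def _npf_stationary(config, sigma, L_slp, L_mid=1.0, preset="NPF",
                    t_end=100.0, burn_in=50.0):
    """Batched stationary run; returns per-replicate (a_f, sigma_out)."""
    grid = make_grid(GridKind.AXISYMMETRIC_SPHERE, config.grid_n, 2.0)
    dist = "lognormal" if sigma > 1.0 else "normal"
    seeds = [config.seed + i for i in range(config.n_reps)]
    proc = BatchedInputProcess(GradientSpec(L_mid, L_slp),
                               NoiseSpec(sigma=sigma, distribution=dist,
                                         noise_dt=config.dt),
                               grid, seeds=seeds)
    model = make_preset(preset)
    traj = simulate_generic(model, proc, t_end=t_end, dt=config.dt,
                            burn_in=burn_in, record_scalars_only=True)
    stage = traj.metadata["n_stages"]
    mean, std = M.stationary_stats(traj, f"af{stage}", window_s=t_end)
    return seeds, np.atleast_1d(mean), np.atleast_1d(std)


@register("fig1B")
def _fig1B(config: ExperimentConfig):
    """Extent of NPF polarization vs noise sigma (L_slp = 0.1 /um)."""
    rows = []
    for sigma in config.overrides.get("sigmas", (0.0, 0.01, 0.1, 1.0)):
        seeds, af, _ = _npf_stationary(config, sigma, L_slp=0.1)
        for s, v in zip(seeds, af):
            rows.append(dict(condition=f"sigma={sigma}", replicate=s - config.seed,
                             seed=s, metric="a_f", value=float(v)))
    return rows


@register("fig1_output_noise")
def _fig1_noise(config: ExperimentConfig):
    """Output noise sigma_out of the NPF model vs input sigma."""
    rows = []
    for sigma in config.overrides.get("sigmas", (0.01, 0.1, 1.0, 10.0)):
        seeds, af, std = _npf_stationary(config, sigma, L_slp=0.1)
        for s, v, so in zip(seeds, af, std):
            rows.append(dict(condition=f"sigma={sigma}", replicate=s - config.seed,
                             seed=s, metric="sigma_out", value=float(so)))
            rows.append(dict(condition=f"sigma={sigma}", replicate=s - config.seed,
                             seed=s, metric="a_f", value=float(v)))
    return rows


@register("snr_sweep")
def _snr_sweep(config: ExperimentConfig):
    """NPF polarization over a (L_slp x sigma) grid — SNR collapse."""
    slopes = config.overrides.get("slopes", (0.02, 0.05, 0.1))
    sigmas = config.overrides.get("sigmas", (0.2, 0.5, 1.0))
    rows = []
    for L_slp in slopes:
        for sigma in sigmas:
            seeds, af, _ = _npf_stationary(config, sigma, L_slp=L_slp)
            cond = f"L_slp={L_slp},sigma={sigma}"
            for s, v in zip(seeds, af):
                rows.append(dict(condition=cond, replicate=s - config.seed,
                                 seed=s, metric="a_f", value=float(v)))
                rows.append(dict(condition=cond, replicate=s - config.seed,
                                 seed=s, metric="snr", value=L_slp / sigma))
    return rows


@register("fig2B")
def _fig2B(config: ExperimentConfig):
    """One- vs two-stage architectures under noise (sigma=0.1, slope 0.01)."""
    rows = []
    sigma = config.overrides.get("sigma", 0.1)
    for preset in ("NPF", "NPF+NPF", "PF", "NPF+PF"):
        seeds, af, _ = _npf_stationary(config, sigma, L_slp=0.01,
                                       preset=preset, t_end=100.0, burn_in=150.0)
        for s, v in zip(seeds, af):
            rows.append(dict(condition=preset, replicate=s - config.seed,
                             seed=s, metric="a_f", value=float(v)))
    return rows


@register("fig3AB")
def _fig3AB(config: ExperimentConfig):
    """Noise-free settling time t_s per model architecture."""
    grid = make_grid(GridKind.AXISYMMETRIC_SPHERE, config.grid_n, 2.0)
    gradient = GradientSpec(L_mid=1.0, L_slp=0.01)
    presets = config.overrides.get(
        "presets", ("NPF", "PF", "NPF+NPF", "NPF+PF"))
    rows = []
    for preset in presets:
        res = M.settling_time(make_preset(preset), gradient, grid=grid,
                              dt=config.dt)
        for metric, value in (("t_s", res.t_s), ("t_initial", res.t_initial),
                              ("t_switch", res.t_switch),
                              ("a_f_steady", res.a_f_steady)):
            rows.append(dict(condition=preset, replicate=0, seed=config.seed,
                             metric=metric, value=float(value)))
    return rows


# ---------------------------------------------------------------------------
# yeast-model experiments
# ---------------------------------------------------------------------------

#: Monte Carlo protocol lengths (s): noise is on from t=0 (the direction
#: is decided during noisy establishment); the direction is read from
#: the time-averaged active-Cdc42 field over the final window.
MC_T_END = 600.0
MC_WINDOW = 300.0


def yeast_direction_mc(params: YeastParams, L_slp: float, sigma: float,
                       n_reps: int, seed: int, grid_n: int = 60,
                       L_mid: float = 10.0, dt: float = 0.01,
                       t_end: float = MC_T_END,
                       window: float = MC_WINDOW) -> tuple[list[int], np.ndarray]:
    """Replicate cos(theta) of the yeast model under a noisy gradient.

    Returns ``(seeds, cos_theta_values)``; replicates that never
    polarize (no detectable anisotropy) yield ``nan``.
    """
    grid = make_grid(GridKind.CIRCLE, grid_n, 2.0)
    seeds = [seed + i for i in range(n_reps)]
    proc = BatchedInputProcess(GradientSpec(L_mid, L_slp),
                               NoiseSpec(sigma=sigma, noise_dt=dt),
                               grid, seeds=seeds)
    traj = simulate_yeast(params, proc, t_end=t_end, dt=dt, burn_in=0.0,
                          record_every=int(round(10.0 / dt)))
    c42a = traj.species["C42a"]
    t_mask = traj.times >= t_end - window
    mean_field = c42a[t_mask].mean(axis=0)  # (n_reps, n)
    theta = M.polarization_direction(mean_field, grid)
    return seeds, M.directional_accuracy(theta, 0.0)


@register("fig3C")
def _fig3C(config: ExperimentConfig):
    """Directional accuracy vs G-protein cycle speed (sigma=1, 0.1%/um)."""
    base = config.overrides.get("params", YeastParams())
    rows = []
    for factor, cond in ((10.0, "fast"), (1.0, "normal"), (0.1, "slow")):
        params = scale_gprotein_speed(base, factor)
        seeds, cos = yeast_direction_mc(params, L_slp=0.01, sigma=1.0,
                                        n_reps=config.n_reps, seed=config.seed,
                                        grid_n=config.yeast_grid_n, dt=config.dt)
        for s, v in zip(seeds, cos):
            rows.append(dict(condition=cond, replicate=s - config.seed,
                             seed=s, metric="cos_theta", value=float(v)))
    return rows


@register("fig5A")
def _fig5A(config: ExperimentConfig):
    """Directional accuracy vs gradient slope (sigma=3, L_mid=10 nM)."""
    base = config.overrides.get("params", YeastParams())
    rows = []
    for L_slp in config.overrides.get("slopes", (0.1, 0.01, 0.001)):
        seeds, cos = yeast_direction_mc(base, L_slp=L_slp, sigma=3.0,
                                        n_reps=config.n_reps, seed=config.seed,
                                        grid_n=config.yeast_grid_n, dt=config.dt)
        for s, v in zip(seeds, cos):
            rows.append(dict(condition=f"L_slp={L_slp}", replicate=s - config.seed,
                             seed=s, metric="cos_theta", value=float(v)))
    return rows


@register("fig4A")
def _fig4A(config: ExperimentConfig):
    """Mutant phenotypes under uniform pheromone with noise (sigma=3).

    Each genotype is run with noise from the start; after an
    establishment phase the final 10 minutes are scored for peak
    number, polarization ratio (max/mean of active Cdc42), mean level
    and peak drift.
    """
    base = config.overrides.get("params", YeastParams())
    grid = make_grid(GridKind.CIRCLE, config.yeast_grid_n, 2.0)
    establish = config.overrides.get("establish_s", 600.0)
    observe = config.overrides.get("observe_s", 600.0)
    rows = []
    for mutant in ("wild_type", "bem1_delta", "bni1_delta"):
        params = apply_mutant(base, mutant)
        seeds = [config.seed + i for i in range(config.n_reps)]
        proc = BatchedInputProcess(GradientSpec(10.0, 0.0),
                                   NoiseSpec(sigma=3.0, noise_dt=config.dt),
                                   grid, seeds=seeds)
        traj = simulate_yeast(params, proc, t_end=establish + observe,
                              dt=config.dt, burn_in=0.0,
                              record_every=int(round(10.0 / config.dt)))
        c42a = traj.species["C42a"]
        i0 = int(np.searchsorted(traj.times, establish))
        start, end = c42a[i0], c42a[-1]
        for b, s in enumerate(seeds):
            ratio = end[b].max() / max(end[b].mean(), 1e-12)
            n_pk = M.count_peaks(end[b], grid)
            try:
                th0 = M.polarization_direction(start[b], grid)
                th1 = M.polarization_direction(end[b], grid)
                drift = abs(float(np.angle(np.exp(1j * (th1 - th0)))))
            except M.UndefinedDirectionError:
                drift = np.nan
            for metric, value in (("ratio", ratio), ("n_peaks", n_pk),
                                  ("drift_rad", drift),
                                  ("c42a_mean", end[b].mean())):
                rows.append(dict(condition=mutant, replicate=b, seed=s,
                                 metric=metric, value=float(value)))
    return rows


def sweep(parameter_grid: dict[str, Sequence], base: ExperimentConfig
          ) -> pd.DataFrame:
    """Cross-product execution of an experiment over override values.

    ``parameter_grid`` maps override keys to value lists; each cell is
    run with a per-cell seed offset so replicates stay independent.
    """
    keys = list(parameter_grid)
    tables = []
    combos = [[]]
    for k in keys:
        combos = [c + [v] for c in combos for v in parameter_grid[k]]
    for i, combo in enumerate(combos):
        overrides = {**base.overrides, **dict(zip(keys, combo))}
        cfg = replace(base, overrides=overrides,
                      seed=base.seed + i * max(base.n_reps, 1))
        t = run_experiment(cfg)
        for k, v in zip(keys, combo):
            t[f"sweep_{k}"] = str(v)
        tables.append(t)
    return pd.concat(tables, ignore_index=True)
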