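"""Synthetic ligand inputs: static gradients plus spatial white noise.

The external cue seen by the cell is modelled Langevin-style as
``u(x, t) = u'(x, t) + eta(x, t)`` — a deterministic linear gradient
``u'`` plus a stochastic term ``eta`` that is regenerated independently
at every surface node each noise time step (piecewise-constant in time,
spatially and temporally white).

The gradient is parameterized by the concentration at the cell midpoint
(``L_mid``), the slope per micrometre (``L_slp``) and a direction; the
direction may reverse on a schedule (180-degree switch protocol).  Noise
draws are either normal or shifted log-normal with mean 0 and standard
deviation ``sigma``; the log-normal variant bounds ``eta`` from below so
that total input stays non-negative even when ``sigma`` is large
relative to ``L_mid``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import Field, GridKind, SurfaceGrid


@dataclass(frozen=True)
class GradientSpec:
    """Static linear ligand gradient across the cell.

    ``L_mid`` is the concentration at the cell midplane, ``L_slp`` the
    slope (concentration per um along the gradient axis) and
    ``direction`` the angle of the gradient axis in radians (circle
    grids; ignored for axisymmetric grids, whose axis is the gradient
    axis by construction).  ``switch_schedule`` lists ``(time_s,
    new_direction_rad)`` events, e.g. a 180-degree reversal.
    """

    L_mid: float
    L_slp: float = 0.0
    direction: float = 0.0
    switch_schedule: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.L_mid < 0:
            raise ValueError("L_mid must be non-negative")
        object.__setattr__(
            self, "switch_schedule",
            tuple(sorted((float(t), float(d)) for t, d in self.switch_schedule)),
        )

    def direction_at(self, t: float) -> float:
        d = self.direction
        for t_ev, d_ev in self.switch_schedule:
            if t >= t_ev:
                d = d_ev
        return d

    def relative_slope(self) -> float:
        """Slope as a fraction of the midpoint concentration (per um)."""
        return self.L_slp / self.L_mid if self.L_mid > 0 else np.inf


@dataclass(frozen=True)
class NoiseSpec:
    """Spatially-uncorrelated input noise, refreshed every ``noise_dt``.

    ``sigma`` is the literal per-node standard deviation at the default
    discretization (no 1/sqrt(dx*dt) rescaling): each grid node receives
    an i.i.d. draw held constant for one noise step.  ``lognormal_floor``
    sets the mean of the underlying log-normal (and hence the lower
    bound ``-lognormal_floor`` of the shifted draw); when ``None`` it is
    chosen from the accompanying gradient so that ``u' + eta >= 0``.
    """

    sigma: float
    distribution: str = "normal"
    noise_dt: float = 0.01
    seed: int = 0
    lognormal_floor: float | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.noise_dt <= 0:
            raise ValueError("noise_dt must be positive")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")


def static_gradient(spec: GradientSpec, grid: SurfaceGrid, t: float = 0.0) -> Field:
    """Evaluate the deterministic gradient ``u'`` on the grid at time ``t``.

    The node value is ``L_mid + L_slp * d`` where ``d`` is the signed
    distance (um) from the cell midplane along the current gradient
    axis: ``r*cos(theta - theta_g)`` on the circle, ``r*z`` on the
    axisymmetric sphere (a switched axisymmetric gradient flips sign).
    """
    d = _axis_distance(spec, grid, t)
    values = spec.L_mid + spec.L_slp * d
    if np.any(values < 0):
        raise ValueError(
            "gradient produces negative concentrations on the cell "
            f"(L_mid={spec.L_mid}, L_slp={spec.L_slp}, r={grid.radius})"
        )
    return Field(values, grid)


def _axis_distance(spec: GradientSpec, grid: SurfaceGrid, t: float) -> np.ndarray:
    direction = spec.direction_at(t)
    if grid.kind is GridKind.CIRCLE:
        return grid.radius * np.cos(grid.theta - direction)
    # axisymmetric: the polar axis is the gradient axis, front at z=1 for
    # direction 0; a direction in the opposite half-plane reverses z
    flip = np.cos(direction) < 0
    return grid.radius * grid.z * (-1.0 if flip else 1.0)


def _lognormal_params(sigma: float, mean: float) -> tuple[float, float]:
    """(mu, s) of a log-normal with the given mean and std ``sigma``."""
    s2 = np.log1p((sigma / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return mu, np.sqrt(s2)


def sample_noise(
    spec: NoiseSpec,
    grid: SurfaceGrid,
    rng: np.random.Generator,
    size: tuple[int, ...] = (),
) -> np.ndarray:
    """Draw one noise step: i.i.d. per-node values, mean 0, std ``sigma``.

    Normal noise is ``N(0, sigma^2)``.  Log-normal noise draws a
    log-normal with mean ``lognormal_floor`` (default ``sigma``) and
    variance ``sigma^2``, then subtracts its mean — giving mean 0, std
    ``sigma`` and support bounded below by ``-lognormal_floor``.
    """
    shape = (*size, grid.n_points)
    if spec.sigma == 0:
        return np.zeros(shape)
    if spec.distribution == "normal":
        return rng.normal(0.0, spec.sigma, size=shape)
    floor = spec.lognormal_floor if spec.lognormal_floor is not None else spec.sigma
    mu, s = _lognormal_params(spec.sigma, floor)
    return rng.lognormal(mu, s, size=shape) - floor


class InputProcess:
    """Reproducible stochastic input ``u(x, t) = u'(x, t) + eta(x, t)``.

    ``eta`` is piecewise constant on noise steps ``[m*k_t, (m+1)*k_t)``
    and i.i.d. across nodes and steps.  Evaluation is driven by the
    noise-step index so that a fixed seed yields a bitwise-identical
    realization regardless of how the process is sampled in time;
    internally draws are prefetched in chunks for speed.
    """

    def __init__(self, gradient: GradientSpec, noise: NoiseSpec, grid: SurfaceGrid,
                 chunk: int = 256):
        if noise.distribution == "lognormal" and noise.lognormal_floor is None:
            # bound eta below by the minimum of u' so u never goes negative
            umin = float(np.min(static_gradient(gradient, grid).values))
            if umin <= 0:
                umin = noise.sigma
            noise = replace(noise, lognormal_floor=umin)
        self.gradient = gradient
        self.noise = noise
        self.grid = grid
        self._chunk = int(chunk)
        self.reset()

    def reset(self, seed: int | None = None):
        """Rewind the noise stream (optionally re-seeding)."""
        if seed is not None:
            self.noise = replace(self.noise, seed=seed)
        self._rng = np.random.default_rng(np.random.Philox(self.noise.seed))
        self._buf: np.ndarray | None = None
        self._buf_start = 0  # noise-step index of _buf[0]
        self._next_step = 0  # next step index the rng will produce

    def noise_at_step(self, m: int) -> np.ndarray:
        """Noise field for noise-step index ``m`` (monotone access)."""
        if self.noise.sigma == 0:
            return np.zeros(self.grid.n_points)
        if m < self._buf_start:
            raise ValueError("noise steps must be accessed in non-decreasing order; "
                             "call reset() to rewind")
        while self._buf is None or m >= self._next_step:
            n_draw = max(self._chunk, m - self._next_step + 1)
            self._buf = sample_noise(self.noise, self.grid, self._rng, size=(n_draw,))
            self._buf_start = self._next_step
            self._next_step += n_draw
        return self._buf[m - self._buf_start]

    def __call__(self, t: float) -> np.ndarray:
        """Total input field ``u`` at time ``t``."""
        u = static_gradient(self.gradient, self.grid, t).values
        if self.noise.sigma:
            u = u + self.noise_at_step(int(np.floor(t / self.noise.noise_dt + 1e-9)))
        return u

    def deterministic(self, t: float) -> np.ndarray:
        return static_gradient(self.gradient, self.grid, t).values


class BatchedInputProcess:
    """Independent input realizations for a batch of replicate seeds.

    Yields noise arrays of shape ``(n_seeds, n_points)``; replicate ``i``
    reproduces exactly the single-seed :class:`InputProcess` stream for
    ``seeds[i]``.
    """

    def __init__(self, gradient: GradientSpec, noise: NoiseSpec, grid: SurfaceGrid,
                 seeds: Sequence[int], chunk: int = 256):
        self.seeds = list(seeds)
        self.procs = [
            InputProcess(gradient, noise, grid, chunk=chunk)
            for _ in self.seeds
        ]
        for proc, s in zip(self.procs, self.seeds):
            proc.reset(seed=int(s))
        self.gradient = gradient
        self.noise = self.procs[0].noise
        self.grid = grid

    def __call__(self, t: float) -> np.ndarray:
        u_det = static_gradient(self.gradient, self.grid, t).values
        if self.noise.sigma == 0:
            return np.broadcast_to(u_det, (len(self.seeds), self.grid.n_points)).copy()
        m = int(np.floor(t / self.noise.noise_dt + 1e-9))
        eta = np.stack([p.noise_at_step(m) for p in self.procs])
        return u_det[None, :] + eta


def make_input_process(
    gradient: GradientSpec, noise: NoiseSpec, grid: SurfaceGrid
) -> InputProcess:
    """Assemble the input evaluator ``u(node, t)`` from its components."""
    return InputProcess(gradient, noise, grid)


def microfluidics_gradient_params(L_max: float, L_min: float) -> tuple[float, float]:
    """Convert microfluidic chamber extremes to (L_mid, L_slp).

    For the Y-chamber device geometry used for yeast gradient assays:
    ``L_mid = 0.5*(L_max + L_min)`` and ``L_slp = 0.0025*(L_max - L_min)``
    per um.
    """
    if L_min < 0 or L_max < L_min:
        raise ValueError("require L_max >= L_min >= 0")
    return 0.5 * (L_max + L_min), 0.0025 * (L_max - L_min)
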