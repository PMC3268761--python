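"""Coarse-grained model of gradient sensing and polarization response.

A single stage tracks a membrane polarity marker ``a(x, t)`` and a
global negative-feedback regulator ``b(t)``:

    da/dt = Ds * lap(a) + k0 * H_q(u) + k1 * H_h(p * a) - k2*a - k3*b*a
    db/dt = k4 * (a_avg - k_ss) * b,        p = H_q(beta * u)

where ``H_n(x) = x^n / (1 + x^n)`` is a Hill function, ``u`` the
external input and ``a_avg`` the surface average of ``a``.  The ``k0``
term is input ultrasensitivity (the NPF regime, amplification by a
steep dose-response), the ``k1`` term a positive feedback loop (the PF
regime) gated by the input through ``p`` so that feedback cannot lock
in without ligand.  ``b`` integrates the deviation of ``a_avg`` from
the set point ``k_ss``, enforcing robust adaptation: whatever the input
level, the mean amount of marker returns to ``k_ss``.

Stages can be chained in series (the output field of stage *i* is the
input of stage *i+1*), each stage keeping its own integral controller —
the filter-amplifier cascades (e.g. NPF+PF) are built this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .geometry import (
    Field,
    IntegrationError,
    SurfaceGrid,
    Trajectory,
    implicit_diffusion_solver,
    laplacian_operator,
    surface_average,
)
from .inputs import BatchedInputProcess, InputProcess

#: Membrane diffusion coefficient of the polarity marker (um^2/s).
#: Calibrated so the noise-free NPF response polarizes to a_f ~ 2 at
#: L_slp = 0.1 /um while diffusive smoothing still suppresses
#: grid-scale noise (see docs/methods.md); flagged "calibrated" in run
#: metadata.
DEFAULT_DS = 0.05

#: Input Hill coefficient for the high-ultrasensitivity regime.
DEFAULT_Q = 1000.0


def hill(x: np.ndarray | float, n: float) -> np.ndarray:
    """Overflow-safe Hill function ``x^n / (1 + x^n)`` for ``x >= 0``.

    Evaluated as ``expit(n * log(x))`` so that coefficients as large as
    ``n = 1000`` never overflow.  ``hill(0, n) = 0`` and, by the
    logistic limit, ``hill(x, 0) = 1/2`` for every x > 0 (the convention
    used when a feedback loop is severed by zeroing its exponent).
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logx = np.log(np.maximum(x, 0.0))
    out = expit(n * logx)
    if n == 0:
        # expit(0 * -inf) would be nan at x=0; keep the 1/2 convention
        out = np.where(x > 0, 0.5, 0.5) if np.isscalar(out) else np.full_like(out, 0.5)
    else:
        out = np.where(x > 0, out, 0.0)
    return out


@dataclass(frozen=True)
class GenericStageParams:
    """Rate constants of one generic stage.

    ``k0``/``k1`` set the balance between input-ultrasensitive and
    positive-feedback production, ``k2`` first-order decay, ``k3`` the
    strength of the global inhibitor, ``k4`` the integral-feedback gain,
    ``q``/``h`` the input and feedback Hill coefficients, ``beta`` the
    input scaling inside the feedback gate ``p`` and ``k_ss`` the
    adaptation set point.  ``speed_factor`` records cumulative speed
    scaling applied to ``k0..k4``.
    """

    Ds: float = DEFAULT_DS
    k0: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    k4: float = 1.0
    q: float = DEFAULT_Q
    h: float = 4.0
    beta: float = 1.0
    k_ss: float = 1.0
    speed_factor: float = 1.0

    def __post_init__(self):
        for name in ("Ds", "k0", "k1", "k2", "k3", "k4", "q", "h", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_ss <= 0:
            raise ValueError("k_ss must be positive")


@dataclass
class GenericStageState:
    """State of one stage: marker field ``a`` plus global inhibitor ``b``."""

    a: Field
    b: float | np.ndarray


@dataclass(frozen=True)
class CascadeSpec:
    """Serial wiring of stages: output field of stage i feeds stage i+1."""

    stages: tuple[GenericStageParams, ...]

    def __post_init__(self):
        if len(self.stages) < 1:
            raise ValueError("cascade needs at least one stage")

    @property
    def n_stages(self) -> int:
        return len(self.stages)


def as_cascade(model: GenericStageParams | CascadeSpec) -> CascadeSpec:
    if isinstance(model, GenericStageParams):
        return CascadeSpec((model,))
    return model


def scale_speed(
    model: GenericStageParams | CascadeSpec, factor: float
) -> GenericStageParams | CascadeSpec:
    """Scale the reaction rates ``k0..k4`` by ``factor`` (Ds unchanged).

    Multiplying all rate constants rescales the kinetics without moving
    any steady state; diffusion is deliberately left fixed, so speed
    scaling changes the balance between reaction and spatial smoothing.
    """
    if factor <= 0:
        raise ValueError("speed factor must be positive")
    if isinstance(model, CascadeSpec):
        return CascadeSpec(tuple(scale_speed(s, factor) for s in model.stages))
    return replace(
        model,
        k0=model.k0 * factor,
        k1=model.k1 * factor,
        k2=model.k2 * factor,
        k3=model.k3 * factor,
        k4=model.k4 * factor,
        speed_factor=model.speed_factor * factor,
    )


def _reaction(a, b, u, p: GenericStageParams):
    """Reaction part of the stage right-hand side (no diffusion).

    Negative inputs (possible under unbounded normal noise) are clamped
    to zero inside the Hill terms only, leaving the additive noise model
    otherwise untouched; ``a`` is likewise floored at 0 in the feedback
    term.
    """
    u_pos = np.maximum(u, 0.0)
    prod = p.k0 * hill(u_pos, p.q)
    if p.k1:
        gate = hill(p.beta * u_pos, p.q)
        prod = prod + p.k1 * hill(gate * np.maximum(a, 0.0), p.h)
    b_col = np.asarray(b)[..., None] if np.ndim(b) else b
    da = prod - p.k2 * a - p.k3 * b_col * a
    return da


def generic_rhs(
    state: GenericStageState,
    params: GenericStageParams,
    u: Field | np.ndarray,
) -> tuple[Field, float | np.ndarray]:
    """Full time derivative (da/dt, db/dt) of one stage, diffusion included."""
    a = state.a.values
    grid = state.a.grid
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(np.asarray(state.b)))):
        raise ValueError("non-finite state passed to generic_rhs")
    u_vals = u.values if isinstance(u, Field) else np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u_vals)):
        raise ValueError("non-finite input passed to generic_rhs")
    da = _reaction(a, state.b, u_vals, params)
    if params.Ds:
        da = da + params.Ds * (a @ grid.laplacian_matrix.T.toarray()
                               if a.ndim > 1 else grid.laplacian_matrix @ a)
    abar = surface_average(a, grid)
    db = params.k4 * (abar - params.k_ss) * np.asarray(state.b)
    return Field(da, grid), db


class _CascadeStepper:
    """Vectorized IMEX (implicit diffusion / explicit reaction) stepper.

    State arrays carry an optional leading replicate axis so that a
    whole Monte Carlo batch advances per step.  Noise is frozen within
    each dt (dt = noise step by default).
    """

    def __init__(self, spec: CascadeSpec, grid: SurfaceGrid, dt: float,
                 scheme: str = "imex"):
        self.spec = spec
        self.grid = grid
        self.dt = dt
        self.scheme = scheme
        self.w = grid.quad_weights / grid.quad_weights.sum()
        self.lap = laplacian_operator(grid)
        self.solvers = [
            implicit_diffusion_solver(grid, s.Ds, dt) if scheme == "imex" else None
            for s in spec.stages
        ]

    def init_state(self, batch_shape: tuple[int, ...] = ()):
        n = self.grid.n_points
        a = [np.full((*batch_shape, n), s.k_ss) for s in self.spec.stages]
        b = [np.ones(batch_shape) for s in self.spec.stages]
        return a, b

    def step(self, a: list, b: list, u0, t: float):
        dt = self.dt
        u = u0
        for i, p in enumerate(self.spec.stages):
            ai, bi = a[i], b[i]
            da = _reaction(ai, bi, u, p)
            if self.scheme == "euler":
                new = ai + dt * (da + (p.Ds * self.lap(ai) if p.Ds else 0.0))
            else:
                new = ai + dt * da
                if p.Ds:
                    new = self.solvers[i](new)
            np.maximum(new, 0.0, out=new)  # guard rare undershoot
            abar = new @ self.w
            b[i] = bi + dt * p.k4 * (abar - p.k_ss) * bi
            a[i] = new
            u = new  # stage coupling: next stage reads this stage's marker
        if not np.all(np.isfinite(a[-1])):
            raise IntegrationError(
                f"generic cascade diverged at t={t + dt:.4g} s", t=t + dt)
        return a, b


def simulate_generic(
    model: GenericStageParams | CascadeSpec,
    input_process: InputProcess | BatchedInputProcess,
    t_end: float,
    dt: float = 0.01,
    seed: int | None = None,
    burn_in: float = 100.0,
    record_every: int = 1,
    record_scalars_only: bool = False,
    scheme: str = "imex",
) -> Trajectory:
    """Simulate a generic stage or cascade driven by a noisy input.

    The run starts from ``a = k_ss`` (uniform), ``b = 1`` and is first
    equilibrated noise-free under the deterministic gradient for
    ``burn_in`` seconds; noise is then switched on and the trajectory
    recorded for ``t_end`` seconds (time axis restarts at 0 at noise
    onset).  Snapshots of every stage field ``a1..aS`` and controller
    ``b1..bS`` are stored every ``record_every`` steps; with
    ``record_scalars_only`` only the front value ``af_i`` and surface
    average ``abar_i`` of each stage are kept (memory-light mode for
    long stationary windows).
    """
    spec = as_cascade(model)
    grid = input_process.grid
    if seed is not None:
        input_process.reset(seed=seed)
    if dt <= 0 or dt > input_process.noise.noise_dt + 1e-12:
        raise ValueError("require 0 < dt <= noise_dt")

    stepper = _CascadeStepper(spec, grid, dt, scheme=scheme)
    batched = isinstance(input_process, BatchedInputProcess)
    batch_shape = (len(input_process.seeds),) if batched else ()
    a, b = stepper.init_state(batch_shape)

    # noise-free burn-in under the static gradient
    n_burn = int(round(burn_in / dt))
    u_det = input_process.deterministic(0.0) if not batched else (
        input_process.procs[0].deterministic(0.0))
    for k in range(n_burn):
        a, b = stepper.step(a, b, u_det, k * dt)

    n_steps = int(round(t_end / dt))
    n_rec = n_steps // record_every + 1
    front = grid.front_index
    w = stepper.w
    species: dict[str, np.ndarray] = {}
    S = spec.n_stages
    for i in range(S):
        if not record_scalars_only:
            species[f"a{i + 1}"] = np.empty((n_rec, *batch_shape, grid.n_points))
        species[f"b{i + 1}"] = np.empty((n_rec, *batch_shape))
        species[f"af{i + 1}"] = np.empty((n_rec, *batch_shape))
        species[f"abar{i + 1}"] = np.empty((n_rec, *batch_shape))
    times = np.empty(n_rec)

    def record(idx, t):
        times[idx] = t
        for i in range(S):
            if not record_scalars_only:
                species[f"a{i + 1}"][idx] = a[i]
            species[f"b{i + 1}"][idx] = b[i]
            species[f"af{i + 1}"][idx] = a[i][..., front]
            species[f"abar{i + 1}"][idx] = a[i] @ w

    record(0, 0.0)
    idx = 1
    for k in range(n_steps):
        u = input_process(k * dt)
        a, b = stepper.step(a, b, u, k * dt)
        if (k + 1) % record_every == 0 and idx < n_rec:
            record(idx, (k + 1) * dt)
            idx += 1

    meta = {
        "model": "generic",
        "n_stages": S,
        "dt": dt,
        "burn_in": burn_in,
        "sigma": input_process.noise.sigma,
        "L_mid": input_process.gradient.L_mid,
        "L_slp": input_process.gradient.L_slp,
        "k_x": grid.n_points,
        "calibrated": ["Ds", "q", "h", "beta"],
    }
    if batched:
        meta["seeds"] = list(input_process.seeds)
    return Trajectory(times[:idx], {k_: v[:idx] for k_, v in species.items()},
                      grid, rng_seed=getattr(input_process.noise, "seed", None),
                      metadata=meta)


#: Hill coefficients of the calibrated regimes.  ``q = 50`` keeps both
#: the ultrasensitive input term and the feedback gate ``p`` steep
#: enough to polarize on a 1% gradient while remaining responsive to a
#: 180-degree reversal; ``h = 8`` is the high-gain feedback loop.  Any
#: q well above ~30 reproduces the same noise-free polarization extent
#: (the Hill term saturates); the defaults are calibrated against the
#: settling-time and stationary-noise study conditions (docs/methods.md).
_PRESET_BASE = {
    "NPF": dict(k0=10.0, k1=0.0, q=50.0),
    "PF": dict(k0=1.0, k1=10.0, q=50.0, h=8.0),
    "low_PF": dict(k0=1.0, k1=10.0, q=50.0, h=2.0),
    "high_PF": dict(k0=1.0, k1=10.0, q=50.0, h=8.0),
}

#: Non-final stages of a cascade act as unity-gain low-pass filters: a
#: q = 2 input Hill term has logarithmic slope q*(1 - H(1)) = 1 at the
#: operating point u = 1, so the relative front-to-back contrast passes
#: through unchanged while the stage's relaxation time-averages the
#: noise.  An amplifying (high-q) first stage would saturate and erase
#: the gradient information the downstream amplifier needs.
_FILTER_Q = 2.0


def make_preset(name: str) -> GenericStageParams | CascadeSpec:
    """Named model configurations.

    Single stages: ``NPF`` (k0=10, k1=0, ultrasensitive input), ``PF``
    (k0=1, k1=10, positive-feedback amplification), ``low_PF`` /
    ``high_PF`` (feedback Hill coefficient 2 / 8).  Cascades join stage
    names with ``+`` (``NPF+PF``, ``NPF+NPF``...); every stage before
    the last becomes a unity-gain (q=2) filter variant of its module.
    A ``_slow`` / ``_fast`` suffix scales all rate constants by 0.1 /
    10, either on the whole model (``NPF+PF_slow`` is ambiguous — use
    the trailing suffix form only on single stages) or per stage
    (``NPF_slow+PF_slow``).
    """
    name = name.strip()
    if "+" in name:
        parts = name.split("+")
        stages = tuple(
            _single_preset(part, filter_stage=(i < len(parts) - 1))
            for i, part in enumerate(parts)
        )
        return CascadeSpec(stages)
    return _single_preset(name)


def _single_preset(name: str, filter_stage: bool = False) -> GenericStageParams:
    name = name.strip()
    if name.endswith(("_slow", "_fast")):
        base, suffix = name.rsplit("_", 1)
        factor = 0.1 if suffix == "slow" else 10.0
        return scale_speed(_single_preset(base, filter_stage), factor)
    try:
        kwargs = dict(_PRESET_BASE[name])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: "
                         f"{sorted(_PRESET_BASE)} (+ cascades and _slow/_fast)")
    if filter_stage:
        kwargs["q"] = _FILTER_Q
    return GenericStageParams(**kwargs)
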