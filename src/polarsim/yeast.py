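"""Mechanistic model of yeast pheromone-gradient cell polarization.

Two signalling stages wired as a filter-amplifier:

* **Stage 1 — heterotrimeric G-protein cycle.**  Receptor (R) binds
  alpha-factor (L) to form the active complex (RL), which catalyzes
  G-protein activation, splitting heterotrimer G into Galpha-GTP (Ga)
  and free Gbetagamma (Gbg); Ga hydrolyses to Gd which re-associates
  with Gbg.  The cycle is slow, so the RL and Gbg fields are
  time-averaged versions of the noisy ligand input.
* **Stage 2 — Cdc42 cycle.**  Free Gbg recruits the GEF Cdc24 to the
  membrane (C24m), which activates Cdc42 (C42 -> C42a).  Active Cdc42
  recruits the scaffold Bem1 (B1m), which recruits more Cdc24 — the
  fast *inner* positive feedback loop.  The PAK Cla4 provides global
  negative feedback by promoting Cdc24 removal.  A slow *outer*
  positive feedback loop redirects receptor synthesis toward sites of
  high Cdc42 activity (actin-directed secretion), expressed by the
  polarized-synthesis weight ``p_s = C42a / <C42a>``.

Membrane species diffuse with a common coefficient D; Cdc24 and Bem1
exchange with well-mixed cytoplasmic pools (tracked as conserved
fractions), and Cla4a is a single well-mixed activity.

All rate constants live in :class:`YeastParams`.  The published source
of this model ships its numeric constants in supplementary material
that the package does not vendor; the defaults here are a calibrated
set (flagged in run metadata) chosen to reproduce the study's
quantitative directional-accuracy and mutant-phenotype conditions —
see docs/methods.md for the calibration protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .geometry import (
    GridKind,
    IntegrationError,
    SurfaceGrid,
    Trajectory,
    implicit_diffusion_solver,
)
from .inputs import BatchedInputProcess, InputProcess
from .generic import hill

#: names of the membrane surface fields, in integration order
MEMBRANE_SPECIES = ("R", "RL", "G", "Ga", "Gbg", "Gd", "C24m", "C42", "C42a", "B1m")


@dataclass(frozen=True)
class HillSpec:
    """Saturating regulatory function ``x -> max * (x/K)^n / (1 + (x/K)^n)``."""

    K: float
    n: float
    max: float = 1.0

    def __call__(self, x):
        return self.max * hill(np.asarray(x, dtype=float) / self.K, self.n)


@dataclass(frozen=True)
class YeastParams:
    """Rate constants and totals of the yeast polarization model.

    Units: lengths um, times s, ligand nM, membrane species in
    molecules/um^2; Cdc24 / Bem1 cytoplasmic pools are tracked as the
    fraction of their totals remaining in the cytoplasm, and Cla4a is a
    dimensionless well-mixed activity.
    """

    # shared membrane diffusion
    D: float = 0.01

    # stage 1: receptor and heterotrimeric G-protein cycle.  Binding and
    # G-cycle turnover are sub-second to seconds; receptor synthesis and
    # removal (the outer loop's substrate) turn over in minutes.
    kRL: float = 0.1         # ligand binding, /nM/s
    kRLm: float = 0.5        # unbinding, /s (Kd = 5 nM)
    kRd0: float = 5e-4       # free receptor removal, /s
    kRd1: float = 2.5e-3     # bound receptor removal (endocytosis), /s
    kRs: float = 0.1         # receptor synthesis, molecules/um^2/s
    kGa: float = 0.025       # G activation by RL, um^2/s
    kGd: float = 0.35        # Ga hydrolysis, /s
    kG1: float = 0.015       # Gd + Gbg re-association, um^2/s
    G_total: float = 199.0   # heterotrimer density equivalent (10^4 per cell)

    # stage 2: Cdc42 cycle (fast inner loop, ~1/s turnover)
    k24cm0: float = 10.0     # Gbg-driven Cdc24 recruitment, molecules/um^2/s
    k24cm1: float = 30.0     # Bem1-driven Cdc24 recruitment, molecules/um^2/s
    k24mc: float = 0.5       # Cdc24 release, /s
    k24d: float = 0.5        # Cla4-dependent Cdc24 removal, /s per Cla4a
    k42a: float = 0.5        # Cdc42 activation by Cdc24, um^2/s
    k42d: float = 1.0        # Cdc42 deactivation, /s
    kB1cm: float = 1.0       # Bem1 recruitment by C42a, um^2/s
    kB1mc: float = 1.0       # Bem1 release, /s
    kCla4a: float = 1.0      # Cla4 activation, /s
    kCla4d: float = 0.03     # Cla4 deactivation, /s (slow global feedback)
    C24_pool: float = 10.0   # total Cdc24, as uniform surface density equiv.
    B1_pool: float = 19.9    # total Bem1, as uniform surface density equiv.
    C42_density: float = 59.7    # total Cdc42 density (3000 per cell)

    # regulatory saturating functions.  f_Gbg is very steep (the
    # ultrasensitive readout of free Gbetagamma); f_Cla4's threshold
    # places the uniform state just below the onset of the inner-loop
    # instability, so polarization is an ignition race between the
    # deterministic gradient bias and noise (docs/methods.md).
    f_Gbg: HillSpec = field(default_factory=lambda: HillSpec(K=0.795, n=40.0))
    f_Bem1: HillSpec = field(default_factory=lambda: HillSpec(K=12.0, n=8.0))
    f_Cla4: HillSpec = field(default_factory=lambda: HillSpec(K=11.0, n=8.0))

    # mutants and speed scaling
    bni1_delta: bool = False   # outer loop removed: isotropic synthesis
    gprotein_speed_factor: float = 1.0

    def __post_init__(self):
        for name in ("kRL", "kRLm", "kRd0", "kRd1", "kRs", "kGa", "kGd", "kG1",
                     "k24cm0", "k24cm1", "k24mc", "k24d", "k42a", "k42d",
                     "kB1cm", "kB1mc", "kCla4a", "kCla4d", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("G_total", "C24_pool", "B1_pool", "C42_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def bem1_delta(self) -> bool:
        """Inner loop severed (Bem1-driven recruitment absent or constant)."""
        return self.f_Bem1.n == 0 or self.k24cm1 == 0


def apply_mutant(params: YeastParams, mutant: str,
                 hard_zero: bool = True) -> YeastParams:
    """Return a mutant parameter set.

    ``bem1_delta`` removes the Bem1-dependent Cdc24 recruitment term
    (the bem1-299 truncation cannot bind Cdc24), severing the inner
    loop; with ``hard_zero=False`` the lesion instead zeroes the Hill
    exponent of the Bem1 term, which by the Hill(h=0) = 1/2 convention
    leaves a constant half-maximal recruitment — a milder variant kept
    for sensitivity analysis.  ``bni1_delta``
    removes the *polarized* component of receptor synthesis — delivery
    becomes isotropic (``p_s = 1`` everywhere), severing the outer loop
    while preserving receptor numbers.  ``wild_type`` is the identity.
    """
    if mutant in ("wild_type", "wt"):
        return params
    if mutant == "bem1_delta":
        if hard_zero:
            return replace(params, k24cm1=0.0)
        return replace(params, f_Bem1=replace(params.f_Bem1, n=0.0))
    if mutant == "bni1_delta":
        return replace(params, bni1_delta=True)
    raise ValueError(f"unknown mutant {mutant!r}; expected wild_type, "
                     "bem1_delta or bni1_delta")


def scale_gprotein_speed(params: YeastParams, factor: float) -> YeastParams:
    """Scale only the stage-1 (receptor / G-protein cycle) rates.

    Multiplies {kRL, kRLm, kRd0, kRd1, kRs, kGa, kGd, kG1} by ``factor``;
    stage-2 rates and diffusion are untouched, so the filter becomes
    faster or slower relative to the downstream amplifier.
    """
    if factor <= 0:
        raise ValueError("speed factor must be positive")
    return replace(
        params,
        kRL=params.kRL * factor, kRLm=params.kRLm * factor,
        kRd0=params.kRd0 * factor, kRd1=params.kRd1 * factor,
        kRs=params.kRs * factor, kGa=params.kGa * factor,
        kGd=params.kGd * factor, kG1=params.kG1 * factor,
        gprotein_speed_factor=params.gprotein_speed_factor * factor,
    )


@dataclass
class YeastState:
    """All species on one grid: ten membrane fields + well-mixed scalars.

    Cytoplasmic Cdc24 and Bem1 are stored as fractions of their totals
    (closed by conservation against the membrane-bound surface
    integrals).
    """

    fields: dict[str, np.ndarray]
    Cla4a: np.ndarray | float
    grid: SurfaceGrid
    params: YeastParams

    def surface_integral(self, name: str) -> np.ndarray | float:
        return (self.fields[name] * self.grid.quad_weights).sum(axis=-1)

    def surface_mean(self, name: str) -> np.ndarray | float:
        w = self.grid.quad_weights
        return (self.fields[name] * w).sum(axis=-1) / w.sum()

    @property
    def C24c(self):
        return 1.0 - self.surface_mean("C24m") / self.params.C24_pool

    @property
    def B1c(self):
        return 1.0 - self.surface_mean("B1m") / self.params.B1_pool

    def conservation_totals(self) -> dict[str, np.ndarray | float]:
        """The three conserved surface totals (Galpha, Gbetagamma, Cdc42)."""
        return {
            "Galpha": self.surface_integral("G") + self.surface_integral("Ga")
            + self.surface_integral("Gd"),
            "Gbetagamma": self.surface_integral("G") + self.surface_integral("Gbg"),
            "Cdc42": self.surface_integral("C42") + self.surface_integral("C42a"),
        }


def initial_state(params: YeastParams, grid: SurfaceGrid,
                  batch_shape: tuple[int, ...] = ()) -> YeastState:
    """Unstimulated uniform state: free receptor and heterotrimer only."""
    n = grid.n_points
    shape = (*batch_shape, n)
    f = {name: np.zeros(shape) for name in MEMBRANE_SPECIES}
    f["R"] = np.full(shape, params.kRs / params.kRd0 if params.kRd0 else 199.0)
    f["G"] = np.full(shape, params.G_total)
    f["C42"] = np.full(shape, params.C42_density)
    return YeastState(f, np.zeros(batch_shape) if batch_shape else 0.0,
                      grid, params)


def _reaction_rhs(f: Mapping[str, np.ndarray], cla4a, params: YeastParams,
                  L: np.ndarray, w_frac: np.ndarray):
    """Reaction (non-diffusive) part of all species derivatives.

    ``w_frac`` is the normalized quadrature weight vector used for
    surface averages/integrals; batched states broadcast over leading
    axes.
    """
    p = params
    L = np.maximum(L, 0.0)

    c24c = 1.0 - (f["C24m"] @ w_frac["mean"]) / p.C24_pool
    b1c = 1.0 - (f["B1m"] @ w_frac["mean"]) / p.B1_pool
    c42a_avg = f["C42a"] @ w_frac["mean"]

    # polarized receptor synthesis: outer loop weight.  Without the
    # formin Bni1, new receptor is delivered isotropically (ps = 1
    # everywhere) — the polarized component of synthesis is zero but
    # delivery itself continues, so receptor numbers are preserved.
    if p.bni1_delta:
        ps = 1.0
    else:
        avg = np.asarray(c42a_avg)[..., None]
        ps = np.where(avg > 0, f["C42a"] / np.maximum(avg, np.finfo(float).tiny), 1.0)

    bind = p.kRL * L * f["R"]
    unbind = p.kRLm * f["RL"]
    g_act = p.kGa * f["RL"] * f["G"]
    g_reassoc = p.kG1 * f["Gd"] * f["Gbg"]

    c24c_col = np.asarray(c24c)[..., None] if np.ndim(c24c) else c24c
    b1c_col = np.asarray(b1c)[..., None] if np.ndim(b1c) else b1c
    cla4_col = np.asarray(cla4a)[..., None] if np.ndim(cla4a) else cla4a
    recruit24 = (p.k24cm0 * p.f_Gbg(f["Gbg"] / p.G_total)
                 + p.k24cm1 * p.f_Bem1(f["B1m"])) * c24c_col
    c42_act = p.k42a * f["C24m"] * f["C42"]

    d = {
        "R": -bind + unbind - p.kRd0 * f["R"] + ps * p.kRs,
        "RL": bind - unbind - p.kRd1 * f["RL"],
        "G": -g_act + g_reassoc,
        "Ga": g_act - p.kGd * f["Ga"],
        "Gbg": g_act - g_reassoc,
        "Gd": p.kGd * f["Ga"] - g_reassoc,
        "C24m": recruit24 - p.k24mc * f["C24m"] - p.k24d * cla4_col * f["C24m"],
        "C42": -c42_act + p.k42d * f["C42a"],
        "C42a": c42_act - p.k42d * f["C42a"],
        "B1m": p.kB1cm * f["C42a"] * b1c_col - p.kB1mc * f["B1m"],
    }
    d_cla4 = p.kCla4a * p.f_Cla4(c42a_avg) - p.kCla4d * np.asarray(cla4a)
    return d, d_cla4, (c24c, b1c)


def yeast_rhs(state: YeastState, params: YeastParams,
              L: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray | float]:
    """Full time derivatives of all species (diffusion included).

    Returns ``(field_derivatives, dCla4a/dt)``.  Raises on non-finite
    state and on a negative cytoplasmic pool (conservation violation).
    """
    grid = state.grid
    for name, v in state.fields.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in species {name!r}")
    w = {"area": grid.quad_weights,
         "mean": grid.quad_weights / grid.quad_weights.sum()}
    d, d_cla4, (c24c, b1c) = _reaction_rhs(state.fields, state.Cla4a, params,
                                           np.asarray(L, dtype=float), w)
    if np.any(np.asarray(c24c) < -1e-9) or np.any(np.asarray(b1c) < -1e-9):
        raise RuntimeError("conservation violation: cytoplasmic pool negative")
    if params.D:
        lap_t = grid.laplacian_matrix.T.toarray()
        for name in d:
            d[name] = d[name] + params.D * (state.fields[name] @ lap_t)
    return d, d_cla4


def _stiffness_rate(params: YeastParams, L_mid: float) -> float:
    """Crude bound on the fastest reaction rate (1/s) at typical densities."""
    p = params
    return max(
        p.kRL * L_mid + p.kRLm + p.kRd1,
        p.kGa * p.G_total, p.kGd, p.kG1 * p.G_total,
        p.k24mc + p.k24d * 20.0,
        p.k42a * p.C42_density + p.k42d,
        p.kB1cm * p.C42_density + p.kB1mc,
    )


class _YeastStepper:
    """IMEX stepper (implicit diffusion, explicit reactions), batch-aware.

    Reactions are sub-stepped automatically when the fastest rate would
    make a plain explicit update unstable at the requested dt (the 10x
    speed-scaled G-protein cycle needs this); the noise input is still
    held frozen across the whole dt, preserving the noise-step model.
    """

    def __init__(self, params: YeastParams, grid: SurfaceGrid, dt: float,
                 scheme: str = "imex", substeps: int | None = None,
                 L_mid_hint: float = 10.0):
        self.params = params
        self.grid = grid
        self.dt = dt
        self.scheme = scheme
        self.w = {"area": grid.quad_weights,
                  "mean": grid.quad_weights / grid.quad_weights.sum()}
        if substeps is None:
            substeps = max(1, int(np.ceil(dt * _stiffness_rate(params, L_mid_hint) / 0.2)))
        self.substeps = substeps
        if scheme == "imex":
            self.solve = implicit_diffusion_solver(grid, params.D, dt)
        else:
            self.lap_t = grid.laplacian_matrix.T.toarray()

    def step(self, f: dict, cla4a, L, t: float):
        h = self.dt / self.substeps
        for _ in range(self.substeps):
            d, d_cla4, _pools = _reaction_rhs(f, cla4a, self.params, L, self.w)
            if self.scheme == "euler" and self.params.D:
                for name in d:
                    d[name] = d[name] + self.params.D * (f[name] @ self.lap_t)
            f = {name: f[name] + h * d[name] for name in f}
            for v in f.values():
                np.maximum(v, 0.0, out=v)  # guard rare explicit undershoot
            cla4a = np.maximum(np.asarray(cla4a) + h * d_cla4, 0.0)
        if self.scheme != "euler" and self.params.D:
            f = {name: self.solve(v) for name, v in f.items()}
        if not np.all(np.isfinite(f["C42a"])):
            raise IntegrationError(f"yeast model diverged at t={t + self.dt:.4g} s",
                                   t=t + self.dt)
        return f, cla4a


def simulate_yeast(
    params: YeastParams,
    input_process: InputProcess | BatchedInputProcess,
    t_end: float,
    dt: float = 0.01,
    seed: int | None = None,
    burn_in: float = 600.0,
    record_every: int = 100,
    record_species: tuple[str, ...] = ("C42a",),
    initial: YeastState | None = None,
) -> Trajectory:
    """Simulate the yeast model driven by a noisy pheromone input.

    The run is first equilibrated noise-free under the deterministic
    gradient for ``burn_in`` seconds ("after approaching steady state"),
    then noise is switched on for ``t_end`` seconds with snapshots of
    ``record_species`` stored every ``record_every`` steps.  Surface
    averages of every membrane species, the Cla4a activity and the
    conserved totals are recorded at the same cadence.
    """
    grid = input_process.grid
    if seed is not None:
        input_process.reset(seed=seed)
    if dt <= 0 or dt > input_process.noise.noise_dt + 1e-12:
        raise ValueError("require 0 < dt <= noise_dt")

    batched = isinstance(input_process, BatchedInputProcess)
    batch_shape = (len(input_process.seeds),) if batched else ()
    stepper = _YeastStepper(params, grid, dt)
    if initial is None:
        state0 = initial_state(params, grid, batch_shape)
    else:
        state0 = initial
    f = {k: v.copy() for k, v in state0.fields.items()}
    cla4a = np.array(state0.Cla4a, dtype=float)

    u_det = (input_process.procs[0] if batched else input_process).deterministic(0.0)
    n_burn = int(round(burn_in / dt))
    for k in range(n_burn):
        f, cla4a = stepper.step(f, cla4a, u_det, k * dt)

    n_steps = int(round(t_end / dt))
    n_rec = n_steps // record_every + 1
    species: dict[str, np.ndarray] = {}
    for name in record_species:
        species[name] = np.empty((n_rec, *batch_shape, grid.n_points))
    for name in MEMBRANE_SPECIES:
        species[f"{name}_avg"] = np.empty((n_rec, *batch_shape))
    species["Cla4a"] = np.empty((n_rec, *batch_shape))
    times = np.empty(n_rec)
    w_mean = stepper.w["mean"]

    def record(idx, t):
        times[idx] = t
        for name in record_species:
            species[name][idx] = f[name]
        for name in MEMBRANE_SPECIES:
            species[f"{name}_avg"][idx] = f[name] @ w_mean
        species["Cla4a"][idx] = cla4a

    record(0, 0.0)
    idx = 1
    for k in range(n_steps):
        u = input_process(k * dt)
        f, cla4a = stepper.step(f, cla4a, u, k * dt)
        if (k + 1) % record_every == 0 and idx < n_rec:
            record(idx, (k + 1) * dt)
            idx += 1

    meta = {
        "model": "yeast",
        "dt": dt,
        "burn_in": burn_in,
        "sigma": input_process.noise.sigma,
        "L_mid": input_process.gradient.L_mid,
        "L_slp": input_process.gradient.L_slp,
        "k_x": grid.n_points,
        "gprotein_speed_factor": params.gprotein_speed_factor,
        "mutant": ("bem1_delta" if params.bem1_delta
                   else "bni1_delta" if params.bni1_delta else "wild_type"),
        "calibrated": "rate constants (see docs/methods.md)",
    }
    if batched:
        meta["seeds"] = list(input_process.seeds)
    final = YeastState(f, cla4a, grid, params)
    traj = Trajectory(times[:idx], {k_: v[:idx] for k_, v in species.items()},
                      grid, rng_seed=getattr(input_process.noise, "seed", None),
                      metadata=meta)
    traj.metadata["final_state"] = final
    return traj
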