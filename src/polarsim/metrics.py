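"""Output statistics of polarization simulations.

Implements the quantities used throughout the package to score a
polarization response:

* ``a_f`` — the marker value at the front of the cell (the node at
  ``z = 1`` on axisymmetric grids, the node nearest the gradient axis
  on circles); time-averaged when noise is on.
* ``sigma_out`` — temporal standard deviation of ``a_f`` in the
  stationary regime (output smoothness).
* ``theta_pol`` / ``cos(theta)`` — polarization direction from the
  circular centre of mass of the polarized species, and its cosine
  relative to the gradient direction (directional accuracy).
* ``a_f_norm = (a_f - k_ss) * cos(theta)`` — combined score.
* ``t_s`` — settling time: the average of the 5%-band response times to
  gradient onset and to a 180-degree gradient reversal (noise-free).

Replicate aggregation (Monte Carlo mean +- SEM) is provided by
:func:`monte_carlo`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import GridKind, SurfaceGrid, Trajectory
from .inputs import GradientSpec, NoiseSpec, InputProcess
from . import generic as _generic


class UndefinedDirectionError(ValueError):
    """The field is too uniform for a polarization direction to exist."""


class SettlingTimeoutError(RuntimeError):
    def __init__(self, message, residual):
        super().__init__(message)
        self.residual = residual


def stationary_stats(
    traj: Trajectory,
    species: str,
    window_s: float = 100.0,
    n_samples: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-mean and time-std of a species over the final window.

    Defaults reproduce the stationary-distribution estimate used for all
    reported numbers: 10000 samples over the last 100 s of the run.
    Returns ``(mean, std)`` with the time axis reduced.
    """
    t_end = traj.times[-1]
    if window_s > t_end - traj.times[0] + 1e-9:
        raise ValueError(
            f"window of {window_s} s exceeds trajectory span "
            f"[{traj.times[0]}, {t_end}] s")
    win = traj.window(t_end - window_s, t_end + 1e-9)
    arr = win.species[species]
    if arr.shape[0] > n_samples:
        idx = np.linspace(0, arr.shape[0] - 1, n_samples).round().astype(int)
        arr = arr[idx]
    return arr.mean(axis=0), arr.std(axis=0)


def front_index(grid: SurfaceGrid, direction: float = 0.0) -> int:
    """Node index of the cell front for a gradient pointing at ``direction``."""
    if grid.kind is GridKind.CIRCLE:
        delta = np.angle(np.exp(1j * (grid.theta - direction)))
        return int(np.argmin(np.abs(delta)))
    # axisymmetric: front at z=1 unless the gradient is reversed
    return int(np.argmax(grid.z)) if np.cos(direction) >= 0 else int(np.argmin(grid.z))


def front_value(values: np.ndarray, grid: SurfaceGrid, direction: float = 0.0):
    """Marker value at the front of the cell (positional, not the peak)."""
    return np.asarray(values, dtype=float)[..., front_index(grid, direction)]


def output_noise(
    traj: Trajectory,
    stage: int | None = None,
    window_s: float = 100.0,
    direction: float = 0.0,
) -> np.ndarray | float:
    """Temporal std of the front value over the stationary window."""
    if stage is None:
        stage = max(int(k[2:]) for k in traj.species if k.startswith("af"))
    name = f"af{stage}"
    if name in traj.species and direction == 0.0:
        _, std = stationary_stats(traj, name, window_s=window_s)
        return std
    a = traj.species[f"a{stage}"]
    af = front_value(a, traj.grid, direction)
    t_end = traj.times[-1]
    mask = traj.times >= t_end - window_s
    return af[mask].std(axis=0)


def polarization_direction(
    values: np.ndarray, grid: SurfaceGrid, tol: float = 1e-9
):
    """Direction of the weighted circular centre of mass of a field.

    ``theta_pol = atan2(sum w f sin(theta), sum w f cos(theta))``.  For a
    field with no detectable anisotropy (resultant below ``tol`` times
    the total mass) the direction is undefined and an error is raised
    (scalar input) or ``nan`` returned (batched input).
    """
    v = np.asarray(values, dtype=float)
    w = grid.quad_weights
    theta = grid.theta if grid.kind is GridKind.CIRCLE else grid.node_coords
    c = (v * w * np.cos(theta)).sum(axis=-1)
    s = (v * w * np.sin(theta)).sum(axis=-1)
    mass = np.abs(v * w).sum(axis=-1)
    resultant = np.hypot(c, s)
    undefined = resultant < tol * np.maximum(mass, np.finfo(float).tiny)
    if v.ndim == 1:
        if undefined:
            raise UndefinedDirectionError(
                "field is uniform to tolerance; polarization direction undefined")
        return float(np.arctan2(s, c))
    out = np.arctan2(s, c)
    return np.where(undefined, np.nan, out)


def directional_accuracy(theta_pol, theta_gradient) -> np.ndarray | float:
    """cos(theta) between polarization and gradient directions."""
    return np.cos(np.asarray(theta_pol) - theta_gradient)


def normalized_polarization(a_f, cos_theta, k_ss: float = 1.0):
    """Combined score ``(a_f - k_ss) * cos(theta)``.

    Polarization extent above the adapted baseline, projected onto the
    gradient direction; 0 for an unpolarized or orthogonal response.
    """
    return (np.asarray(a_f) - k_ss) * np.asarray(cos_theta)


@dataclass
class PolarityMetrics:
    """Bundle of the polarity statistics for one run."""

    a_f: float
    sigma_out: float | None = None
    theta_pol: float | None = None
    cos_theta: float | None = None
    a_f_norm: float | None = None
    t_s: float | None = None
    abar_profile: np.ndarray | None = None


def count_peaks(values: np.ndarray, grid: SurfaceGrid,
                threshold: float = 1.3) -> int:
    """Number of contiguous regions exceeding ``threshold`` x the mean.

    Used to classify polarization phenotypes (0 = unpolarized, 1 =
    single peak, >1 = multiple peaks); regions wrap around on periodic
    (circle) grids.
    """
    v = np.asarray(values, dtype=float)
    hi = v > threshold * v.mean()
    if not hi.any():
        return 0
    if hi.all():
        return 1
    edges = np.diff(hi.astype(int))
    n_up = int((edges == 1).sum())
    if grid.kind is GridKind.CIRCLE:
        if not hi[0] and hi[-1]:
            pass  # the wrap-around region's rise is counted by edges
        elif hi[0] and not hi[-1]:
            n_up += 1  # region starting at index 0
    else:
        if hi[0]:
            n_up += 1
    return max(n_up, 1)


# ---------------------------------------------------------------------------
# settling-time protocol (noise-free step response + 180 degree reversal)
# ---------------------------------------------------------------------------

@dataclass
class SettlingResult:
    t_s: float
    t_initial: float
    t_switch: float
    a_f_steady: float
    times: np.ndarray | None = None
    a_f_trace: np.ndarray | None = None


def _settle_once(stepper, a, b, u, front, dt, band_frac, band_mode,
                 max_time, converge_tol=1e-7, check_every=2.0):
    """Run to steady state, then locate the last exit from the 5% band."""
    af0 = a[-1][front]
    trace = [af0]
    n_check = max(1, int(round(check_every / dt)))
    n_max = int(round(max_time / dt))
    prev = af0
    steady = None
    for k in range(n_max):
        a, b = stepper.step(a, b, u, k * dt)
        trace.append(a[-1][front])
        if (k + 1) % n_check == 0:
            cur = trace[-1]
            if abs(cur - prev) < converge_tol * max(1.0, abs(cur)):
                steady = cur
                break
            prev = cur
    if steady is None:
        resid = abs(trace[-1] - prev)
        raise SettlingTimeoutError(
            f"no steady state within {max_time} s (residual {resid:.3g})", resid)
    trace = np.asarray(trace)
    transition = abs(steady - af0)
    ref = transition if band_mode == "transition" else abs(steady)
    band = band_frac * max(ref, np.finfo(float).tiny)
    outside = np.abs(trace - steady) > band
    t_settle = (int(np.max(np.nonzero(outside)[0])) + 1) * dt if outside.any() else 0.0
    return t_settle, steady, trace, (a, b)


def settling_time(
    model,
    gradient: GradientSpec,
    grid: SurfaceGrid | None = None,
    dt: float = 0.01,
    band_frac: float = 0.05,
    band_mode: str = "transition",
    max_time: float = 2000.0,
    keep_traces: bool = False,
) -> SettlingResult:
    """Noise-free settling time of a generic model or cascade.

    Protocol: starting from the unstimulated state (``a = k_ss``
    uniform, ``b = 1``), the gradient is applied at t = 0 and
    ``t_initial`` is the last time the front value leaves a band of
    ``band_frac`` (default 5%) of the transition magnitude around its
    new steady value.  The gradient is then reversed 180 degrees and
    ``t_switch`` measured the same way at the new front.  ``t_s`` is the
    mean of the two.  ``band_mode="steady"`` measures the band relative
    to the steady-state level instead of the transition magnitude.
    """
    if band_mode not in ("transition", "steady"):
        raise ValueError("band_mode must be 'transition' or 'steady'")
    spec = _generic.as_cascade(model)
    if grid is None:
        from .geometry import make_grid
        grid = make_grid(GridKind.AXISYMMETRIC_SPHERE, 200, 2.0)
    stepper = _generic._CascadeStepper(spec, grid, dt)
    a, b = stepper.init_state()

    proc = InputProcess(gradient, NoiseSpec(sigma=0.0), grid)
    u_fwd = proc.deterministic(0.0)
    rev = GradientSpec(gradient.L_mid, gradient.L_slp,
                       gradient.direction + np.pi)
    u_rev = InputProcess(rev, NoiseSpec(sigma=0.0), grid).deterministic(0.0)

    f_fwd = front_index(grid, gradient.direction)
    f_rev = front_index(grid, gradient.direction + np.pi)

    t_init, steady, trace1, (a, b) = _settle_once(
        stepper, a, b, u_fwd, f_fwd, dt, band_frac, band_mode, max_time)
    t_switch, steady2, trace2, _ = _settle_once(
        stepper, a, b, u_rev, f_rev, dt, band_frac, band_mode, max_time)

    res = SettlingResult(
        t_s=0.5 * (t_init + t_switch),
        t_initial=t_init,
        t_switch=t_switch,
        a_f_steady=float(steady2),
    )
    if keep_traces:
        res.times = dt * np.arange(len(trace1) + len(trace2))
        res.a_f_trace = np.concatenate([trace1, trace2])
    return res


# ---------------------------------------------------------------------------
# Monte Carlo aggregation
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloSummary:
    """Replicate values of one metric with mean and standard error."""

    values: np.ndarray
    seeds: list[int]
    failures: list[int] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(np.std(self.values, ddof=1) / np.sqrt(len(self.values)))

    @property
    def complete(self) -> bool:
        return not self.failures


def monte_carlo(
    replicate: Callable[[int], float],
    n_replicates: int,
    seed_base: int = 0,
    seeds: Sequence[int] | None = None,
) -> MonteCarloSummary:
    """Run ``replicate(seed)`` for n independent seeds and aggregate.

    Seeds are ``seed_base + i`` unless given explicitly; a failed
    replicate is recorded in ``failures`` and excluded from the mean, so
    an incomplete summary is visible rather than silent.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if seeds is None:
        seeds = [seed_base + i for i in range(n_replicates)]
    values, ok_seeds, failures = [], [], []
    for s in seeds:
        try:
            values.append(float(replicate(int(s))))
            ok_seeds.append(int(s))
        except Exception:
            failures.append(int(s))
    return MonteCarloSummary(np.asarray(values), ok_seeds, failures)
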