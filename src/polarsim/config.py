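"""YAML/JSON configuration loading for simulation inputs.

A config file describes the three input blocks::

    grid:     {kind: circle, n: 200, radius_um: 2.0}
    gradient: {L_mid: 10.0, L_slp: 0.01, direction_deg: 0.0,
               switches: [[300.0, 180.0]]}
    noise:    {sigma: 1.0, distribution: normal, dt: 0.01, seed: 0}

Any block may be omitted, in which case package defaults apply.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .geometry import SurfaceGrid, make_grid
from .inputs import GradientSpec, InputProcess, NoiseSpec


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def grid_from_config(cfg: dict) -> SurfaceGrid:
    c = cfg.get("grid", {})
    return make_grid(c.get("kind", "circle"), int(c.get("n", 200)),
                     float(c.get("radius_um", 2.0)))


def gradient_from_config(cfg: dict) -> GradientSpec:
    c = cfg.get("gradient", {})
    switches = tuple(
        (float(t), np.deg2rad(float(d))) for t, d in c.get("switches", [])
    )
    return GradientSpec(
        L_mid=float(c.get("L_mid", 1.0)),
        L_slp=float(c.get("L_slp", 0.0)),
        direction=np.deg2rad(float(c.get("direction_deg", 0.0))),
        switch_schedule=switches,
    )


def noise_from_config(cfg: dict) -> NoiseSpec:
    c = cfg.get("noise", {})
    return NoiseSpec(
        sigma=float(c.get("sigma", 0.0)),
        distribution=c.get("distribution", "normal"),
        noise_dt=float(c.get("dt", 0.01)),
        seed=int(c.get("seed", 0)),
    )


def input_process_from_config(cfg: dict) -> InputProcess:
    grid = grid_from_config(cfg)
    return InputProcess(gradient_from_config(cfg), noise_from_config(cfg), grid)
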