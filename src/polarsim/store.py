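"""Structured result store: trajectories and metric tables on disk.

Trajectories go to an HDF5 container (one group per trajectory, one
dataset per species, grid metadata as attributes); metric tables are
written as flat CSV plus a JSON summary so results can be inspected
without any custom tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import GridKind, SurfaceGrid, Trajectory, make_grid


def save_trajectory(path: str | Path, traj: Trajectory, name: str = "trajectory",
                    mode: str = "a") -> None:
    """Write a trajectory to an HDF5 file under group ``name``."""
    with h5py.File(path, mode) as fh:
        if name in fh:
            del fh[name]
        grp = fh.create_group(name)
        grp.create_dataset("times", data=traj.times)
        sp = grp.create_group("species")
        for key, arr in traj.species.items():
            sp.create_dataset(key, data=arr, compression="gzip", compression_opts=1)
        for key, val in traj.grid.metadata().items():
            grp.attrs[f"grid_{key}"] = val
        if traj.rng_seed is not None:
            grp.attrs["rng_seed"] = traj.rng_seed
        meta = {k: v for k, v in traj.metadata.items()
                if isinstance(v, (str, int, float, bool, list, tuple))}
        grp.attrs["metadata_json"] = json.dumps(meta)


def load_trajectory(path: str | Path, name: str = "trajectory") -> Trajectory:
    with h5py.File(path, "r") as fh:
        grp = fh[name]
        grid = make_grid(GridKind(grp.attrs["grid_kind"]),
                         int(grp.attrs["grid_n_points"]),
                         float(grp.attrs["grid_radius_um"]))
        species = {k: np.asarray(v) for k, v in grp["species"].items()}
        traj = Trajectory(
            np.asarray(grp["times"]), species, grid,
            rng_seed=int(grp.attrs["rng_seed"]) if "rng_seed" in grp.attrs else None,
            metadata=json.loads(grp.attrs.get("metadata_json", "{}")),
        )
    return traj


def write_results_table(path: str | Path, table, summary: dict | None = None) -> None:
    """Write a long-format metrics DataFrame as CSV (+ JSON summary)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if summary is not None:
        path.with_suffix(".json").write_text(json.dumps(summary, indent=2,
                                                        default=float))
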