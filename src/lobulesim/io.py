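"""Run output: legacy-ASCII VTK field snapshots, CSV time series, manifests."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from .lattice import LobuleLattice

__all__ = ["write_vtk_structured", "write_outputs"]


def _vtk_order(field: np.ndarray, shape) -> np.ndarray:
    """Reorder a z-fastest raveled grid field to VTK's x-fastest layout."""
    return np.transpose(np.asarray(field).reshape(shape), (2, 1, 0)).ravel()


def write_vtk_structured(
    path,
    dims: tuple[int, int, int],
    spacing: float,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write a legacy-ASCII VTK structured-points snapshot.

    ``dims`` counts cells; point fields live on the ``(nx+1, ny+1, nz+1)``
    junction grid (z-fastest raveling, as used throughout the package) and
    cell fields on the ``(nx, ny, nz)`` cell grid.
    """
    nx, ny, nz = dims
    lines = [
        "# vtk DataFile Version 3.0",
        "lobulesim field snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing} {spacing} {spacing}",
    ]

    def emit(data, n, header):
        lines.append(header.format(n=n))
        for name, field in data.items():
            shape = (nx + 1, ny + 1, nz + 1) if n == (nx + 1) * (ny + 1) * (nz + 1) else (nx, ny, nz)
            vals = _vtk_order(field, shape)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(f"{v:.9g}" for v in vals[i : i + 6]) for i in range(0, len(vals), 6))

    if point_data:
        emit(point_data, (nx + 1) * (ny + 1) * (nz + 1), "POINT_DATA {n}")
    if cell_data:
        emit(cell_data, nx * ny * nz, "CELL_DATA {n}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_outputs(
    out_dir,
    timeseries=None,
    snapshots=None,
    lattice: LobuleLattice | None = None,
    config=None,
    seeds: dict | None = None,
    extra: dict | None = None,
) -> dict:
    """Write a run directory and return its manifest.

    ``timeseries`` is a DataFrame (written as ``timeseries.csv``);
    ``snapshots`` a list of ``(label, point_data, cell_data)`` tuples, one
    VTK file each (requires ``lattice`` for grid geometry).  The manifest
    (``manifest.json``) records files, seeds, the resolved config and any
    extra entries (residuals, wall time).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    if timeseries is not None:
        ts_path = out / "timeseries.csv"
        timeseries.to_csv(ts_path, index=False)
        files.append(ts_path.name)
    for label, point_data, cell_data in snapshots or []:
        if lattice is None:
            raise ValueError("snapshots require the lattice for grid geometry")
        p = out / f"{label}.vtk"
        write_vtk_structured(p, lattice.dims, lattice.cell.pitch, point_data, cell_data)
        files.append(p.name)
    if config is not None:
        from .config import save_config

        save_config(config, out / "config.yaml")
        files.append("config.yaml")
    from . import __version__

    manifest = {
        "version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": sorted(files),
        "seeds": seeds or {},
        **(extra or {}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
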