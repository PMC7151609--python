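"""Seeded test fixtures: reduced-scale geometries with known behavior.

- ``chain``: a 1x1xn duct whose four corner chains are symmetric, so every
  axial segment carries the closed-form series-path flux and transport
  reduces to plug flow — the analytic oracle geometry.
- ``tiny_lobule``: a 6x6x6 lobule with the standard four-inlet/one-outlet
  port layout, small enough for brute-force cross-checks.
- ``column``: a 1x1xn stack for confined (uniaxial) consolidation runs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import ScenarioConfig
from .lattice import LobuleLattice, UnitCell, _assemble_raw, _junction_index, assemble_lobule, build_unit_cell
from .properties import FlowProperties

__all__ = ["generate_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("chain", "tiny_lobule", "column")


def _build_duct(cell: UnitCell, n: int) -> LobuleLattice:
    """1x1xn duct: four singleton inlets at the z=0 corners, outlet at z=n.

    By symmetry the four vertical corner chains carry equal flow and the
    horizontal rungs none, so each axial segment obeys the series-path
    closed form.
    """
    dims = (1, 1, n)
    base = _assemble_raw(cell, dims)
    jidx = lambda i, j, k: _junction_index(dims, i, j, k)
    inlets = tuple(np.array([jidx(i, j, 0)]) for (i, j) in ((0, 0), (1, 0), (0, 1), (1, 1)))
    outlet = np.array([jidx(i, j, n) for (i, j) in ((0, 0), (1, 0), (0, 1), (1, 1))])
    return replace(base, inlet_ports=inlets, outlet_port=outlet)


def generate_fixture(
    name: str, seed: int = 0, n: int | None = None, properties: FlowProperties | None = None
) -> tuple[LobuleLattice, ScenarioConfig]:
    """Build a named fixture lattice plus a matching scenario config."""
    props = properties or FlowProperties()
    cell = build_unit_cell(props)
    if name == "chain":
        n = n or 10
        lat = _build_duct(cell, n)
        dims = (1, 1, n)
    elif name == "tiny_lobule":
        n = n or 6
        lat = assemble_lobule(cell, (n, n, n))
        dims = (n, n, n)
    elif name == "column":
        n = n or 16
        lat = _build_duct(cell, n)
        dims = (1, 1, n)
    else:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    config = ScenarioConfig.model_validate({"lattice": {"dims": list(dims), "master_seed": seed}})
    return lat, config
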