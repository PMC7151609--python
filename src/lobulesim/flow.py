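"""Steady incompressible Darcy flow on the dual-compartment lobule lattice.

Pressure unknowns live on sinusoid junctions and tissue nodes.  Sinusoid
segments conduct with their Poiseuille-derived permeability over the square
channel cross-section; face-adjacent tissue cubes conduct with the
Carman-Kozeny tissue permeability; tissue nodes exchange with each adjacent
sinusoid segment through a Warren-Root-style shape-factor conductance
(tissue mobility x contact area / half pitch), split symmetrically between
the segment's two endpoint junctions.  The inlet ports are held at the
prescribed portal-central pressure drop above the outlet port; all other
boundaries are closed.  Units: um, Pa, min (fluxes in um^3/min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .lattice import LobuleLattice, apply_percolation
from .properties import InvalidParameterError

__all__ = [
    "FlowSolution",
    "MissingBoundaryError",
    "solve_steady_flow",
    "flow_vs_percolation",
    "nodal_imbalance",
]

_SEC_PER_MIN = 60.0


class MissingBoundaryError(RuntimeError):
    """The pressure system has no Dirichlet boundary and is singular."""


@dataclass(frozen=True)
class FlowSolution:
    """Nodal pressures and volumetric fluxes of a steady Darcy solve."""

    junction_pressure: np.ndarray  # (J,) Pa
    tissue_pressure: np.ndarray  # (C,) Pa
    segment_flux: np.ndarray  # (E,) um^3/min, signed a->b
    exchange_flux: np.ndarray  # (C, 12) um^3/min, signed tissue->segment
    inlet_rates: np.ndarray  # (4,) um^3/min into the lattice
    outlet_rate: float  # um^3/min out of the lattice
    residual: float  # relative linear-system residual
    spanning: bool  # inlet-outlet sinusoid connectivity existed
    delta_p: float  # applied pressure drop, Pa

    @property
    def total_inlet_rate(self) -> float:
        return float(self.inlet_rates.sum())


def _conductances(lattice: LobuleLattice, viscosity: float):
    """Per-segment, tissue-tissue and exchange conductances in um^3/(Pa min)."""
    cell = lattice.cell
    mu_min = viscosity / _SEC_PER_MIN  # Pa min
    g_seg = lattice.segment_permeability() * cell.channel_area / (mu_min * cell.pitch)
    k_tis = cell.properties.tissue_permeability
    g_tis = k_tis * cell.tissue_edge**2 / (mu_min * cell.pitch)
    # Shape factor: tissue mobility x contact area / half-pitch per cell-segment link.
    contact = cell.tissue_edge * cell.sinusoid_channel_width
    g_ex = k_tis * contact / (mu_min * 0.5 * cell.pitch)
    return g_seg, g_tis, g_ex


def _port_connected_segments(lattice: LobuleLattice) -> tuple[np.ndarray, bool]:
    """Active segments whose sinusoid component touches a port; spanning flag."""
    adj = lattice.sinusoid_adjacency(active_only=True)
    _, labels = connected_components(adj, directed=False)
    port_labels = set(labels[lattice.port_junctions()])
    outlet_labels = set(labels[lattice.outlet_port])
    spanning = any(
        bool(outlet_labels.intersection(labels[p])) for p in lattice.inlet_ports
    )
    seg_ok = lattice.active & np.isin(labels[lattice.segments[:, 0]], sorted(port_labels))
    return seg_ok, spanning


def solve_steady_flow(
    lattice: LobuleLattice,
    delta_p: float = 100.0,
    viscosity: float | None = None,
    tol: float = 1e-10,
) -> FlowSolution:
    """Solve steady Darcy flow at a fixed inlet-outlet pressure drop.

    Inlet junctions are held at ``delta_p`` Pa, outlet junctions at 0 Pa.
    Sinusoid components not connected to any port are excluded and carry
    exactly zero flux; if no inlet-outlet spanning cluster exists the
    zero-flow solution is returned with ``spanning=False`` and a warning.
    """
    if delta_p < 0.0:
        raise InvalidParameterError(f"pressure drop must be >= 0, got {delta_p}")
    if viscosity is None:
        viscosity = lattice.cell.properties.blood_viscosity
    if viscosity <= 0.0:
        raise InvalidParameterError(f"viscosity must be positive, got {viscosity}")
    if min(len(p) for p in lattice.inlet_ports) == 0:
        raise MissingBoundaryError("missing boundary: an inlet port set is empty")
    if len(lattice.outlet_port) == 0:
        raise MissingBoundaryError("missing boundary: the outlet port set is empty")

    nj, nc = lattice.n_junctions, lattice.n_cells
    seg_ok, spanning = _port_connected_segments(lattice)
    zero = FlowSolution(
        junction_pressure=np.zeros(nj),
        tissue_pressure=np.zeros(nc),
        segment_flux=np.zeros(lattice.n_segments),
        exchange_flux=np.zeros((nc, 12)),
        inlet_rates=np.zeros(4),
        outlet_rate=0.0,
        residual=0.0,
        spanning=spanning,
        delta_p=delta_p,
    )
    if not spanning:
        warnings.warn(
            "no inlet-outlet spanning sinusoid cluster; returning zero-flow solution",
            stacklevel=2,
        )
        return zero

    g_seg, g_tis, g_ex = _conductances(lattice, viscosity)
    n = nj + nc  # tissue node c -> unknown nj + c

    rows, cols, vals = [], [], []

    def add_links(a, b, g):
        rows.extend((a, b, a, b))
        cols.extend((a, b, b, a))
        vals.extend((g, g, -g, -g))

    seg = lattice.segments[seg_ok]
    add_links(seg[:, 0], seg[:, 1], g_seg[seg_ok])

    pairs = lattice.tissue_neighbor_pairs()
    gt = np.full(len(pairs), g_tis)
    add_links(nj + pairs[:, 0], nj + pairs[:, 1], gt)

    # Exchange half-links: tissue node to each endpoint of its port-connected segments.
    cs = lattice.cell_segments  # (C, 12)
    link_ok = seg_ok[cs]
    cidx, lidx = np.nonzero(link_ok)
    sidx = cs[cidx, lidx]
    for end in (0, 1):
        add_links(nj + cidx, lattice.segments[sidx, end], np.full(len(cidx), 0.5 * g_ex))

    rows = np.concatenate(rows) if rows and isinstance(rows[0], np.ndarray) else np.asarray(rows)
    cols = np.concatenate(cols) if cols and isinstance(cols[0], np.ndarray) else np.asarray(cols)
    vals = np.concatenate(vals) if vals and isinstance(vals[0], np.ndarray) else np.asarray(vals)
    lap = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    inlet_all = np.concatenate(lattice.inlet_ports)
    dirichlet = np.zeros(n, dtype=bool)
    dirichlet[inlet_all] = True
    dirichlet[lattice.outlet_port] = True
    p_fix = np.zeros(n)
    p_fix[inlet_all] = delta_p

    # Unknowns: non-Dirichlet nodes with at least one conductance link.
    degree = np.asarray(abs(lap).sum(axis=1)).ravel()
    free = (~dirichlet) & (degree > 0)

    p = p_fix.copy()
    if free.any():
        a_ff = lap[free][:, free].tocsc()
        b = -(lap[free][:, dirichlet] @ p_fix[dirichlet])
        x = splu(a_ff).solve(b)
        res = np.linalg.norm(a_ff @ x - b)
        scale = np.linalg.norm(b)
        residual = res / scale if scale > 0 else res
        if residual > tol:  # pragma: no cover - direct solver, defensive
            raise RuntimeError(f"flow solve residual {residual:.3e} exceeds tol {tol:.3e}")
        p[free] = x
    else:
        residual = 0.0

    net_out = lap @ p  # net volumetric outflow per node
    pj, pt = p[:nj], p[nj:]

    segment_flux = np.zeros(lattice.n_segments)
    segment_flux[seg_ok] = g_seg[seg_ok] * (pj[seg[:, 0]] - pj[seg[:, 1]])

    exchange = np.zeros((nc, 12))
    pa = pj[lattice.segments[cs[cidx, lidx], 0]]
    pb = pj[lattice.segments[cs[cidx, lidx], 1]]
    exchange[cidx, lidx] = 0.5 * g_ex * (2.0 * pt[cidx] - pa - pb)

    inlet_rates = np.array([float(net_out[port].sum()) for port in lattice.inlet_ports])
    outlet_rate = -float(net_out[lattice.outlet_port].sum())

    return FlowSolution(
        junction_pressure=pj,
        tissue_pressure=pt,
        segment_flux=segment_flux,
        exchange_flux=exchange,
        inlet_rates=inlet_rates,
        outlet_rate=outlet_rate,
        residual=float(residual),
        spanning=True,
        delta_p=delta_p,
    )


def nodal_imbalance(lattice: LobuleLattice, sol: FlowSolution) -> float:
    """Worst interior-node flux imbalance relative to the total inlet rate.

    Sums signed segment fluxes and tissue-sinusoid exchange fluxes into every
    node; ports are excluded (they exchange with the outside).
    """
    nj, nc = lattice.n_junctions, lattice.n_cells
    div = np.zeros(nj + nc)
    seg = lattice.segments
    np.add.at(div, seg[:, 0], sol.segment_flux)
    np.add.at(div, seg[:, 1], -sol.segment_flux)
    # Exchange half-link fluxes from the stored pressures (the per-link total
    # in sol.exchange_flux does not resolve the two endpoints).
    _, _, g_ex = _conductances(lattice, lattice.cell.properties.blood_viscosity)
    seg_ok, _ = _port_connected_segments(lattice)
    cs = lattice.cell_segments
    link_ok = seg_ok[cs]
    cidx, lidx = np.nonzero(link_ok)
    sidx = cs[cidx, lidx]
    pj, pt = sol.junction_pressure, sol.tissue_pressure
    for end in (0, 1):
        ends = seg[sidx, end]
        q_half = 0.5 * g_ex * (pt[cidx] - pj[ends])
        np.add.at(div, nj + cidx, q_half)
        np.add.at(div, ends, -q_half)
    # Tissue-tissue neighbor fluxes.
    pairs = lattice.tissue_neighbor_pairs()
    g_seg_all, g_tis, _ = _conductances(lattice, lattice.cell.properties.blood_viscosity)
    q_t = g_tis * (pt[pairs[:, 0]] - pt[pairs[:, 1]])
    np.add.at(div, nj + pairs[:, 0], q_t)
    np.add.at(div, nj + pairs[:, 1], -q_t)
    div[lattice.port_junctions()] = 0.0
    scale = max(abs(sol.total_inlet_rate), 1e-300)
    return float(np.max(np.abs(div))) / scale


def flow_vs_percolation(
    lattice: LobuleLattice,
    fractions=(1.0, 0.7, 0.4, 0.2),
    seeds=(0, 1, 2, 3, 4),
    delta_p: float = 100.0,
    viscosity: float | None = None,
) -> pd.DataFrame:
    """Inlet flow rates across percolation fractions and percolation seeds.

    Returns one row per (fraction, seed) with the four per-port inlet rates
    and the total; fibrotic occlusion of sinusoid segments reduces the
    portal inflow at fixed pressure drop.
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise InvalidParameterError(f"percolation fraction must lie in (0, 1], got {f}")
    rows = []
    for frac in fractions:
        for seed in seeds:
            lat = apply_percolation(lattice, frac, seed) if frac < 1.0 else lattice
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = solve_steady_flow(lat, delta_p=delta_p, viscosity=viscosity)
            rows.append(
                {
                    "fraction": frac,
                    "seed": seed,
                    "inlet_0": sol.inlet_rates[0],
                    "inlet_1": sol.inlet_rates[1],
                    "inlet_2": sol.inlet_rates[2],
                    "inlet_3": sol.inlet_rates[3],
                    "total_inlet": sol.total_inlet_rate,
                    "spanning": sol.spanning,
                }
            )
    return pd.DataFrame(rows)
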