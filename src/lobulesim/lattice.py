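"""Unit cell and lobule lattice geometry.

The basic conceptual unit is a hepatocyte + ECM tissue cube (24 um edge)
wrapped by sinusoid channel segments (6 um square cross-section, i.e. a
3 um-radius tube) running along the 12 edges of the 30 um cell.  A lobule is
an ``nx x ny x nz`` stack of these units: sinusoid segments form a cubic bond
lattice between junction points, each cell carries one tissue node coupled to
its adjacent segments by a dual-continuum exchange coefficient, blood enters
at four portal (corner-column) inlet ports and leaves at one central-column
outlet.  Fibrosis is modelled by bond percolation (random removal of sinusoid
segments) and optional random per-segment permeability heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .properties import FlowProperties, InvalidParameterError

__all__ = [
    "UnitCell",
    "LobuleLattice",
    "build_unit_cell",
    "assemble_lobule",
    "apply_percolation",
    "spanning_clusters",
    "randomize_segment_permeability",
]


@dataclass(frozen=True)
class UnitCell:
    """The repeating lobule element: tissue cube + edge sinusoid channels."""

    properties: FlowProperties
    tissue_edge: float = 24.0  # um
    sinusoid_channel_width: float = 6.0  # um, = 2R

    def __post_init__(self) -> None:
        if self.tissue_edge <= 0.0 or self.sinusoid_channel_width <= 0.0:
            raise InvalidParameterError("unit-cell dimensions must be positive")

    @property
    def pitch(self) -> float:
        """Lattice spacing: tissue edge plus one channel width (um)."""
        return self.tissue_edge + self.sinusoid_channel_width

    @property
    def channel_area(self) -> float:
        """Square channel cross-section (um^2)."""
        return self.sinusoid_channel_width**2

    @property
    def tissue_volume(self) -> float:
        return self.tissue_edge**3

    @property
    def sinusoid_volume(self) -> float:
        """Sinusoid volume owned per cell: 12 edges shared 4-fold -> 3 segments."""
        return 3.0 * self.pitch * self.channel_area

    def volume_fractions(self) -> tuple[float, float]:
        """(sinusoid, tissue) fractions of the accounted cell volume; sum to 1."""
        total = self.sinusoid_volume + self.tissue_volume
        return self.sinusoid_volume / total, self.tissue_volume / total


def build_unit_cell(
    params: FlowProperties, tissue_edge: float = 24.0, channel_width: float | None = None
) -> UnitCell:
    """Construct the unit cell; channel width defaults to 2x the tube radius."""
    if channel_width is None:
        channel_width = 2.0 * params.sinusoid_radius
    return UnitCell(properties=params, tissue_edge=tissue_edge, sinusoid_channel_width=channel_width)


@dataclass(frozen=True)
class LobuleLattice:
    """Assembled dual-compartment lobule lattice.

    Sinusoid junctions live on the ``(nx+1, ny+1, nz+1)`` integer grid with
    spacing ``cell.pitch``; segments are the grid bonds, ordered x-family,
    y-family, z-family in lexicographic junction order.  Tissue nodes are one
    per cell.  ``active`` marks segments retained by percolation and
    ``perm_factor`` holds the per-segment heterogeneity multiplier.
    """

    cell: UnitCell
    dims: tuple[int, int, int]
    segments: np.ndarray  # (E, 2) junction indices
    cell_segments: np.ndarray  # (C, 12) segment indices per cell
    inlet_ports: tuple[np.ndarray, ...]  # 4 junction-index arrays
    outlet_port: np.ndarray  # junction-index array
    active: np.ndarray  # (E,) bool
    perm_factor: np.ndarray  # (E,) float, unit mean
    percolation_fraction: float = 1.0
    seed: int | None = None

    @property
    def n_junctions(self) -> int:
        nx, ny, nz = self.dims
        return (nx + 1) * (ny + 1) * (nz + 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_active_segments(self) -> int:
        return int(self.active.sum())

    def junction_coords(self) -> np.ndarray:
        """(J, 3) junction positions in um."""
        nx, ny, nz = self.dims
        idx = np.indices((nx + 1, ny + 1, nz + 1)).reshape(3, -1).T
        return idx.astype(float) * self.cell.pitch

    def cell_coords(self) -> np.ndarray:
        """(C, 3) tissue-node (cell-center) positions in um."""
        nx, ny, nz = self.dims
        idx = np.indices((nx, ny, nz)).reshape(3, -1).T
        return (idx.astype(float) + 0.5) * self.cell.pitch

    def segment_permeability(self) -> np.ndarray:
        """Per-segment permeability (um^2) including heterogeneity factors."""
        return self.cell.properties.sinusoid_permeability * self.perm_factor

    def port_junctions(self) -> np.ndarray:
        return np.concatenate([*self.inlet_ports, self.outlet_port])

    def sinusoid_adjacency(self, active_only: bool = True) -> sparse.csr_matrix:
        """Unweighted junction adjacency of the sinusoid graph."""
        seg = self.segments[self.active] if active_only else self.segments
        n = self.n_junctions
        data = np.ones(len(seg))
        a = sparse.coo_matrix((data, (seg[:, 0], seg[:, 1])), shape=(n, n))
        return (a + a.T).tocsr()

    def tissue_neighbor_pairs(self) -> np.ndarray:
        """(P, 2) cell-index pairs of face-adjacent tissue cubes."""
        nx, ny, nz = self.dims
        grid = np.arange(self.n_cells).reshape(nx, ny, nz)
        pairs = []
        for ax in range(3):
            a = np.moveaxis(grid, ax, 0)
            pairs.append(np.stack([a[:-1].ravel(), a[1:].ravel()], axis=1))
        return np.concatenate(pairs, axis=0)

    def save_npz(self, path) -> None:
        """Serialize to a .npz container of named arrays."""
        np.savez_compressed(
            path,
            dims=np.asarray(self.dims),
            tissue_edge=self.cell.tissue_edge,
            channel_width=self.cell.sinusoid_channel_width,
            properties=np.array(
                [
                    self.cell.properties.sinusoid_radius,
                    self.cell.properties.sinusoid_porosity,
                    self.cell.properties.sinusoid_permeability,
                    self.cell.properties.tissue_porosity,
                    self.cell.properties.tissue_permeability,
                    self.cell.properties.sinusoid_diffusion,
                    self.cell.properties.tissue_diffusion,
                    self.cell.properties.blood_viscosity,
                    self.cell.properties.fiber_diameter,
                    self.cell.properties.fiber_length,
                ]
            ),
            segments=self.segments,
            cell_segments=self.cell_segments,
            inlet_sizes=np.array([len(p) for p in self.inlet_ports]),
            inlets=np.concatenate(self.inlet_ports),
            outlet=self.outlet_port,
            active=self.active,
            perm_factor=self.perm_factor,
            percolation_fraction=self.percolation_fraction,
            seed=-1 if self.seed is None else self.seed,
        )

    @staticmethod
    def load_npz(path) -> "LobuleLattice":
        with np.load(path) as z:
            p = z["properties"]
            props = FlowProperties(
                sinusoid_radius=float(p[0]),
                sinusoid_porosity=float(p[1]),
                sinusoid_permeability=float(p[2]),
                tissue_porosity=float(p[3]),
                tissue_permeability=float(p[4]),
                sinusoid_diffusion=float(p[5]),
                tissue_diffusion=float(p[6]),
                blood_viscosity=float(p[7]),
                fiber_diameter=float(p[8]),
                fiber_length=float(p[9]),
            )
            cell = UnitCell(props, float(z["tissue_edge"]), float(z["channel_width"]))
            sizes = z["inlet_sizes"]
            splits = np.cumsum(sizes)[:-1]
            inlets = tuple(np.split(z["inlets"], splits))
            seed = int(z["seed"])
            return LobuleLattice(
                cell=cell,
                dims=tuple(int(d) for d in z["dims"]),
                segments=z["segments"],
                cell_segments=z["cell_segments"],
                inlet_ports=inlets,
                outlet_port=z["outlet"],
                active=z["active"],
                perm_factor=z["perm_factor"],
                percolation_fraction=float(z["percolation_fraction"]),
                seed=None if seed < 0 else seed,
            )


def _junction_index(dims, i, j, k):
    _, ny, nz = dims
    return (i * (ny + 1) + j) * (nz + 1) + k


def assemble_lobule(cell: UnitCell, dims: tuple[int, int, int] = (50, 50, 50)) -> LobuleLattice:
    """Assemble the lobule lattice from ``dims`` unit cells.

    Ports follow the idealized lobule layout: four portal inlets at the
    vertical corner columns of boundary junctions and one central-column
    outlet (the pericentral vein).
    """
    if min(dims) < 2:
        raise InvalidParameterError(f"lattice dims must be at least (2, 2, 2), got {dims}")
    return _assemble_raw(cell, dims)


def _assemble_raw(cell: UnitCell, dims: tuple[int, int, int]) -> LobuleLattice:
    """Assembly body without the minimum-size check (fixtures use 1x1xn)."""
    nx, ny, nz = dims
    jidx = lambda i, j, k: _junction_index(dims, i, j, k)

    # Segment families: x-edges, y-edges, z-edges, lexicographic.
    segs = []
    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny + 1), np.arange(nz + 1), indexing="ij")
    segs.append(np.stack([jidx(I, J, K).ravel(), jidx(I + 1, J, K).ravel()], axis=1))
    I, J, K = np.meshgrid(np.arange(nx + 1), np.arange(ny), np.arange(nz + 1), indexing="ij")
    segs.append(np.stack([jidx(I, J, K).ravel(), jidx(I, J + 1, K).ravel()], axis=1))
    I, J, K = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1), np.arange(nz), indexing="ij")
    segs.append(np.stack([jidx(I, J, K).ravel(), jidx(I, J, K + 1).ravel()], axis=1))
    segments = np.concatenate(segs, axis=0)

    ex = nx * (ny + 1) * (nz + 1)
    ey = (nx + 1) * ny * (nz + 1)

    def xseg(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    def yseg(i, j, k):
        return ex + (i * ny + j) * (nz + 1) + k

    def zseg(i, j, k):
        return ex + ey + (i * (ny + 1) + j) * nz + k

    # 12 edges per cell (i, j, k): 4 per direction family.
    ci, cj, ck = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    cols = []
    for b in (0, 1):
        for c in (0, 1):
            cols.append(xseg(ci, cj + b, ck + c))
    for b in (0, 1):
        for c in (0, 1):
            cols.append(yseg(ci + b, cj, ck + c))
    for b in (0, 1):
        for c in (0, 1):
            cols.append(zseg(ci + b, cj + c, ck))
    cell_segments = np.stack(cols, axis=1)

    kk = np.arange(nz + 1)
    inlet_ports = tuple(
        jidx(i, j, kk) for (i, j) in ((0, 0), (nx, 0), (0, ny), (nx, ny))
    )
    outlet_port = jidx(nx // 2, ny // 2, kk)

    return LobuleLattice(
        cell=cell,
        dims=(nx, ny, nz),
        segments=segments,
        cell_segments=cell_segments,
        inlet_ports=inlet_ports,
        outlet_port=outlet_port,
        active=np.ones(len(segments), dtype=bool),
        perm_factor=np.ones(len(segments)),
    )


def apply_percolation(lattice: LobuleLattice, fraction: float, seed: int) -> LobuleLattice:
    """Retain a random ``fraction`` of sinusoid segments (bond percolation).

    The retained count is round-half-away-from-zero of ``fraction * E``.  A
    single seeded permutation orders the segments, and the first ``k`` are
    kept, so retained sets are nested across fractions at a fixed seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise InvalidParameterError(f"percolation fraction must lie in (0, 1], got {fraction}")
    n = lattice.n_segments
    keep = int(np.floor(fraction * n + 0.5))
    order = np.random.default_rng(seed).permutation(n)
    active = np.zeros(n, dtype=bool)
    active[order[:keep]] = True
    return replace(lattice, active=active, percolation_fraction=fraction, seed=seed)


def spanning_clusters(lattice: LobuleLattice) -> tuple[np.ndarray, bool]:
    """Connected-component labels of the active sinusoid graph.

    Returns per-junction labels and a flag that is true iff some component
    touches at least one inlet port and the outlet port (a spanning cluster
    able to carry inlet-to-outlet flow exists).
    """
    adj = lattice.sinusoid_adjacency(active_only=True)
    _, labels = connected_components(adj, directed=False)
    outlet_labels = set(labels[lattice.outlet_port])
    spanning = any(
        bool(outlet_labels.intersection(labels[port])) for port in lattice.inlet_ports
    )
    return labels, spanning


def randomize_segment_permeability(
    lattice: LobuleLattice,
    distribution: str = "lognormal",
    cv: float = 0.3,
    seed: int = 0,
) -> LobuleLattice:
    """Draw unit-mean multiplicative permeability factors per segment.

    ``lognormal``: sigma^2 = ln(1 + cv^2), mu = -sigma^2/2 (exact unit mean).
    ``uniform``: [1 - sqrt(3) cv, 1 + sqrt(3) cv], requires cv <= 1/sqrt(3)
    to keep permeabilities positive.
    """
    if cv < 0.0:
        raise InvalidParameterError(f"coefficient of variation must be >= 0, got {cv}")
    n = lattice.n_segments
    if cv == 0.0:
        return replace(lattice, perm_factor=np.ones(n))
    rng = np.random.default_rng(seed)
    if distribution == "lognormal":
        s2 = np.log1p(cv**2)
        factors = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=n)
    elif distribution == "uniform":
        half = np.sqrt(3.0) * cv
        if half >= 1.0:
            raise InvalidParameterError(
                f"uniform heterogeneity requires cv < 1/sqrt(3), got {cv}"
            )
        factors = rng.uniform(1.0 - half, 1.0 + half, size=n)
    else:
        raise InvalidParameterError(f"unknown distribution {distribution!r}")
    return replace(lattice, perm_factor=factors)
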