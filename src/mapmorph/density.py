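"""Periodic real-space density maps over a P1 unit cell.

A :class:`MapGrid` stores density values on a regular grid indexed fast->slow
along the a, b, c cell axes.  Model maps are calculated as sums of periodic
isotropic Gaussians, one per atom, with

    sigma^2 = B / (8 pi^2) + (0.356 * d_min)^2

so that thermal motion and resolution truncation both blur the atom, and with
each Gaussian integrating to (atomic number x occupancy).  This single-Gaussian
atom is the package's real-space stand-in for a structure-factor F_calc map:
peak positions and overlap maxima, which are all the morphing search uses,
depend only on smooth atom-centred density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage

from .model_io import Structure, UnitCell

__all__ = [
    "MapGrid",
    "AtomDensityModel",
    "read_map",
    "write_map",
    "calc_model_map",
    "map_correlation",
    "interpolate",
    "grid_dims_for",
]

#: Resolution-dependent blur width in the Gaussian atom model (Angstrom per
#: Angstrom of d_min); approximates Fourier truncation at the map resolution.
RESOLUTION_BLUR = 0.356

#: Gaussians are evaluated out to this many sigmas before being dropped.
GAUSSIAN_CUTOFF_SIGMAS = 4.5


@dataclass
class AtomDensityModel:
    """Isotropic Gaussian atom: width ``sigma`` (A), total integral ``amplitude``."""

    sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.amplitude <= 0:
            raise ValueError("sigma and amplitude must be positive")

    @classmethod
    def for_atom(cls, atomic_number: float, b: float, occ: float, d_min: float) -> "AtomDensityModel":
        sigma = math.sqrt(b / (8.0 * math.pi**2) + (RESOLUTION_BLUR * d_min) ** 2)
        return cls(sigma=sigma, amplitude=atomic_number * occ)

    def peak_height(self) -> float:
        return self.amplitude / (2.0 * math.pi * self.sigma**2) ** 1.5


class MapGrid:
    """Real-space density on a periodic grid covering one P1 cell.

    Values are indexed ``values[i, j, k]`` with i, j, k counting grid steps
    along the a, b, c axes respectively; the point (i, j, k) sits at
    fractional coordinates (i/na, j/nb, k/nc).
    """

    def __init__(self, cell: UnitCell, values: np.ndarray, d_min: float | None = None):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError("map values must be a 3-D array")
        if min(values.shape) < 4:
            raise ValueError("map grid must have at least 4 points per axis")
        if not np.all(np.isfinite(values)):
            raise ValueError("map contains non-finite values")
        self.cell = cell
        self.values = values
        self.d_min = d_min

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Nominal grid spacing along each cell axis (A)."""
        return np.array(self.cell.lengths()) / np.array(self.dims)

    @property
    def voxel_volume(self) -> float:
        return self.cell.to_gemmi().volume / float(np.prod(self.dims))

    def copy(self) -> "MapGrid":
        return MapGrid(self.cell, self.values.copy(), self.d_min)

    def same_frame(self, other: "MapGrid") -> bool:
        # tolerance at PDB CRYST1 precision, so cells that round-tripped
        # through coordinate or map headers still count as the same frame
        return self.dims == other.dims and np.allclose(
            self.cell.orth_matrix, other.cell.orth_matrix, atol=2e-3
        )

    # -- coordinate transforms -------------------------------------------

    def frac_from_orth(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.cell.frac_matrix.T

    def orth_from_frac(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.cell.orth_matrix.T

    def grid_from_orth(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous grid coordinates (in grid steps) of orthogonal points."""
        return self.frac_from_orth(xyz) * np.array(self.dims)

    def min_image_offsets(self, center: np.ndarray) -> np.ndarray:
        """Minimum-image orthogonal offset of every grid point from ``center``.

        Returns an array of shape dims + (3,).
        """
        na, nb, nc = self.dims
        fi = np.arange(na) / na
        fj = np.arange(nb) / nb
        fk = np.arange(nc) / nc
        cf = self.frac_from_orth(np.asarray(center, dtype=float))
        df = np.stack(np.meshgrid(fi - cf[0], fj - cf[1], fk - cf[2], indexing="ij"), axis=-1)
        df -= np.round(df)
        return df @ self.cell.orth_matrix.T


def grid_dims_for(cell: UnitCell, d_min: float, grid_factor: float) -> tuple[int, int, int]:
    """Grid sampling counts giving spacing close to ``grid_factor * d_min``.

    Flooring the count keeps the spacing at or above the requested fraction
    of d_min, so the default factor of 1/4 yields spacing within
    [d_min/4, d_min/3].
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if not 0.2 <= grid_factor <= 0.5:
        raise ValueError("grid_factor outside sensible range [0.2, 0.5]")
    dims = []
    for length in cell.lengths():
        n = max(4, int(math.floor(length / (grid_factor * d_min))))
        dims.append(n)
    return tuple(dims)  # type: ignore[return-value]


def _atomic_number(element: str) -> int:
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element {element!r}")
    return el.atomic_number


def add_atom_density(values: np.ndarray, grid: MapGrid, xyz: np.ndarray,
                     model: AtomDensityModel) -> None:
    """Accumulate one periodic Gaussian atom into ``values`` (in place).

    Only the subgrid within GAUSSIAN_CUTOFF_SIGMAS of the centre is touched;
    indices wrap periodically.
    """
    dims = np.array(grid.dims)
    spacing = grid.spacing
    cutoff = GAUSSIAN_CUTOFF_SIGMAS * model.sigma
    half = np.minimum(np.ceil(cutoff / spacing).astype(int), dims // 2)
    gpos = grid.grid_from_orth(xyz)
    lo = np.floor(gpos).astype(int) - half
    idx = [np.arange(lo[d], lo[d] + 2 * half[d] + 1) for d in range(3)]
    # orthogonal offsets of subgrid points from the atom (subgrid never wraps
    # onto itself because half <= dims//2)
    fr = [(idx[d] - gpos[d]) / dims[d] for d in range(3)]
    df = np.stack(np.meshgrid(*fr, indexing="ij"), axis=-1)
    dx = df @ grid.cell.orth_matrix.T
    r2 = np.einsum("...i,...i->...", dx, dx)
    peak = model.peak_height()
    dens = peak * np.exp(-r2 / (2.0 * model.sigma**2))
    wrapped = [np.mod(idx[d], dims[d]) for d in range(3)]
    np.add.at(values, np.ix_(*wrapped), dens)


def calc_model_map(structure: Structure, d_min: float, grid_factor: float = 0.25,
                   dims: tuple[int, int, int] | None = None) -> MapGrid:
    """Calculate a model-based density map: one periodic Gaussian per atom."""
    if structure.cell is None:
        raise ValueError("structure has no unit cell")
    if structure.n_atoms == 0:
        raise ValueError("cannot calculate a map from an empty model")
    if dims is None:
        dims = grid_dims_for(structure.cell, d_min, grid_factor)
    grid = MapGrid(structure.cell, np.zeros(dims), d_min=d_min)
    for atom in structure.atoms():
        if atom.occ <= 0:
            continue
        model = AtomDensityModel.for_atom(_atomic_number(atom.element), atom.b, atom.occ, d_min)
        add_atom_density(grid.values, grid, atom.xyz, model)
    return grid


def map_correlation(a: MapGrid, b: MapGrid) -> float:
    """Pearson correlation of two maps over all grid points."""
    if not a.same_frame(b):
        raise ValueError("maps must share cell and grid dimensions")
    x = a.values.ravel()
    y = b.values.ravel()
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant map: correlation undefined")
    return float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * sx * sy))


def interpolate(grid: MapGrid, xyz: np.ndarray) -> np.ndarray | float:
    """Trilinear interpolation with periodic wrapping.

    Accepts a single point (shape (3,)) or an array of points (n, 3); returns
    a scalar or an array of n values accordingly.
    """
    pts = np.asarray(xyz, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    gpos = grid.grid_from_orth(pts)
    vals = ndimage.map_coordinates(grid.values, gpos.T, order=1, mode="grid-wrap")
    return float(vals[0]) if single else vals


def read_map(path: str) -> MapGrid:
    """Read a CCP4/MRC map covering a full P1 cell.

    Axis order is normalized so values index fast->slow along a, b, c.
    """
    m = gemmi.read_ccp4_map(str(path))
    sg = m.grid.spacegroup
    if sg is not None and sg.number != 1:
        raise ValueError(
            f"map spacegroup {sg.hm!r} is not P1; expand the map to a full P1 cell first"
        )
    if not m.full_cell():
        raise ValueError("map does not cover a full unit cell")
    m.setup(float("nan"))
    values = np.array(m.grid, copy=True, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("map does not cover a full unit cell (missing values)")
    cell = UnitCell.from_gemmi(m.grid.unit_cell)
    return MapGrid(cell, values)


def write_map(grid: MapGrid, path: str) -> None:
    """Write a map as CCP4 format (mode 2, full cell)."""
    g = gemmi.FloatGrid(*grid.dims)
    g.set_unit_cell(grid.cell.to_gemmi())
    g.spacegroup = gemmi.SpaceGroup("P1")
    arr = np.array(g, copy=False)
    arr[:] = grid.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
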