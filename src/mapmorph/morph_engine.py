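"""Per-residue FFT translation search against a target density map.

For each residue with a centre atom (CA for amino acids) a local model map is
built from all atoms within r_morph of that atom, zeroed outside the sphere
and offset to zero mean inside it.  Its overlap with the target map,

    O(x) = sum_g local(g - x) * target(g),

is evaluated at every grid offset x via FFTs over the whole unit cell.  Only
offsets within r_max of the origin are considered; the argmax grid offset
(dx_max), the density-weighted centroid of the peak containing it (dx_cent),
and a local model-to-map correlation at dx_max (cc_local) are recorded.

Sign convention: O(x) is the overlap of the model displaced by +x with the
target, so dx is the vector ADDED to the residue's coordinates to improve the
fit.  Overlaps between a displaced residue and density belonging to its
neighbours are deliberately not checked; the smoothing stage absorbs most
such artefacts.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .density import MapGrid, AtomDensityModel, add_atom_density, _atomic_number
from .model_io import Structure

__all__ = [
    "MorphConfig",
    "ResidueShift",
    "local_model_map",
    "overlap_function",
    "extract_shift",
    "local_cc",
    "residue_shift_search",
    "EmptyNeighborhoodError",
]


class EmptyNeighborhoodError(ValueError):
    """No atoms within r_morph of the search centre."""


@dataclass
class MorphConfig:
    """Tunable parameters of the morphing procedure.

    Defaults follow the regime of ~3 A maps: a 6 A density sphere per
    residue, translations up to 2 A, an 11-residue smoothing window, a local
    correlation cut-off of 0.05 and six cycles.
    """

    r_morph: float = 6.0          # A, radius of the per-residue density sphere
    r_max: float = 2.0            # A, largest translation considered
    cc_min: float = 0.05          # local-correlation inclusion threshold
    window: int = 11              # residues in the smoothing window (odd)
    n_cycles: int = 6
    d_min: float = 3.0            # A, nominal map resolution
    grid_factor: float = 0.25     # grid spacing as a fraction of d_min
    smooth_on: str = "dx_cent"    # which shift vector feeds smoothing
    regularize: bool = True
    early_stop_shift: float = 0.05  # A, stop iterating below this mean shift

    def __post_init__(self) -> None:
        for name in ("r_morph", "r_max", "cc_min", "window", "n_cycles", "d_min", "grid_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.smooth_on not in ("dx_cent", "dx_max"):
            raise ValueError("smooth_on must be 'dx_cent' or 'dx_max'")


@dataclass
class ResidueShift:
    """Translation-search result for one residue."""

    chain_id: str
    seq_id: int
    dx_max: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dx_cent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cc_local: float = 0.0
    included: bool = False
    no_peak: bool = False  # all overlap values in the search ball were <= 0

    def vector(self, which: str) -> np.ndarray:
        if which == "dx_cent":
            return self.dx_cent
        if which == "dx_max":
            return self.dx_max
        raise ValueError(which)


def _check_radius(grid: MapGrid, radius: float) -> None:
    shortest = min(grid.cell.lengths())
    if radius >= shortest / 2:
        raise ValueError(
            f"radius {radius} A exceeds half the shortest cell edge ({shortest / 2:.2f} A)"
        )


def local_model_map(structure: Structure, center: np.ndarray, r_morph: float,
                    template_grid: MapGrid) -> MapGrid:
    """Model map from atoms within r_morph of ``center``, zero outside the sphere.

    Distances use the minimum-image convention.  Inside the sphere a constant
    offset is subtracted so the in-sphere mean is exactly zero; this removes
    the spurious overlap a uniform density blob would have everywhere.
    """
    _check_radius(template_grid, r_morph)
    center = np.asarray(center, dtype=float)
    d_min = template_grid.d_min if template_grid.d_min is not None else 3.0
    frac = template_grid.cell.frac_matrix

    def min_image_dist(xyz: np.ndarray) -> float:
        df = frac @ (xyz - center)
        df -= np.round(df)
        return float(np.linalg.norm(template_grid.cell.orth_matrix @ df))

    values = np.zeros(template_grid.dims)
    grid = MapGrid(template_grid.cell, values, d_min=d_min)
    n_used = 0
    for atom in structure.atoms():
        if atom.occ <= 0:
            continue
        if min_image_dist(atom.xyz) > r_morph:
            continue
        model = AtomDensityModel.for_atom(_atomic_number(atom.element), atom.b, atom.occ, d_min)
        add_atom_density(grid.values, grid, atom.xyz, model)
        n_used += 1
    if n_used == 0:
        raise EmptyNeighborhoodError(f"no atoms within {r_morph} A of search centre")

    offsets = grid.min_image_offsets(center)
    inside = np.einsum("...i,...i->...", offsets, offsets) <= r_morph**2
    grid.values[~inside] = 0.0
    grid.values[inside] -= grid.values[inside].mean()
    return grid


def overlap_function(local: MapGrid, target: MapGrid,
                     target_fft: np.ndarray | None = None) -> MapGrid:
    """Overlap integral O(x) = sum_g local(g - x) * target(g) at every offset x.

    Computed as a cross-correlation via forward/inverse FFTs over the full
    cell.  ``target_fft`` may carry a precomputed ``rfftn`` of the target to
    amortize it across residues.
    """
    if local.dims != target.dims:
        raise ValueError("local and target maps must share grid dimensions")
    if target_fft is None:
        target_fft = np.fft.rfftn(target.values)
    o = np.fft.irfftn(np.conj(np.fft.rfftn(local.values)) * target_fft,
                      s=local.dims, axes=(0, 1, 2))
    return MapGrid(local.cell, o, d_min=local.d_min)


def _signed_offset_grid(grid: MapGrid) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal offset vector and squared length of each grid point from origin,
    wrapping indices past half the cell to negative offsets."""
    dims = np.array(grid.dims)
    axes = []
    for d in range(3):
        i = np.arange(dims[d], dtype=float)
        i[i > dims[d] / 2] -= dims[d]
        axes.append(i / dims[d])
    df = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    dx = df @ grid.cell.orth_matrix.T
    return dx, np.einsum("...i,...i->...", dx, dx)


def extract_shift(overlap: MapGrid, r_max: float,
                  peak_fraction: float = 0.9) -> tuple[np.ndarray, np.ndarray, bool]:
    """Best translation within r_max of the origin.

    Returns ``(dx_max, dx_cent, no_peak)``.  dx_max is the offset of the
    highest overlap grid point inside the r_max ball (ties: smallest offset
    length, then lexicographic index order).  dx_cent is the centroid of the
    face-connected peak region containing the argmax, clipped to the ball.
    The region comprises points with O >= O_bg + peak_fraction*(O_max - O_bg)
    where O_bg is the in-ball minimum, and each point is weighted by its
    height above that threshold; referencing the local background rather than
    zero matters because at typical map resolutions the overlap peak rides on
    a broad pedestal that would otherwise drag the centroid towards the
    geometric centre of the ball.  If no positive overlap exists in the ball
    both vectors are zero and ``no_peak`` is set.
    """
    _check_radius(overlap, r_max)
    dx, r2 = _signed_offset_grid(overlap)
    ball = r2 <= r_max**2
    vals = overlap.values
    in_ball = np.where(ball)
    if len(in_ball[0]) == 0:
        return np.zeros(3), np.zeros(3), True
    ball_vals = vals[in_ball]
    vmax = ball_vals.max()
    if vmax <= 0:
        return np.zeros(3), np.zeros(3), True
    vmin = ball_vals.min()

    # deterministic tie-break: among maxima, smallest |offset|, then lexicographic
    is_max = ball_vals >= vmax
    cand = np.flatnonzero(is_max)
    cand_r2 = r2[in_ball][cand]
    best = cand[np.lexsort((cand, cand_r2))[0]]
    argmax = (in_ball[0][best], in_ball[1][best], in_ball[2][best])
    dx_max = dx[argmax]

    if vmax == vmin:  # flat overlap in the ball: no sub-grid information
        return dx_max, dx_max.copy(), False

    # flood fill (face connectivity, periodic) of the peak region
    dims = overlap.dims
    thresh = vmin + peak_fraction * (vmax - vmin)
    keep = (vals >= thresh) & ball
    seen = np.zeros(dims, dtype=bool)
    queue = deque([argmax])
    seen[argmax] = True
    members = []
    while queue:
        p = queue.popleft()
        members.append(p)
        for d in range(3):
            for step in (-1, 1):
                q = list(p)
                q[d] = (q[d] + step) % dims[d]
                q = tuple(q)
                if not seen[q] and keep[q]:
                    seen[q] = True
                    queue.append(q)
    idx = tuple(np.array([m[d] for m in members]) for d in range(3))
    w = vals[idx] - thresh
    w[w < 0] = 0.0
    if w.sum() <= 0:  # single-point region sitting exactly at the threshold
        return dx_max, dx_max.copy(), False
    dx_cent = (dx[idx] * w[:, None]).sum(axis=0) / w.sum()
    return dx_max, dx_cent, False


def local_cc(target: MapGrid, local: MapGrid, dx: np.ndarray, r_morph: float,
             center: np.ndarray) -> float:
    """Pearson correlation between the target and the dx-shifted local model map.

    Evaluated over grid points inside the r_morph sphere around the shifted
    centre; the local map is sampled at the unshifted positions, the target at
    the shifted ones (nearest-grid displacement, so values stay on-grid).
    Returns 0 when either side has no variance.
    """
    if local.dims != target.dims:
        raise ValueError("maps must share grid dimensions")
    dims = np.array(local.dims)
    center = np.asarray(center, dtype=float)
    dx = np.asarray(dx, dtype=float)
    # displacement in whole grid steps (dx comes from the overlap grid search)
    steps = np.round(local.frac_from_orth(dx) * dims).astype(int)
    offsets = local.min_image_offsets(center)
    inside = np.einsum("...i,...i->...", offsets, offsets) <= r_morph**2
    ii, jj, kk = np.where(inside)
    model_vals = local.values[ii, jj, kk]
    ti = (ii + steps[0]) % dims[0]
    tj = (jj + steps[1]) % dims[1]
    tk = (kk + steps[2]) % dims[2]
    target_vals = target.values[ti, tj, tk]
    sm = model_vals.std()
    st = target_vals.std()
    if sm == 0 or st == 0:
        return 0.0
    mm = model_vals - model_vals.mean()
    tt = target_vals - target_vals.mean()
    return float(np.dot(mm, tt) / (len(mm) * sm * st))


def residue_shift_search(structure: Structure, target: MapGrid,
                         config: MorphConfig) -> list[ResidueShift]:
    """One translation search per residue possessing a centre atom.

    The search always uses the structure's coordinates as given (no
    intra-pass updates).  Residues whose centre atom is missing are skipped;
    residues with an empty r_morph neighbourhood or cc_local below cc_min are
    reported with ``included=False``.
    """
    if structure.cell is None:
        raise ValueError("structure has no unit cell")
    target_fft = np.fft.rfftn(target.values)
    results: list[ResidueShift] = []
    for chain, res in structure.residues():
        if res.is_water:
            continue
        center_atom = res.center_atom
        if center_atom is None:
            continue
        shift = ResidueShift(chain.chain_id, res.seq_id)
        try:
            local = local_model_map(structure, center_atom.xyz, config.r_morph, target)
        except EmptyNeighborhoodError:
            results.append(shift)
            continue
        overlap = overlap_function(local, target, target_fft=target_fft)
        dx_max, dx_cent, no_peak = extract_shift(overlap, config.r_max)
        cc = local_cc(target, local, dx_max, config.r_morph, center_atom.xyz)
        shift.dx_max = dx_max
        shift.dx_cent = dx_cent
        shift.cc_local = cc
        shift.no_peak = no_peak
        shift.included = (not no_peak) and cc >= config.cc_min
        results.append(shift)
    return results
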