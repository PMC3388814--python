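"""Synthetic ground-truth systems: ideal poly-alanine models in P1 cells,
smooth deformation fields, and calculated target maps.

Everything here is generated, never downloaded: the whole test suite runs
from these fixtures.  Models are built from ideal internal coordinates
(Engh-Huber-type bond lengths and angles, canonical alpha-helix torsions), so
the regularizer's restraints are satisfied by construction.  Deformations are
applied as one translation per residue — the displacement of the residue's
CA under the field — mirroring exactly the class of motions the morphing
search can recover.  The field is stored with each case, so recovery can be
scored against the exact inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .density import MapGrid, calc_model_map
from .model_io import Atom, Chain, Residue, Structure, UnitCell
from .morph_engine import MorphConfig

__all__ = [
    "DeformationField",
    "make_helix",
    "make_two_helix_hinge",
    "deform",
    "make_case",
    "MorphCase",
    "build_polyala",
]

# backbone internal coordinates (Engh-Huber-type ideals)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.0, 117.2, 121.7, 120.8
A_N_CA_CB, A_C_CA_CB = 110.4, 110.5
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -120.0, 130.0
OMEGA = 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d given a-b-c."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB from the intersection of the two ideal bond-angle cones (L chirality)."""
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    c1 = math.cos(math.radians(A_N_CA_CB))
    c2 = math.cos(math.radians(A_C_CA_CB))
    dot = float(u1 @ u2)
    # v = alpha*u1 + beta*u2 + gamma*w, with w the unit normal of (u1, u2)
    det = 1.0 - dot * dot
    alpha = (c1 - c2 * dot) / det
    beta = (c2 - c1 * dot) / det
    w = np.cross(u1, u2)
    w = w / np.linalg.norm(w)
    gamma2 = 1.0 - (alpha * alpha + beta * beta + 2 * alpha * beta * dot)
    gamma = math.sqrt(max(gamma2, 0.0))
    v = alpha * u1 + beta * u2 - gamma * w  # minus sign selects the L enantiomer
    return ca + B_CA_CB * v


def build_polyala(torsions: list[tuple[float, float]], chain_id: str = "A",
                  first_seq_id: int = 1) -> list[Residue]:
    """Poly-alanine chain from a (phi, psi) list; one residue per entry.

    Atoms per residue: N, CA, C, O, CB.  The first residue is placed in a
    canonical frame; the chain grows by NeRF placement with omega fixed at
    180 degrees.
    """
    residues: list[Residue] = []
    n_prev = ca_prev = c_prev = None
    for i, (phi, psi) in enumerate(torsions):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([B_N_CA, 0.0, 0.0])
            ang = math.radians(A_N_CA_C)
            c = ca + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            n = _place(n_prev, ca_prev, c_prev, B_C_N, A_CA_C_N, psi_prev)
            ca = _place(ca_prev, c_prev, n, B_N_CA, A_C_N_CA, OMEGA)
            c = _place(c_prev, n, ca, B_CA_C, A_N_CA_C, phi)
        o = _place(n, ca, c, B_C_O, A_CA_C_O, psi + 180.0)
        cb = _place_cb(n, ca, c)
        atoms = [
            Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c),
            Atom("O", "O", o), Atom("CB", "C", cb),
        ]
        residues.append(Residue(first_seq_id + i, "ALA", atoms))
        n_prev, ca_prev, c_prev, psi_prev = n, ca, c, psi
    return residues


def _center_in_cell(residues: list[Residue], cell_margin: float) -> Structure:
    coords = np.concatenate([r.coords() for r in residues])
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    lengths = hi - lo + 2.0 * cell_margin
    cell = UnitCell(*lengths)
    shift = cell_margin - lo
    for r in residues:
        for a in r.atoms:
            a.xyz = a.xyz + shift
    return Structure([Chain("A", residues)], cell)


def make_helix(n_res: int, cell_margin: float = 8.0) -> Structure:
    """Ideal poly-alanine alpha-helix centred in a P1 cell with the given padding."""
    if n_res < 4:
        raise ValueError("need at least 4 residues for a helix")
    residues = build_polyala([(HELIX_PHI, HELIX_PSI)] * n_res)
    return _center_in_cell(residues, cell_margin)


def make_two_helix_hinge(n_res_per_arm: int, cell_margin: float = 8.0,
                         linker_res: int = 3) -> Structure:
    """Two ideal helices joined by an extended linker, one chain, consecutive numbering."""
    if n_res_per_arm < 8:
        raise ValueError("need at least 8 residues per arm")
    torsions = ([(HELIX_PHI, HELIX_PSI)] * n_res_per_arm
                + [(EXTENDED_PHI, EXTENDED_PSI)] * linker_res
                + [(HELIX_PHI, HELIX_PSI)] * n_res_per_arm)
    residues = build_polyala(torsions)
    return _center_in_cell(residues, cell_margin)


@dataclass
class DeformationField:
    """Smooth per-residue displacement field.

    kinds and parameters:
      - ``rigid_translation``: ``translation`` (A vector) applied to every residue.
      - ``hinge``: rotation by ``angle_deg`` about ``axis`` through ``point``;
        residues with seq_id in ``moving_range`` rotate one way, those in
        ``counter_range`` (optional) the other, giving a symmetric elbow bend.
        Each residue is *translated* by the displacement of its CA under the
        rotation, so intra-residue geometry is exactly preserved.
      - ``sinusoidal``: residue j displaced by
        ``amplitude * sin(2 pi j / wavelength) * direction``.

    ``max_displacement`` bounds the per-residue displacement magnitude; by
    default 2 A, the translation-search radius, so the field stays within
    what morphing can recover.
    """

    kind: str
    translation: np.ndarray | None = None
    point: np.ndarray | None = None
    axis: np.ndarray | None = None
    angle_deg: float = 0.0
    moving_range: tuple[int, int] | None = None
    counter_range: tuple[int, int] | None = None
    amplitude: float = 0.0
    wavelength: float = 10.0
    direction: np.ndarray | None = None
    max_displacement: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("rigid_translation", "hinge", "sinusoidal"):
            raise ValueError(f"unknown deformation kind {self.kind!r}")

    def _rotation(self, angle_deg: float) -> np.ndarray:
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        t = math.radians(angle_deg)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)

    def displacement(self, seq_id: int, ca_xyz: np.ndarray) -> np.ndarray:
        if self.kind == "rigid_translation":
            return np.asarray(self.translation, dtype=float)
        if self.kind == "hinge":
            p = np.asarray(self.point, dtype=float)
            if self.moving_range and self.moving_range[0] <= seq_id <= self.moving_range[1]:
                rot = self._rotation(self.angle_deg)
            elif self.counter_range and self.counter_range[0] <= seq_id <= self.counter_range[1]:
                rot = self._rotation(-self.angle_deg)
            else:
                return np.zeros(3)
            return rot @ (ca_xyz - p) + p - ca_xyz
        # sinusoidal
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        return self.amplitude * math.sin(2.0 * math.pi * seq_id / self.wavelength) * d


def deform(structure: Structure, field: DeformationField) -> Structure:
    """Apply a deformation field: one translation per residue, evaluated at its CA."""
    new = structure.copy()
    for chain, res in new.residues():
        center = res.center_atom
        anchor = center.xyz if center is not None else res.coords().mean(axis=0)
        dx = field.displacement(res.seq_id, anchor)
        mag = float(np.linalg.norm(dx))
        if mag > field.max_displacement + 1e-9:
            raise ValueError(
                f"residue {res.seq_id}: displacement {mag:.2f} A exceeds "
                f"bound {field.max_displacement} A"
            )
        for atom in res.atoms:
            atom.xyz = atom.xyz + dx
    return new


@dataclass
class MorphCase:
    """One synthetic morphing problem with its bookkeeping."""

    kind: str
    seed: int
    truth: Structure
    start_model: Structure
    target_map: MapGrid
    config: MorphConfig
    field: DeformationField | None = None


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_case(kind: str, seed: int = 0, d_min: float = 3.0,
              grid_factor: float = 0.25) -> MorphCase:
    """Deterministic ground-truth morphing scenario.

    kinds: ``null`` (start = truth), ``rigid`` (20-residue helix offset by a
    1.2 A translation), ``hinge`` (two 12-residue arms bent symmetrically
    about the linker, start-vs-truth main-chain r.m.s.d. in the 1-2 A range),
    ``sinusoid`` (1 A-amplitude wave along a 20-residue helix).
    """
    rng = np.random.default_rng(seed)
    config = MorphConfig(d_min=d_min, grid_factor=grid_factor)
    if kind == "null":
        truth = make_helix(20)
        field = None
        start = truth.copy()
    elif kind == "rigid":
        truth = make_helix(20)
        field = DeformationField("rigid_translation",
                                 translation=1.2 * _random_unit(rng))
        start = deform(truth, field)
    elif kind == "hinge":
        truth = make_two_helix_hinge(12)
        chain = truth.chains[0]
        linker_mid = chain.residues[len(chain.residues) // 2]
        cas = np.array([r.center_atom.xyz for r in chain.residues])
        # hinge axis displaced 30 A from the molecule so the two arms swing in
        # nearly uniform opposite directions; angle set so the largest CA
        # displacement is 1.9 A, just inside the 2 A search radius.  This puts
        # the start-vs-truth main-chain r.m.s.d. in the 1-2 A band typical of
        # distant molecular-replacement templates.
        axis = _random_unit(rng)
        w = _random_unit(rng)
        w = w - (w @ axis) * axis
        w /= np.linalg.norm(w)
        point = cas.mean(axis=0) + 30.0 * w
        rel = cas - point
        perp = rel - np.outer(rel @ axis, axis)
        max_radius = float(np.linalg.norm(perp, axis=1).max())
        angle = math.degrees(2.0 * math.asin(1.9 / (2.0 * max_radius)))
        field = DeformationField(
            "hinge",
            point=point,
            axis=axis,
            angle_deg=angle,
            moving_range=(linker_mid.seq_id + 1, chain.residues[-1].seq_id),
            counter_range=(chain.residues[0].seq_id, linker_mid.seq_id - 1),
        )
        start = deform(truth, field)
    elif kind == "sinusoid":
        truth = make_helix(20)
        field = DeformationField("sinusoidal", amplitude=1.0, wavelength=10.0,
                                 direction=_random_unit(rng))
        start = deform(truth, field)
    else:
        raise ValueError(f"unknown case kind {kind!r}")
    target = calc_model_map(truth, d_min=d_min, grid_factor=grid_factor)
    return MorphCase(kind, seed, truth, start, target, config, field)
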