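"""Real-space geometry regularization of the backbone after shift application.

Morphing translates whole residues independently, so the peptide links
between neighbouring residues end up distorted.  This module restores
chemically reasonable backbone geometry by minimizing a harmonic restraint
energy, optionally biased towards the target density:

    E = w_b * sum_bonds (d - d0)^2
      + w_a * sum_angles (theta - theta0)^2        [theta in degrees]
      + w_pos * sum_atoms |x - x_start|^2
      - w_map * sum_atoms rho(x) / rms(rho)

minimized by steepest descent with backtracking line search.  Ideal bond
lengths and angles are standard Engh-Huber-type values for the protein
backbone.  Side chains ride on their residue's translation and are restrained
only by the positional term, preserving their internal geometry and
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import MapGrid, interpolate
from .model_io import Structure

__all__ = ["GeometryRestraints", "regularize"]

IDEAL_BONDS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide link to the next residue
    ("C", "O"): 1.231,
}

IDEAL_ANGLES = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "N"): 117.2,  # spans the peptide link
    ("C", "N", "CA"): 121.7,  # spans the peptide link
    ("CA", "C", "O"): 120.8,
}


@dataclass
class GeometryRestraints:
    """Harmonic restraint targets and weights for backbone regularization."""

    bond_ideals: dict = field(default_factory=lambda: dict(IDEAL_BONDS))
    angle_ideals: dict = field(default_factory=lambda: dict(IDEAL_ANGLES))
    w_bond: float = 1.0     # per A^2
    w_angle: float = 0.1    # per deg^2
    w_pos: float = 0.05     # per A^2, anchors atoms to their starting position
    w_map: float = 0.2      # pull into density (map rms-normalized)
    step_tol: float = 1e-4  # A, stop when the largest atom move falls below
    max_steps: int = 200

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.bond_ideals.values()):
            raise ValueError("bond ideals must be positive")
        for w in (self.w_bond, self.w_angle, self.w_pos, self.w_map):
            if w < 0:
                raise ValueError("weights must be non-negative")


def _collect_terms(structure: Structure, restraints: GeometryRestraints):
    """Index bond and angle terms over the backbone.

    Returns (atom_index_map, bonds, angles) where bonds is a list of
    (i, j, d0) and angles a list of (i, j, k, theta0_deg); peptide-link terms
    appear only between consecutively numbered residues of the same chain.
    """
    atoms = list(structure.atoms())
    index = {id(a): i for i, a in enumerate(atoms)}

    bonds: list[tuple[int, int, float]] = []
    angles: list[tuple[int, int, int, float]] = []

    def bb(res, name):
        a = res.find_atom(name)
        return None if a is None else index[id(a)]

    for chain in structure.chains:
        for seg in chain.segments:
            for pos, res in enumerate(seg):
                if res.is_water:
                    continue
                n, ca, c, o = (bb(res, x) for x in ("N", "CA", "C", "O"))
                if n is not None and ca is not None:
                    bonds.append((n, ca, restraints.bond_ideals[("N", "CA")]))
                if ca is not None and c is not None:
                    bonds.append((ca, c, restraints.bond_ideals[("CA", "C")]))
                if c is not None and o is not None:
                    bonds.append((c, o, restraints.bond_ideals[("C", "O")]))
                if None not in (n, ca, c):
                    angles.append((n, ca, c, restraints.angle_ideals[("N", "CA", "C")]))
                if None not in (ca, c, o):
                    angles.append((ca, c, o, restraints.angle_ideals[("CA", "C", "O")]))
                if pos + 1 < len(seg):
                    nxt = seg[pos + 1]
                    n2, ca2 = bb(nxt, "N"), bb(nxt, "CA")
                    if c is not None and n2 is not None:
                        bonds.append((c, n2, restraints.bond_ideals[("C", "N")]))
                    if None not in (ca, c, n2):
                        angles.append((ca, c, n2, restraints.angle_ideals[("CA", "C", "N")]))
                    if None not in (c, n2, ca2):
                        angles.append((c, n2, ca2, restraints.angle_ideals[("C", "N", "CA")]))
    return atoms, bonds, angles


def _bond_energy_grad(x, bonds, w):
    e = 0.0
    g = np.zeros_like(x)
    for i, j, d0 in bonds:
        v = x[i] - x[j]
        d = np.linalg.norm(v)
        if d < 1e-8:
            continue
        diff = d - d0
        e += w * diff * diff
        gv = 2.0 * w * diff * v / d
        g[i] += gv
        g[j] -= gv
    return e, g


def _angle_energy_grad(x, angles, w):
    e = 0.0
    g = np.zeros_like(x)
    for i, j, k, t0 in angles:
        u = x[i] - x[j]
        v = x[k] - x[j]
        lu = np.linalg.norm(u)
        lv = np.linalg.norm(v)
        if lu < 1e-8 or lv < 1e-8:
            continue
        cu = u / lu
        cv = v / lv
        cos_t = np.clip(cu @ cv, -1.0, 1.0)
        theta = np.degrees(np.arccos(cos_t))
        diff = theta - t0
        e += w * diff * diff
        sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
        # d theta / dx in degrees
        pref = -np.degrees(1.0) / sin_t
        gi = pref * (cv - cos_t * cu) / lu
        gk = pref * (cu - cos_t * cv) / lv
        common = 2.0 * w * diff
        g[i] += common * gi
        g[k] += common * gk
        g[j] -= common * (gi + gk)
    return e, g


def _map_energy_grad(x, target: MapGrid, w, scale, h=0.05):
    vals = interpolate(target, x)
    e = -w * scale * float(np.sum(vals))
    g = np.zeros_like(x)
    for d in range(3):
        xp = x.copy(); xp[:, d] += h
        xm = x.copy(); xm[:, d] -= h
        g[:, d] = -w * scale * (interpolate(target, xp) - interpolate(target, xm)) / (2 * h)
    return e, g


def _energy_and_grad(x, x0, bonds, angles, r: GeometryRestraints,
                     target: MapGrid | None, map_scale: float):
    e_b, g_b = _bond_energy_grad(x, bonds, r.w_bond)
    e_a, g_a = _angle_energy_grad(x, angles, r.w_angle)
    dpos = x - x0
    e_p = r.w_pos * float(np.sum(dpos * dpos))
    g_p = 2.0 * r.w_pos * dpos
    e = e_b + e_a + e_p
    g = g_b + g_a + g_p
    if target is not None and r.w_map > 0:
        e_m, g_m = _map_energy_grad(x, target, r.w_map, map_scale)
        e += e_m
        g += g_m
    if not np.isfinite(e):
        raise ValueError("non-finite restraint energy")
    return e, g


def regularize(structure: Structure, restraints: GeometryRestraints | None = None,
               target: MapGrid | None = None, max_steps: int | None = None,
               energy_trace: list | None = None) -> Structure:
    """Minimize the backbone restraint energy by gradient descent.

    Returns a new structure.  The energy is non-increasing across accepted
    steps; iteration stops when the largest single-atom move in a step drops
    below ``step_tol`` or after ``max_steps`` steps.  If ``energy_trace`` is
    a list, the energy after every accepted step is appended to it.
    """
    r = restraints or GeometryRestraints()
    steps = r.max_steps if max_steps is None else max_steps
    new = structure.copy()
    atoms, bonds, angles = _collect_terms(new, r)
    if not atoms:
        return new
    x = np.array([a.xyz for a in atoms])
    x0 = x.copy()
    map_scale = 0.0
    if target is not None and r.w_map > 0:
        rms = float(np.sqrt(np.mean(target.values**2)))
        map_scale = 1.0 / rms if rms > 0 else 0.0

    e, g = _energy_and_grad(x, x0, bonds, angles, r, target, map_scale)
    if energy_trace is not None:
        energy_trace.append(e)
    step = 0.05  # A per unit gradient component, adapted by backtracking
    for _ in range(steps):
        gmax = np.abs(g).max()
        if gmax < 1e-12:
            break
        direction = -g / gmax  # largest component moves by `step` A
        accepted = False
        for _ in range(20):
            x_new = x + step * direction
            e_new, g_new = _energy_and_grad(x_new, x0, bonds, angles, r, target, map_scale)
            if e_new < e:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        moved = np.abs(x_new - x).max()
        x, e, g = x_new, e_new, g_new
        if energy_trace is not None:
            energy_trace.append(e)
        step = min(step * 1.5, 0.5)
        if moved < r.step_tol:
            break

    for atom, row in zip(atoms, x):
        atom.xyz = row.copy()
    return new
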