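"""Atomic model I/O and the structure hierarchy used throughout the package.

Models are plain dataclasses (Structure -> Chain -> Residue -> Atom) holding
orthogonal Angstrom coordinates in a P1 unit cell.  PDB parsing and writing
are delegated to gemmi; this module only normalizes the hierarchy (alternate
locations, ordering, segment bookkeeping) into the form the morphing engine
expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "UnitCell",
    "EmptyModelError",
    "read_model",
    "write_model",
    "mainchain_atoms",
    "MAINCHAIN_NAMES",
]

#: PDB names of protein main-chain atoms, in canonical order.
MAINCHAIN_NAMES = ("N", "CA", "C", "O")

#: Residue names treated as solvent/hetero and excluded from search & metrics.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class EmptyModelError(ValueError):
    """Raised when a coordinate file contains no usable ATOM records."""


@dataclass
class UnitCell:
    """P1 unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional to orthogonal (Angstrom) coordinates."""
        m = self.to_gemmi().orth.mat
        return np.array(m.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        """3x3 matrix mapping orthogonal (Angstrom) to fractional coordinates."""
        m = self.to_gemmi().frac.mat
        return np.array(m.tolist(), dtype=float)

    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass
class Atom:
    """One atom: name, element symbol, orthogonal coordinates, B factor, occupancy."""

    name: str
    element: str
    xyz: np.ndarray
    b: float = 20.0
    occ: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.b < 0:
            raise ValueError("B factor must be non-negative")


@dataclass
class Residue:
    """One residue; ``center_atom_name`` is CA for amino acids, C1' for nucleotides."""

    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    center_atom_name: str = "CA"

    def find_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def center_atom(self) -> Atom | None:
        return self.find_atom(self.center_atom_name)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.xyz = row.copy()


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"chain {self.chain_id}: residues not strictly increasing in seq_id")

    @property
    def segments(self) -> list[list[Residue]]:
        """Maximal runs of consecutively numbered residues."""
        segs: list[list[Residue]] = []
        for res in self.residues:
            if segs and res.seq_id == segs[-1][-1].seq_id + 1:
                segs[-1].append(res)
            else:
                segs.append([res])
        return segs


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    cell: UnitCell | None = None
    spacegroup_label: str = "P 1"

    def residues(self) -> Iterator[tuple[Chain, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    def atoms(self) -> Iterator[Atom]:
        for _, res in self.residues():
            for atom in res.atoms:
                yield atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        atoms = list(self.atoms())
        if xyz.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(atoms, xyz):
            atom.xyz = row.copy()

    def copy(self) -> "Structure":
        chains = []
        for ch in self.chains:
            residues = [
                Residue(
                    seq_id=r.seq_id,
                    name=r.name,
                    atoms=[Atom(a.name, a.element, a.xyz.copy(), a.b, a.occ) for a in r.atoms],
                    center_atom_name=r.center_atom_name,
                )
                for r in ch.residues
            ]
            chains.append(Chain(ch.chain_id, residues))
        cell = None
        if self.cell is not None:
            cell = UnitCell(self.cell.a, self.cell.b, self.cell.c,
                            self.cell.alpha, self.cell.beta, self.cell.gamma)
        return Structure(chains, cell, self.spacegroup_label)


_NUCLEOTIDES = frozenset({
    "A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU",
})


def _center_atom_name(residue_name: str) -> str:
    return "C1'" if residue_name in _NUCLEOTIDES else "CA"


def _pick_altloc(gres: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, first seen on ties."""
    chosen: dict[str, gemmi.Atom] = {}
    for a in gres:
        prev = chosen.get(a.name)
        if prev is None or a.occ > prev.occ:
            chosen[a.name] = a
    # preserve file order of the retained atoms
    kept = set(id(a) for a in chosen.values())
    return [a for a in gres if id(a) in kept]


def read_model(path: str, cell: UnitCell | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB-format text file.
    cell:
        Unit cell to use when the file lacks a CRYST1 record.  A missing
        CRYST1 without this fallback is an error, because every downstream
        map operation needs a crystal frame.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()

    if st.cell.is_crystal():
        use_cell = UnitCell.from_gemmi(st.cell)
    elif cell is not None:
        use_cell = cell
    else:
        raise ValueError(f"{path}: no CRYST1 record and no cell supplied")

    chains: list[Chain] = []
    if len(st) == 0:
        raise EmptyModelError(f"{path}: empty model (no ATOM records)")
    model = st[0]
    for gchain in model:
        residues: list[Residue] = []
        last_key: tuple[int, str] | None = None
        for gres in gchain:
            # Insertion codes break consecutive numbering; encode by bumping
            # into a fresh residue object keyed on (num, icode) order of file.
            key = (gres.seqid.num, gres.seqid.icode or "")
            if last_key is not None and key == last_key:
                continue
            last_key = key
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]),
                     b=max(a.b_iso, 0.0), occ=min(max(a.occ, 0.0), 1.0))
                for a in _pick_altloc(gres)
            ]
            residues.append(Residue(gres.seqid.num, gres.name, atoms,
                                    _center_atom_name(gres.name)))
        # drop duplicate seq_ids arising from insertion codes: keep first,
        # renumber the rest past the chain end so numbering stays strict
        seen: set[int] = set()
        fixed: list[Residue] = []
        next_free = max((r.seq_id for r in residues), default=0) + 1
        for r in residues:
            if r.seq_id in seen:
                r = Residue(next_free, r.name, r.atoms, r.center_atom_name)
                next_free += 1
            seen.add(r.seq_id)
            fixed.append(r)
        fixed.sort(key=lambda r: r.seq_id)
        if fixed:
            chains.append(Chain(gchain.name, fixed))

    structure = Structure(chains, use_cell, st.spacegroup_hm or "P 1")
    if structure.n_atoms == 0:
        raise EmptyModelError(f"{path}: empty model (no ATOM records)")
    return structure


def to_gemmi(structure: Structure) -> gemmi.Structure:
    """Convert to a gemmi Structure (single model) for output."""
    st = gemmi.Structure()
    if structure.cell is not None:
        st.cell = structure.cell.to_gemmi()
    st.spacegroup_hm = structure.spacegroup_label
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.xyz)
                ga.b_iso = atom.b
                ga.occ = atom.occ
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_model(structure: Structure, path: str) -> None:
    """Write a :class:`Structure` as PDB (CRYST1 + ATOM + TER records)."""
    if structure.n_atoms == 0:
        raise EmptyModelError("refusing to write an empty model")
    to_gemmi(structure).write_pdb(str(path))


def mainchain_atoms(structure: Structure) -> list[Atom]:
    """Protein main-chain atoms (N, CA, C, O) in model order, waters excluded."""
    out: list[Atom] = []
    for _, res in structure.residues():
        if res.is_water:
            continue
        for atom in res.atoms:
            if atom.name in MAINCHAIN_NAMES:
                out.append(atom)
    return out


def mainchain_coords(structure: Structure) -> np.ndarray:
    atoms = mainchain_atoms(structure)
    if not atoms:
        return np.zeros((0, 3))
    return np.array([a.xyz for a in atoms], dtype=float)
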