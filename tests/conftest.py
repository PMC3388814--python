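import numpy as np
import pytest

from mapmorph.model_io import Atom, Chain, Residue, Structure, UnitCell
from mapmorph.synthetic import make_case, make_helix


def make_residue(seq_id, atom_specs, name="ALA"):
    """atom_specs: list of (name, element, xyz)."""
    atoms = [Atom(n, el, np.asarray(x, dtype=float)) for n, el, x in atom_specs]
    return Residue(seq_id, name, atoms)


@pytest.fixture(scope="session")
def helix20():
    return make_helix(20)


@pytest.fixture(scope="session")
def rigid_case():
    return make_case("rigid", seed=1)


@pytest.fixture(scope="session")
def hinge_case():
    return make_case("hinge", seed=1)


@pytest.fixture(scope="session")
def null_case():
    return make_case("null", seed=1)


@pytest.fixture()
def tiny_structure():
    """3 residues, 2 chains, inside a 20 A cubic cell."""
    res_a1 = make_residue(1, [
        ("N", "N", (5.0, 5.0, 5.0)),
        ("CA", "C", (6.458, 5.0, 5.0)),
        ("C", "C", (7.0, 6.4, 5.0)),
        ("O", "O", (6.4, 7.4, 5.2)),
        ("CB", "C", (7.0, 4.3, 6.2)),
    ])
    res_a2 = make_residue(2, [
        ("N", "N", (8.3, 6.5, 5.0)),
        ("CA", "C", (9.2, 7.6, 5.2)),
        ("C", "C", (10.6, 7.1, 5.4)),
        ("O", "O", (11.5, 7.9, 5.5)),
    ], name="GLY")
    res_b1 = make_residue(1, [
        ("N", "N", (12.0, 12.0, 12.0)),
        ("CA", "C", (13.4, 12.2, 12.0)),
        ("C", "C", (14.0, 13.5, 12.3)),
        ("O", "O", (13.4, 14.5, 12.6)),
    ])
    return Structure(
        [Chain("A", [res_a1, res_a2]), Chain("B", [res_b1])],
        UnitCell(20.0, 20.0, 20.0),
    )
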