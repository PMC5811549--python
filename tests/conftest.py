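"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from midaskit.structio import Atom, Structure
from midaskit.synthdata import SiteSpec, make_site_structure


def make_atom(
    serial=1,
    name="CA",
    element="C",
    resname="ALA",
    resnum=1,
    chain="A",
    pos=(0.0, 0.0, 0.0),
    occ=1.0,
    b=20.0,
    kind="atom",
    altloc="",
):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        altloc=altloc,
        residue_name=resname,
        residue_number=resnum,
        insertion_code="",
        chain_id=chain,
        position=tuple(float(c) for c in pos),
        occupancy=occ,
        b_factor=b,
        record_kind=kind,
    )


@pytest.fixture
def twelve_atom_structure():
    """One chain, three Ala residues of 4 backbone atoms each (12 atoms)."""
    atoms = []
    serial = 0
    for r in range(1, 4):
        for j, name in enumerate(("N", "CA", "C", "O")):
            serial += 1
            el = "N" if name == "N" else ("O" if name == "O" else "C")
            atoms.append(
                make_atom(
                    serial=serial,
                    name=name,
                    element=el,
                    resnum=r,
                    pos=(3.8 * r + 0.9 * j, 1.1 * j, 0.4 * (j % 2)),
                    b=10.0 * r,
                )
            )
    return Structure(id="fix12", atoms=atoms, cell=(30, 30, 30, 90, 90, 90))


@pytest.fixture
def octahedral_mg_site():
    """Ideal octahedral Mg fixture: 3 protein + 3 water donors at 2.10 A."""
    spec = SiteSpec(
        geometry="octahedral",
        metal="Mg",
        bond_length=2.10,
        n_protein_ligands=3,
        n_waters=3,
    )
    return make_site_structure(spec)


@pytest.fixture
def heptacoordinate_ca_site():
    """Pentagonal-bipyramidal Ca: 3 protein + 4 water donors, 2 bridged."""
    spec = SiteSpec(
        geometry="pentagonal_bipyramidal",
        metal="Ca",
        bond_length=2.4,
        n_protein_ligands=3,
        n_waters=4,
        bridged_residues=("ASP", "THR"),
        salt_bridge=2.9,
    )
    return make_site_structure(spec)


def random_coords(rng: np.random.Generator, n: int, spread: float = 5.0) -> np.ndarray:
    return rng.uniform(-spread, spread, size=(n, 3))


def random_rigid_motion(rng: np.random.Generator):
    """A proper rotation (QR with det fix) and a translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10, 10, size=3)
    return q, t
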