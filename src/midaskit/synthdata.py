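"""Synthetic fixtures with machine-readable ground truth.

Generates small coordinate files that exercise every analysis path: a
divalent metal on an ideal coordination polyhedron with a chosen mix of
protein and water donors, optional water-bridged second-shell residues, a
poly-Ala scaffold carrying a prescribed per-region B-factor pattern, an
optional Asp-Arg salt bridge, rigidly displaced structure pairs with known
offsets, and alignment fixtures with prescribed conserved columns.

Fixture residues use standard amino-acid atom names with idealized local
geometry; bond angles beyond the coordination shell are cosmetic.  All
generators are deterministic under their seed, and each returns a
ground-truth metadata dict alongside the object (written as a JSON sidecar
by :func:`write_fixture`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metalsite import IDEAL_GEOMETRIES
from .structio import Atom, Structure, write_structure

__all__ = [
    "SiteSpec",
    "make_site_structure",
    "make_displaced_pair",
    "make_msa_fixture",
    "write_fixture",
]

AMINO_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: (residue name, donor atom) cycle used for protein first-shell ligands.
PROTEIN_DONORS = (("SER", "OG"), ("ASP", "OD1"), ("THR", "OG1"))

DEFAULT_B = 20.0
METAL_CENTER = np.array([30.0, 30.0, 30.0])


@dataclass(frozen=True)
class SiteSpec:
    """Recipe for a single-metal coordination-site fixture.

    ``n_protein_ligands + n_waters`` must equal the coordination number of
    ``geometry``.  ``bridged_residues`` lists residue types given a
    water-mediated (second-shell) donor behind one of the first-shell
    waters.  ``b_pattern`` maps inclusive scaffold residue ranges to
    B-factors (everything else gets ``DEFAULT_B``); ``salt_bridge`` places
    an Asp-Arg pair at the stated O-N distance on the scaffold side.
    """

    geometry: str = "octahedral"
    metal: str = "Ca"
    bond_length: float = 2.4
    n_protein_ligands: int = 3
    n_waters: int = 3
    bridged_residues: tuple[str, ...] = ()
    salt_bridge: float | None = None
    b_pattern: dict = field(default_factory=dict)
    jitter_sd: float = 0.0
    seed: int = 0
    scaffold_length: int = 40

    def __post_init__(self) -> None:
        if self.geometry not in IDEAL_GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        cn = len(IDEAL_GEOMETRIES[self.geometry])
        if self.n_protein_ligands + self.n_waters != cn:
            raise ValueError(
                f"{self.geometry} needs {cn} donors; got "
                f"{self.n_protein_ligands}+{self.n_waters}"
            )
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if len(self.bridged_residues) > self.n_waters:
            raise ValueError("each bridged residue needs a first-shell water")


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = np.cross(u, ref)
    p /= np.linalg.norm(p)
    return p, np.cross(u, p)


class _Builder:
    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.serial = 0

    def add(self, name, element, resname, resnum, chain, pos, b=DEFAULT_B, het=False):
        self.serial += 1
        self.atoms.append(
            Atom(
                serial=self.serial,
                name=name,
                element=element,
                altloc="",
                residue_name=resname,
                residue_number=resnum,
                insertion_code="",
                chain_id=chain,
                position=tuple(float(c) for c in pos),
                occupancy=1.0,
                b_factor=float(b),
                record_kind="hetatm" if het else "atom",
            )
        )


def _ligand_residue(
    bld: _Builder, resname: str, donor: str, resnum: int, donor_pos: np.ndarray,
    u: np.ndarray, b: float,
) -> None:
    """A chemically plausible residue whose named donor sits at donor_pos.

    Remaining atoms extend outward along u so that only the donor can fall
    in the metal's first shell.
    """
    p, _q = _perp_basis(u)
    bld.add(donor, donor[0], resname, resnum, "A", donor_pos, b)
    if resname == "ASP":
        cg = donor_pos + 1.0 * u + 0.8 * p
        bld.add("CG", "C", resname, resnum, "A", cg, b)
        bld.add("OD2", "O", resname, resnum, "A", cg + 0.5 * u + 1.15 * p, b)
        cb = cg + 1.5 * u
    else:  # SER / THR hydroxyls
        cb = donor_pos + 1.43 * u + 0.3 * p
        bld.add("CB", "C", resname, resnum, "A", cb, b)
        if resname == "THR":
            bld.add("CG2", "C", resname, resnum, "A", cb + 0.9 * u + 1.2 * p, b)
    ca = cb + 1.2 * u + 0.9 * p
    bld.add("CA", "C", resname, resnum, "A", ca, b)
    bld.add("N", "N", resname, resnum, "A", ca + 0.8 * u + 1.2 * p, b)
    c = ca + 1.3 * u - 0.7 * p
    bld.add("C", "C", resname, resnum, "A", c, b)
    bld.add("O", "O", resname, resnum, "A", c + 1.0 * u - 0.7 * p, b)
    if resname == "ASP":
        bld.add("CB", "C", resname, resnum, "A", cb, b)


def _scaffold_b(resnum: int, b_pattern: dict) -> float:
    for (lo, hi), b in b_pattern.items():
        if lo <= resnum <= hi:
            return float(b)
    return DEFAULT_B


def make_site_structure(spec: SiteSpec) -> tuple[Structure, dict]:
    """Build the fixture structure and its ground-truth metadata."""
    rng = np.random.default_rng(spec.seed)
    vertices = IDEAL_GEOMETRIES[spec.geometry]
    bld = _Builder()
    meta: dict = {
        "geometry": spec.geometry,
        "metal": spec.metal,
        "bond_length": spec.bond_length,
        "coordination_number": len(vertices),
        "n_protein_direct": spec.n_protein_ligands,
        "n_water_direct": spec.n_waters,
        "direct_donors": [],
        "bridged": [],
        "salt_bridge": None,
        "b_pattern": {f"{lo}-{hi}": b for (lo, hi), b in spec.b_pattern.items()},
        "seed": spec.seed,
    }

    # metal
    bld.add(spec.metal.upper(), spec.metal, spec.metal.upper(), 501, "M",
            METAL_CENTER, b=15.0, het=True)

    # first shell
    donor_positions = METAL_CENTER + spec.bond_length * vertices
    if spec.jitter_sd > 0:
        donor_positions = donor_positions + rng.normal(
            0.0, spec.jitter_sd, size=donor_positions.shape
        )
    resnum = 150
    water_num = 601
    water_slots: list[tuple[np.ndarray, np.ndarray]] = []
    for i, vpos in enumerate(donor_positions):
        u = vertices[i] / np.linalg.norm(vertices[i])
        if i < spec.n_protein_ligands:
            resname, donor = PROTEIN_DONORS[i % len(PROTEIN_DONORS)]
            _ligand_residue(bld, resname, donor, resnum, vpos, u, DEFAULT_B)
            meta["direct_donors"].append(
                {"residue": f"{resname}{resnum}", "atom": donor, "role": "protein"}
            )
            resnum += 2
        else:
            bld.add("O", "O", "HOH", water_num, "W", vpos, b=25.0, het=True)
            meta["direct_donors"].append(
                {"residue": f"HOH{water_num}", "atom": "O", "role": "water"}
            )
            water_slots.append((vpos, u))
            water_num += 1

    # water-bridged second shell: donor 2.8 A behind a first-shell water
    for j, resname in enumerate(spec.bridged_residues):
        wpos, u = water_slots[j]
        donor = dict(PROTEIN_DONORS)[resname]
        dpos = wpos + 2.8 * u
        _ligand_residue(bld, resname, donor, resnum, dpos, u, DEFAULT_B)
        meta["bridged"].append(
            {
                "residue": f"{resname}{resnum}",
                "atom": donor,
                "via_water": f"W:{601 + j}",
                "water_donor_distance": 2.8,
            }
        )
        resnum += 2

    # poly-Ala scaffold with the B pattern, well away from the site
    start = max(resnum, 201)
    origin = METAL_CENTER + np.array([25.0, 0.0, 0.0])
    for k in range(spec.scaffold_length):
        rn = start + k
        b = _scaffold_b(rn, spec.b_pattern)
        base = origin + np.array([0.0, 3.8 * k, 0.0])
        bld.add("N", "N", "ALA", rn, "A", base + [0.0, 0.0, 0.0], b)
        bld.add("CA", "C", "ALA", rn, "A", base + [1.2, 0.8, 0.3], b)
        bld.add("C", "C", "ALA", rn, "A", base + [2.4, 1.4, 0.0], b)
        bld.add("O", "O", "ALA", rn, "A", base + [3.3, 1.2, 0.9], b)
        bld.add("CB", "C", "ALA", rn, "A", base + [1.4, 1.6, 1.6], b)
    meta["scaffold_range"] = [start, start + spec.scaffold_length - 1]

    # optional Asp-Arg salt bridge, far from both site and scaffold
    if spec.salt_bridge is not None:
        d = float(spec.salt_bridge)
        sb_origin = METAL_CENTER + np.array([-25.0, 0.0, 0.0])
        rn_asp, rn_arg = 152, 192
        u = np.array([0.0, 1.0, 0.0])
        od1 = sb_origin
        _build_asp(bld, rn_asp, od1, DEFAULT_B)
        nh1 = od1 + np.array([0.0, d, 0.0])
        _build_arg(bld, rn_arg, nh1, DEFAULT_B)
        meta["salt_bridge"] = {
            "acidic": f"ASP{rn_asp}",
            "basic": f"ARG{rn_arg}",
            "distance": d,
        }

    struct = Structure(id=f"synthsite-{spec.geometry}-{spec.seed}", atoms=bld.atoms,
                       cell=(80.0, 80.0, 80.0, 90.0, 90.0, 90.0), space_group="P 1")
    return struct, meta


def _build_asp(bld: _Builder, resnum: int, od1: np.ndarray, b: float) -> None:
    u = np.array([-1.0, 0.0, 0.0])
    bld.add("OD1", "O", "ASP", resnum, "B", od1, b)
    cg = od1 + np.array([-1.1, -0.6, 0.0])
    bld.add("CG", "C", "ASP", resnum, "B", cg, b)
    bld.add("OD2", "O", "ASP", resnum, "B", cg + np.array([-0.4, -1.15, 0.0]), b)
    cb = cg + np.array([-1.5, 0.3, 0.4])
    bld.add("CB", "C", "ASP", resnum, "B", cb, b)
    ca = cb + np.array([-1.2, 0.9, -0.3])
    bld.add("CA", "C", "ASP", resnum, "B", ca, b)
    bld.add("N", "N", "ASP", resnum, "B", ca + np.array([-0.9, 1.1, 0.2]), b)
    c = ca + np.array([-1.4, -0.6, 0.0])
    bld.add("C", "C", "ASP", resnum, "B", c, b)
    bld.add("O", "O", "ASP", resnum, "B", c + np.array([-0.9, -0.9, 0.0]), b)


def _build_arg(bld: _Builder, resnum: int, nh1: np.ndarray, b: float) -> None:
    bld.add("NH1", "N", "ARG", resnum, "B", nh1, b)
    cz = nh1 + np.array([0.4, 1.25, 0.0])
    bld.add("CZ", "C", "ARG", resnum, "B", cz, b)
    bld.add("NH2", "N", "ARG", resnum, "B", cz + np.array([1.3, 0.4, 0.0]), b)
    bld.add("NE", "N", "ARG", resnum, "B", cz + np.array([-0.6, 1.2, 0.0]), b)
    cd = cz + np.array([-0.4, 2.6, 0.3])
    bld.add("CD", "C", "ARG", resnum, "B", cd, b)
    cg = cd + np.array([0.3, 1.4, 0.5])
    bld.add("CG", "C", "ARG", resnum, "B", cg, b)
    cb = cg + np.array([0.9, 1.2, -0.2])
    bld.add("CB", "C", "ARG", resnum, "B", cb, b)
    ca = cb + np.array([0.4, 1.4, 0.4])
    bld.add("CA", "C", "ARG", resnum, "B", ca, b)
    bld.add("N", "N", "ARG", resnum, "B", ca + np.array([1.2, 0.8, 0.0]), b)
    c = ca + np.array([-0.8, 1.2, 0.0])
    bld.add("C", "C", "ARG", resnum, "B", c, b)
    bld.add("O", "O", "ARG", resnum, "B", c + np.array([-1.1, 0.8, 0.0]), b)


def make_displaced_pair(
    spec: SiteSpec,
    metal_offset: float = 0.0,
    residue_offsets: dict[tuple[int, str], float] | None = None,
) -> tuple[Structure, Structure, dict]:
    """A structure and a copy with the metal / named atoms nudged.

    ``residue_offsets`` maps (residue_number, atom_name) to a displacement
    magnitude in Angstrom.  Displacement directions are random unit vectors
    drawn from the spec's seed and recorded in the metadata, so the pair has
    exact ground truth for superposition and displacement metrics.
    """
    if metal_offset < 0 or (residue_offsets and min(residue_offsets.values()) < 0):
        raise ValueError("offsets must be non-negative")
    a, meta = make_site_structure(spec)
    rng = np.random.default_rng(spec.seed + 7919)
    residue_offsets = residue_offsets or {}

    known = {(at.residue_number, at.name) for at in a.atoms if at.record_kind == "atom"}
    for key in residue_offsets:
        if key not in known:
            raise ValueError(f"residue offset target {key} not in fixture")

    displaced: dict = {"metal_offset": metal_offset, "residue_offsets": {}}
    new_atoms: list[Atom] = []
    for at in a.atoms:
        if at.record_kind == "hetatm" and at.element == spec.metal and metal_offset > 0:
            d = _unit(rng)
            new_atoms.append(at.moved_to(at.xyz + metal_offset * d))
            displaced["metal_direction"] = d.tolist()
        elif (at.residue_number, at.name) in residue_offsets:
            mag = residue_offsets[(at.residue_number, at.name)]
            d = _unit(rng)
            new_atoms.append(at.moved_to(at.xyz + mag * d))
            displaced["residue_offsets"][f"{at.residue_number}:{at.name}"] = {
                "magnitude": mag,
                "direction": d.tolist(),
            }
        else:
            new_atoms.append(at)
    b = Structure(id=a.id + "-displaced", atoms=new_atoms, cell=a.cell,
                  space_group=a.space_group)
    meta = dict(meta)
    meta["displacements"] = displaced
    return a, b, meta


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_msa_fixture(
    n_rows: int,
    length: int,
    conserved_pairs: dict[int, str] | None = None,
    conserved_rows: list[int] | None = None,
    seed: int = 0,
) -> MultipleSeqAlignment:
    """Random alignment with specified columns pinned to specified letters.

    ``conserved_pairs`` maps 0-based columns to the letter held there;
    ``conserved_rows`` restricts the pinning to those row indices (default
    all rows).  Row 0 is named ``ref``; others ``seq1`` ... Deterministic
    under ``seed``.  Pinned columns are guaranteed to differ from the pin in
    unpinned rows, so conservation fractions are exact by construction.
    """
    conserved_pairs = conserved_pairs or {}
    for col in conserved_pairs:
        if not 0 <= col < length:
            raise ValueError(f"conserved column {col} outside alignment")
    rng = np.random.default_rng(seed)
    rows = []
    pinned = set(conserved_rows) if conserved_rows is not None else set(range(n_rows))
    if conserved_rows is not None and any(r >= n_rows for r in pinned):
        raise ValueError("conserved row index out of range")
    letters = np.array(list(AMINO_LETTERS))
    for r in range(n_rows):
        seq = list(rng.choice(letters, size=length))
        for col, want in conserved_pairs.items():
            if r in pinned:
                seq[col] = want
            elif seq[col] == want:  # make non-conservation exact
                seq[col] = next(ch for ch in AMINO_LETTERS if ch != want)
        rid = "ref" if r == 0 else f"seq{r}"
        rows.append(SeqRecord(Seq("".join(seq)), id=rid, description=""))
    return MultipleSeqAlignment(rows)


def write_fixture(struct: Structure, meta: dict, path: str | Path) -> tuple[Path, Path]:
    """Write fixture PDB plus JSON ground-truth sidecar (<path>.json)."""
    path = Path(path)
    write_structure(struct, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return path, sidecar
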