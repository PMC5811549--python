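"""Coordinate-file I/O, atom selection, and crystal-cell utilities.

Reading and writing go through :mod:`gemmi`; the in-memory model is a flat,
file-ordered atom table (:class:`Structure`) that keeps author residue
numbering, alternate locations, occupancies and isotropic B-factors exactly
as deposited.  A small selection mini-language (see :func:`select_atoms`)
covers the chain / residue / atom / element / record-kind filters the
analysis modules need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "AtomSet",
    "CellReport",
    "read_structure",
    "write_structure",
    "select_atoms",
    "matthews_solvent",
    "WATER_NAMES",
]

#: Residue names treated as water.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: 1.23 A^3/Da == the reciprocal of the canonical 0.74 cm^3/g protein
#: partial specific volume times Avogadro bookkeeping; used by
#: :func:`matthews_solvent`.
PROTEIN_VOLUME_CONSTANT = 1.23


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record.

    ``record_kind`` is ``"atom"`` for polymer atoms and ``"hetatm"`` for
    heterogens (waters, ions, ligands).  ``position`` is a length-3 float
    tuple in Angstrom.
    """

    serial: int
    name: str
    element: str
    altloc: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    position: tuple[float, float, float]
    occupancy: float
    b_factor: float
    record_kind: str  # "atom" | "hetatm"

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor {self.b_factor}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("non-finite coordinate")
        if self.record_kind not in ("atom", "hetatm"):
            raise ValueError(f"bad record_kind {self.record_kind!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    def moved_to(self, position: Iterable[float]) -> "Atom":
        return replace(self, position=tuple(float(c) for c in position))


@dataclass
class Structure:
    """A parsed coordinate file: flat atom list in file order plus cell."""

    id: str
    atoms: list[Atom] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.insertion_code, a.name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in {self.id}")
            seen.add(key)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def chain(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class AtomSet:
    """An ordered, duplicate-free selection of atoms from one structure."""

    source: str
    atoms: list[Atom]

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class CellReport:
    """Matthews-coefficient arithmetic for one crystal form."""

    v_cell: float  # A^3
    z_total: int  # molecules per unit cell
    v_m: float  # A^3/Da
    solvent_fraction: float


def _classify_element(name: str, element: str, residue_name: str, het: bool) -> str:
    """Resolve the element symbol; fall back to residue name for bare metals.

    An atom *named* CA is ambiguous (alpha-carbon vs calcium ion); the element
    column plus record kind disambiguates.  Only when the element column is
    blank do we trust residue names CA/MG on HETATM records.
    """
    el = element.strip().capitalize()
    if el and el != "X":
        return el
    if het and residue_name in ("CA", "MG", "ZN", "MN", "NA", "K", "CL"):
        return residue_name.capitalize()
    return name.strip()[:1].capitalize() if name.strip() else "X"


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path : file path
    format : ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from extension /
        content).

    All ATOM/HETATM records of the first model are kept, including altloc
    variants.  Waters and ions arrive as ``record_kind == "hetatm"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "cif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=_classify_element(
                            at.name, at.element.name, res.name, het
                        ),
                        altloc=at.altloc if at.altloc != "\0" else "",
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_factor=max(at.b_iso, 0.0),
                        record_kind="hetatm" if het else "atom",
                    )
                )
    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = st.spacegroup_hm or None
    sid = (st.name or path.stem).strip() or path.stem
    return Structure(id=sid, atoms=atoms, cell=cell, space_group=sg)


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> Path:
    """Write ``s`` as a PDB file; round-trips the atom table.

    Serials above 99 999 are handled by gemmi's hybrid-36 encoding on write;
    re-reading such files restores sequential numbering.
    """
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    path = Path(path)
    st = gemmi.Structure()
    st.name = s.id
    if s.cell is not None:
        st.cell = gemmi.UnitCell(*s.cell)
    if s.space_group:
        st.spacegroup_hm = s.space_group
    # gemmi's add_chain/add_residue copy their argument, so assemble
    # bottom-up: group atoms, fill residues, then attach.
    grouped: dict[str, list[tuple[tuple, list[Atom]]]] = {}
    for a in s.atoms:
        rk = a.residue_key + (a.residue_name,)
        chain_groups = grouped.setdefault(a.chain_id, [])
        if not chain_groups or chain_groups[-1][0] != rk:
            chain_groups.append((rk, []))
        chain_groups[-1][1].append(a)
    model = gemmi.Model("1")
    for chain_id, chain_groups in grouped.items():
        ch = gemmi.Chain(chain_id)
        for rk, res_atoms in chain_groups:
            res = gemmi.Residue()
            res.name = rk[3]
            res.seqid = gemmi.SeqId(rk[1], rk[2] or " ")
            res.het_flag = "H" if res_atoms[0].record_kind == "hetatm" else "A"
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.altloc = a.altloc or "\0"
                at.pos = gemmi.Position(*a.position)
                at.occ = a.occupancy
                at.b_iso = a.b_factor
                at.serial = a.serial
                res.add_atom(at)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

_QUERY_KEYS = {"chain", "resi", "resn", "name", "element", "record", "altloc"}


def _parse_values(key: str, raw: str) -> set:
    vals = [v for v in raw.replace(",", " ").split() if v]
    if not vals:
        raise ValueError(f"selection clause '{key}' has no values")
    if key == "resi":
        nums: set[int] = set()
        for v in vals:
            if "-" in v[1:]:  # allow negative start
                lo, hi = v.rsplit("-", 1)
                nums.update(range(int(lo), int(hi) + 1))
            else:
                nums.add(int(v))
        return nums
    if key == "element":
        return {v.capitalize() for v in vals}
    if key == "record":
        bad = set(vals) - {"atom", "hetatm"}
        if bad:
            raise ValueError(f"unknown record kind(s) {bad}")
        return set(vals)
    return set(vals)


def _parse_query(query: str) -> dict[str, set]:
    """Parse e.g. ``"chain A and resi 150-154 and name OG and element O"``."""
    clauses: dict[str, set] = {}
    for part in query.split(" and "):
        part = part.strip()
        if not part:
            continue
        tokens = part.split(None, 1)
        if len(tokens) != 2 or tokens[0] not in _QUERY_KEYS:
            raise ValueError(
                f"malformed selection clause {part!r}; keys: {sorted(_QUERY_KEYS)}"
            )
        key = tokens[0]
        if key in clauses:
            raise ValueError(f"duplicate clause {key!r}")
        clauses[key] = _parse_values(key, tokens[1])
    if not clauses:
        raise ValueError("empty selection query")
    return clauses


def select_atoms(s: Structure | AtomSet, query: str) -> AtomSet:
    """Select atoms with a small ``"key values and key values"`` language.

    Keys: ``chain``, ``resi`` (numbers / inclusive ranges), ``resn``,
    ``name``, ``element``, ``record`` (atom|hetatm), ``altloc``.
    Results keep file order.  Unless an ``altloc`` clause is given, only the
    highest-occupancy altloc variant of each atom is kept (ties broken by
    altloc letter order).
    """
    clauses = _parse_query(query)
    atoms = s.atoms if isinstance(s, (Structure, AtomSet)) else list(s)
    out: list[Atom] = []
    for a in atoms:
        if "chain" in clauses and a.chain_id not in clauses["chain"]:
            continue
        if "resi" in clauses and a.residue_number not in clauses["resi"]:
            continue
        if "resn" in clauses and a.residue_name not in clauses["resn"]:
            continue
        if "name" in clauses and a.name not in clauses["name"]:
            continue
        if "element" in clauses and a.element not in clauses["element"]:
            continue
        if "record" in clauses and a.record_kind not in clauses["record"]:
            continue
        if "altloc" in clauses and a.altloc not in clauses["altloc"]:
            continue
        out.append(a)
    if "altloc" not in clauses:
        out = prune_altlocs(out)
    src = s.id if isinstance(s, Structure) else s.source
    return AtomSet(source=src, atoms=out)


def prune_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    """Keep one variant per atom site: highest occupancy, then altloc order."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        elif (a.occupancy, _altloc_rank(a)) > (cur.occupancy, _altloc_rank(cur)):
            best[key] = a
    return [best[k] for k in order]


def _altloc_rank(a: Atom) -> float:
    # empty altloc wins ties over 'A' > 'B' ...; encode as descending rank
    if not a.altloc:
        return 0.0
    return -ord(a.altloc)


# ---------------------------------------------------------------------------
# crystal-cell arithmetic
# ---------------------------------------------------------------------------

def cell_volume(cell: Sequence[float]) -> float:
    """Unit-cell volume (A^3) from the general triclinic formula."""
    a, b, c, al, be, ga = cell
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0:
        raise ValueError(f"degenerate cell {tuple(cell)}")
    return a * b * c * math.sqrt(arg)


def matthews_solvent(
    cell: Sequence[float],
    z_spacegroup: int,
    n_mol_per_au: int,
    mass_per_mol: float,
    volume_constant: float = PROTEIN_VOLUME_CONSTANT,
) -> CellReport:
    """Matthews coefficient V_m and solvent content of a crystal.

    ``V_m = V_cell / (Z * n_AU * M)`` in A^3/Da and
    ``solvent = 1 - volume_constant / V_m`` with the standard 1.23 A^3/Da
    protein constant (0.74 cm^3/g partial specific volume).
    """
    if z_spacegroup <= 0 or n_mol_per_au <= 0 or mass_per_mol <= 0:
        raise ValueError("z, n and mass must be positive")
    v = cell_volume(cell)
    v_m = v / (z_spacegroup * n_mol_per_au * mass_per_mol)
    solvent = 1.0 - volume_constant / v_m
    return CellReport(
        v_cell=v,
        z_total=z_spacegroup * n_mol_per_au,
        v_m=v_m,
        solvent_fraction=solvent,
    )
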