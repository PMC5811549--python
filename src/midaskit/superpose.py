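"""Rigid-body least-squares superposition and displacement metrics.

The workhorse is the Kabsch algorithm (SVD of the cross-covariance matrix
with a determinant sign correction, so the rotation is always proper).  An
optional iterative outlier-rejection loop drops atom pairs whose residual
displacement is an outlier relative to the spread of the current fit and
refits, which mimics what molecular-graphics "align" commands do and is the
appropriate protocol when comparing near-identical crystal structures that
differ in a few flexible loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structio import Atom, AtomSet, Structure

__all__ = [
    "AtomPairing",
    "SuperpositionResult",
    "pair_atoms",
    "superpose",
    "displacement",
    "metal_displacement",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


@dataclass
class AtomPairing:
    """An ordered one-to-one correspondence between atoms of two inputs."""

    pairs: list[tuple[Atom, Atom]]
    method: str  # "explicit-map" | "sequence-alignment" | "identity"
    coverage: float  # fraction of A residues that found a partner

    def __len__(self) -> int:
        return len(self.pairs)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        xa = np.array([p[0].position for p in self.pairs], dtype=float)
        xb = np.array([p[1].position for p in self.pairs], dtype=float)
        return xa, xb


@dataclass
class SuperpositionResult:
    """Kabsch fit of B onto A: ``x_b' = rotation @ x_b + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs_used: int
    pairing: AtomPairing
    used: list[tuple[Atom, Atom]] = field(default_factory=list)
    rejected: list[tuple[Atom, Atom]] = field(default_factory=list)
    per_pair_displacement: np.ndarray = field(default_factory=lambda: np.empty(0))

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid motion (B frame -> A frame) to coordinates."""
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation


def _atoms_of(x: Structure | AtomSet | Sequence[Atom]) -> list[Atom]:
    if isinstance(x, (Structure, AtomSet)):
        return list(x.atoms)
    return list(x)


def _protein_residues(atoms: Sequence[Atom]) -> list[tuple[tuple, list[Atom]]]:
    """Group polymer heavy atoms by residue, preserving file order."""
    groups: list[tuple[tuple, list[Atom]]] = []
    for a in atoms:
        if a.record_kind != "atom" or a.is_hydrogen or a.is_water:
            continue
        key = a.residue_key
        if not groups or groups[-1][0] != key:
            groups.append((key, []))
        groups[-1][1].append(a)
    return groups


def _policy_filter(atoms: Sequence[Atom], atom_policy) -> list[Atom]:
    if atom_policy == "all-heavy":
        return [a for a in atoms if not a.is_hydrogen]
    if atom_policy == "backbone":
        return [a for a in atoms if a.name in BACKBONE_NAMES]
    # explicit atom-name tuple/list
    names = set(atom_policy)
    return [a for a in atoms if a.name in names]


def _align_residue_indices(res_a, res_b) -> list[tuple[int, int]]:
    """Pair residue indices via global sequence alignment (BLOSUM62, 10/0.5)."""
    seq_a = "".join(THREE_TO_ONE.get(g[1][0].residue_name, "X") for g in res_a)
    seq_b = "".join(THREE_TO_ONE.get(g[1][0].residue_name, "X") for g in res_b)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    aln = aligner.align(seq_a, seq_b)[0]
    out: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        out.extend(zip(range(a0, a1), range(b0, b1)))
    return out


def pair_atoms(
    a: Structure | AtomSet | Sequence[Atom],
    b: Structure | AtomSet | Sequence[Atom],
    residue_map: Mapping[int, int] | None = None,
    atom_policy="all-heavy",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> AtomPairing:
    """Build an atom-level correspondence between two structures.

    With ``residue_map`` (author residue number in A -> number in B) the
    correspondence is explicit, e.g. the MIDAS map
    ``{150: 151, 152: 153, 154: 155, 220: 221, 253: 254}``; otherwise
    residues are paired by global sequence alignment.  Within each paired
    residue, only atoms with identical names on both sides are paired,
    filtered by ``atom_policy`` (``"all-heavy"``, ``"backbone"``, or an
    explicit collection of atom names).
    """
    atoms_a = _atoms_of(a)
    atoms_b = _atoms_of(b)
    if chain_a is not None:
        atoms_a = [x for x in atoms_a if x.chain_id == chain_a]
    if chain_b is not None:
        atoms_b = [x for x in atoms_b if x.chain_id == chain_b]
    if not atoms_a or not atoms_b:
        raise ValueError("empty input to pair_atoms")
    res_a = _protein_residues(atoms_a)
    res_b = _protein_residues(atoms_b)

    if residue_map is not None:
        by_num_a = {k[0][1]: k for k in res_a}
        by_num_b = {k[0][1]: k for k in res_b}
        # residue numbers must be unambiguous within the selection
        if len(by_num_a) != len({k[0] for k in res_a}) or len(by_num_b) != len(
            {k[0] for k in res_b}
        ):
            raise ValueError(
                "ambiguous residue numbers; restrict to one chain for explicit maps"
            )
        idx_pairs = []
        for na, nb in residue_map.items():
            if na not in by_num_a or nb not in by_num_b:
                raise KeyError(f"residue map entry {na}->{nb} not found")
            idx_pairs.append((res_a.index(by_num_a[na]), res_b.index(by_num_b[nb])))
        method = "explicit-map"
    else:
        idx_pairs = _align_residue_indices(res_a, res_b)
        method = "sequence-alignment"

    pairs: list[tuple[Atom, Atom]] = []
    for ia, ib in idx_pairs:
        aa = _policy_filter(res_a[ia][1], atom_policy)
        bb = {at.name: at for at in _policy_filter(res_b[ib][1], atom_policy)}
        for at in aa:
            if at.name in bb:
                pairs.append((at, bb[at.name]))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} atom pairs; need at least 3")
    coverage = len(idx_pairs) / max(len(res_a), 1)
    return AtomPairing(pairs=pairs, method=method, coverage=coverage)


def pairing_to_tsv(p: AtomPairing, path) -> None:
    """Write a pairing as two-column TSV: chain:resnum:atom <TAB> chain:resnum:atom."""
    with open(path, "w") as fh:
        for aa, ab in p.pairs:
            fh.write(
                f"{aa.chain_id}:{aa.residue_number}:{aa.name}\t"
                f"{ab.chain_id}:{ab.residue_number}:{ab.name}\n"
            )


def pairing_from_tsv(
    a: Structure | AtomSet, b: Structure | AtomSet, path
) -> AtomPairing:
    """Rebuild a pairing from the TSV written by :func:`pairing_to_tsv`."""

    def index(atoms):
        return {(x.chain_id, x.residue_number, x.name): x for x in _atoms_of(atoms)}

    ia, ib = index(a), index(b)
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            left, right = line.split("\t")
            ka = left.strip().split(":")
            kb = right.strip().split(":")
            key_a = (ka[0], int(ka[1]), ka[2])
            key_b = (kb[0], int(kb[1]), kb[2])
            if key_a not in ia or key_b not in ib:
                raise KeyError(f"pairing row {line.strip()!r} not resolvable")
            pairs.append((ia[key_a], ib[key_b]))
    if len(pairs) < 3:
        raise ValueError("pairing TSV yields fewer than 3 pairs")
    return AtomPairing(pairs=pairs, method="explicit-map", coverage=float("nan"))


def result_to_json_dict(r: SuperpositionResult) -> dict:
    """JSON-serializable summary of a fit."""
    return {
        "rmsd_A": r.rmsd,
        "n_pairs_used": r.n_pairs_used,
        "n_rejected": len(r.rejected),
        "rotation": r.rotation.tolist(),
        "translation": r.translation.tolist(),
        "per_pair_displacement_A": r.per_pair_displacement.tolist(),
    }


def kabsch(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing ``|xa - (xb R^T + t)|``."""
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    h = (xb - cb).T @ (xa - ca)
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = ca - r @ cb
    return r, t


def superpose(
    p: AtomPairing,
    reject: tuple[float, int] | None = None,
) -> SuperpositionResult:
    """Least-squares superposition of the paired atoms (Kabsch).

    ``reject=(sigma, max_cycles)`` enables iterative outlier rejection: after
    each fit, pairs whose displacement exceeds ``mean + sigma * sd`` of the
    current displacement distribution are dropped and the fit recomputed,
    until convergence or ``max_cycles``; at least 3 pairs are always kept.
    RMSD is reported over the retained pairs.
    """
    if len(p) < 3:
        raise ValueError("need at least 3 pairs")
    used = list(p.pairs)
    rejected: list[tuple[Atom, Atom]] = []
    cycles = 0 if reject is None else int(reject[1])
    sigma = None if reject is None else float(reject[0])

    while True:
        xa = np.array([q[0].position for q in used])
        xb = np.array([q[1].position for q in used])
        if np.linalg.matrix_rank(xa - xa.mean(axis=0), tol=1e-8) < 2:
            raise ValueError("degenerate (collinear) geometry")
        r, t = kabsch(xa, xb)
        disp = np.linalg.norm(xa - (xb @ r.T + t), axis=1)
        if cycles <= 0 or sigma is None:
            break
        thr = disp.mean() + sigma * disp.std()
        keep = disp <= max(thr, 1e-12)
        if keep.all() or keep.sum() < 3:
            break
        rejected.extend(q for q, k in zip(used, keep) if not k)
        used = [q for q, k in zip(used, keep) if k]
        cycles -= 1

    rmsd = float(np.sqrt(np.mean(disp**2)))
    return SuperpositionResult(
        rotation=r,
        translation=t,
        rmsd=rmsd,
        n_pairs_used=len(used),
        pairing=p,
        used=used,
        rejected=rejected,
        per_pair_displacement=disp,
    )


def displacement(
    r: SuperpositionResult,
    residue_number: int,
    atom_name: str,
    chain: str | None = None,
) -> float:
    """Distance (A) between a paired atom in A and its B counterpart after the fit.

    The selector addresses the atom in the B frame by author residue number
    and atom name (optionally chain).
    """
    for aa, ab in r.pairing.pairs:
        if (
            ab.residue_number == residue_number
            and ab.name == atom_name
            and (chain is None or ab.chain_id == chain)
        ):
            return float(np.linalg.norm(aa.xyz - r.transform(ab.xyz)))
    raise KeyError(
        f"no paired atom {chain or '*'}:{residue_number}:{atom_name} in B frame"
    )


def metal_displacement(r: SuperpositionResult, metal_a: Atom, metal_b: Atom) -> float:
    """Distance between two metal ions after superposing on protein atoms only.

    The metals must not have taken part in the fit — the fit is defined by
    the protein frame and the metals report how far the ion moved within it.
    """
    in_fit = {id(x) for pair in r.pairing.pairs for x in pair}
    if id(metal_a) in in_fit or id(metal_b) in in_fit:
        raise ValueError("metal atom was part of the superposition pairing")
    if metal_a.record_kind != "hetatm" or metal_b.record_kind != "hetatm":
        raise ValueError("metal_displacement expects hetero (ion) atoms")
    return float(np.linalg.norm(metal_a.xyz - r.transform(metal_b.xyz)))
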