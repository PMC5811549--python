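"""Salt-bridge detection and residue-pair conservation across an MSA.

A salt bridge is recorded when any side-chain carboxylate oxygen of an
Asp/Glu lies within a distance cutoff (default 4.0 A, the standard
convention) of a charged side-chain nitrogen of Arg/Lys/His.  Conservation
of a residue pair (e.g. the Glu-Arg bridge that braces the alpha2 I-domain
MIDAS loops) is scored by mapping reference residue numbers to alignment
columns and checking the required identities in every other row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

from .structio import Atom, Structure

__all__ = [
    "SaltBridge",
    "ConservationReport",
    "find_salt_bridges",
    "read_msa",
    "pair_conservation",
    "global_align",
]

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
DEFAULT_CUTOFF = 4.0  # A


@dataclass(frozen=True)
class SaltBridge:
    """Closest acidic-O / basic-N contact of one residue pair."""

    acidic: Atom
    basic: Atom
    distance: float

    def __str__(self) -> str:  # e.g. "E152(OE1)-R192(NH1) 2.85 A"
        a, b = self.acidic, self.basic
        return (
            f"{a.residue_name}{a.residue_number}({a.name})-"
            f"{b.residue_name}{b.residue_number}({b.name}) {self.distance:.2f} A"
        )


@dataclass
class ConservationReport:
    """Presence of required identities at mapped alignment columns."""

    reference_id: str
    positions: list[int]  # reference residue numbers queried
    columns: list[int]  # 0-based alignment columns
    required: list[str]
    per_sequence: dict[str, bool]
    fraction_conserved: float


def find_salt_bridges(
    s: Structure,
    chain: str | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    include_his: bool = True,
) -> list[SaltBridge]:
    """All Asp/Glu - Arg/Lys(/His) contacts within ``cutoff`` (intra-chain).

    One record per residue pair, carrying the minimum atom-atom distance.
    """
    basic_atoms = dict(BASIC_ATOMS)
    if not include_his:
        basic_atoms.pop("HIS")
    acidic = [
        a
        for a in s.atoms
        if a.record_kind == "atom"
        and a.residue_name in ACIDIC_ATOMS
        and a.name in ACIDIC_ATOMS[a.residue_name]
        and (chain is None or a.chain_id == chain)
    ]
    basic = [
        a
        for a in s.atoms
        if a.record_kind == "atom"
        and a.residue_name in basic_atoms
        and a.name in basic_atoms[a.residue_name]
        and (chain is None or a.chain_id == chain)
    ]
    best: dict[tuple, SaltBridge] = {}
    for aa in acidic:
        for bb in basic:
            if aa.chain_id != bb.chain_id:
                continue
            d = float(np.linalg.norm(aa.xyz - bb.xyz))
            if d > cutoff:
                continue
            key = (aa.residue_key, bb.residue_key)
            if key not in best or d < best[key].distance:
                best[key] = SaltBridge(acidic=aa, basic=bb, distance=d)
    return sorted(
        best.values(),
        key=lambda sb: (sb.acidic.chain_id, sb.acidic.residue_number, sb.basic.residue_number),
    )


def read_msa(path: str | Path, format: str = "fasta"):
    """Read an alignment (``fasta`` or ``clustal``) as a Bio.Align object."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"cannot parse alignment {path}: {exc}") from exc
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment rows in {path}")
    return aln


def _column_of(ref_gapped: str, residue_number: int, ref_start: int) -> int:
    """Alignment column (0-based) of an ungapped reference residue number."""
    target = residue_number - ref_start  # 0-based ungapped index
    if target < 0:
        raise IndexError(f"position {residue_number} before reference start")
    idx = -1
    for col, ch in enumerate(ref_gapped):
        if ch != "-":
            idx += 1
            if idx == target:
                return col
    raise IndexError(f"position {residue_number} beyond reference length")


def pair_conservation(
    aln,
    reference_id: str,
    positions: Sequence[int],
    required_identities: Sequence[str],
    ref_start: int = 1,
) -> ConservationReport:
    """Score every non-reference row for carrying the required residues.

    ``positions`` are author residue numbers in the (ungapped) reference
    sequence, whose first residue is number ``ref_start``.  A sequence is
    conserved when it matches all required letters at the mapped columns.
    """
    if len(positions) != len(required_identities):
        raise ValueError("positions and required_identities differ in length")
    ref = None
    for rec in aln:
        if rec.id == reference_id:
            ref = str(rec.seq)
            break
    if ref is None:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    cols = [_column_of(ref, p, ref_start) for p in positions]
    per: dict[str, bool] = {}
    for rec in aln:
        if rec.id == reference_id:
            continue
        seq = str(rec.seq)
        per[rec.id] = all(
            seq[c].upper() == want.upper() for c, want in zip(cols, required_identities)
        )
    frac = sum(per.values()) / len(per) if per else 0.0
    return ConservationReport(
        reference_id=reference_id,
        positions=list(positions),
        columns=cols,
        required=[r.upper() for r in required_identities],
        per_sequence=per,
        fraction_conserved=frac,
    )


def global_align(seq_a: str, seq_b: str):
    """Global pairwise alignment (BLOSUM62, affine gaps 10/0.5).

    Convenience for building small test alignments; externally generated
    alignments are accepted everywhere else.
    """
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner.align(seq_a, seq_b)[0]
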