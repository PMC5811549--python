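"""Residue-averaged B-factor (flexibility) profiles and loop comparisons.

Crystallographic B-factors report isotropic positional smearing and serve
as per-residue flexibility proxies.  Absolute B scales differ between
crystals (resolution, refinement), so cross-structure comparison is done on
per-chain z-scored profiles; region (loop) means of the normalized profiles
are then directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structio import Structure

__all__ = [
    "FlexibilityProfile",
    "RegionDef",
    "DEFAULT_LOOPS",
    "bfactor_profile",
    "normalize_profile",
    "compare_regions",
]

MAIN_CHAIN_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class RegionDef:
    """A named residue interval (author numbering, inclusive)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"empty region {self.name}")

    def contains(self, resnum: int) -> bool:
        return self.start <= resnum <= self.end


#: Loop boundaries flanking the MIDAS face, estimated from the I-domain
#: secondary-structure annotation (author numbering); they are editable
#: defaults, and every report should restate the ranges actually used.
DEFAULT_LOOPS = {
    "a1I": [
        RegionDef("betaA-alpha1", 148, 158),
        RegionDef("betaB-betaC", 187, 196),
        RegionDef("alpha3-alpha4", 215, 225),
        RegionDef("alphaC-alpha6", 284, 294),
    ],
    "a2I": [
        RegionDef("betaA-alpha1", 149, 159),
        RegionDef("betaB-betaC", 188, 197),
        RegionDef("alpha3-alpha4", 216, 226),
        RegionDef("alphaC-alpha6", 285, 295),
    ],
}


@dataclass
class FlexibilityProfile:
    """Residue-averaged B-factors of one chain.

    ``entries`` columns: residue_number, b_main, b_side, b_all, n_atoms.
    ``b_all`` is the atom-count-weighted mean over all heavy atoms, so it
    equals ``(n_main*b_main + n_side*b_side) / n_atoms``.
    """

    structure_id: str
    chain: str
    entries: pd.DataFrame
    normalized: str = "none"  # "none" | "zscore"
    partition: str = "all"

    def __len__(self) -> int:
        return len(self.entries)

    def values(self, partition: str | None = None) -> pd.Series:
        col = {"main": "b_main", "side": "b_side", "all": "b_all"}[
            partition or self.partition
        ]
        return self.entries.set_index("residue_number")[col]


def bfactor_profile(
    s: Structure, chain: str, partition: str = "all"
) -> FlexibilityProfile:
    """Per-residue mean B-factors for one chain (waters/metals/H excluded).

    ``partition`` selects which column downstream operations read by
    default; all three (main, side, all) are always computed.  Main chain =
    N, CA, C, O (+OXT); side chain = remaining heavy atoms.
    """
    if partition not in ("main", "side", "all"):
        raise ValueError(f"unknown partition {partition!r}")
    rows: dict[int, dict[str, list[float]]] = {}
    for a in s.atoms:
        if a.chain_id != chain or a.record_kind != "atom":
            continue
        if a.is_hydrogen or a.is_water:
            continue
        bucket = rows.setdefault(a.residue_number, {"main": [], "side": []})
        bucket["main" if a.name in MAIN_CHAIN_NAMES else "side"].append(a.b_factor)
    if not rows:
        raise ValueError(f"no polymer atoms in chain {chain!r} of {s.id}")
    recs = []
    for num in sorted(rows):
        m, sd = rows[num]["main"], rows[num]["side"]
        allb = m + sd
        recs.append(
            {
                "residue_number": num,
                "b_main": float(np.mean(m)) if m else np.nan,
                "b_side": float(np.mean(sd)) if sd else np.nan,
                "b_all": float(np.mean(allb)),
                "n_atoms": len(allb),
            }
        )
    return FlexibilityProfile(
        structure_id=s.id,
        chain=chain,
        entries=pd.DataFrame(recs),
        partition=partition,
    )


def normalize_profile(
    p: FlexibilityProfile, method: str = "zscore"
) -> FlexibilityProfile:
    """Z-score the B columns over the profile (population sd).

    Idempotent up to numerical tolerance; raises on a flat profile.
    """
    if method != "zscore":
        raise ValueError(f"unknown normalization {method!r}")
    if len(p) < 2:
        raise ValueError("need at least 2 residues to normalize")
    df = p.entries.copy()
    for col in ("b_main", "b_side", "b_all"):
        v = df[col].to_numpy(dtype=float)
        mask = np.isfinite(v)
        sd = np.nanstd(v[mask]) if mask.any() else 0.0
        if col == "b_all" and sd == 0:
            raise ValueError("degenerate profile: zero B-factor spread")
        if sd > 0:
            df[col] = (v - np.nanmean(v[mask])) / sd
    return replace(p, entries=df, normalized=method)


def compare_regions(
    a: FlexibilityProfile,
    b: FlexibilityProfile,
    regions: list[tuple[RegionDef, RegionDef]],
    partition: str = "all",
) -> pd.DataFrame:
    """Region-mean normalized B of two profiles and their difference.

    ``regions`` pairs a region in profile ``a`` with its counterpart in
    ``b`` (residue numbering may differ between structures).  Positive
    ``delta`` means the region is more flexible in ``a``.  Both profiles
    must be normalized with the same method.
    """
    if a.normalized == "none" or a.normalized != b.normalized:
        raise ValueError("profiles must be normalized with the same method")
    va, vb = a.values(partition), b.values(partition)
    rows = []
    for ra, rb in regions:
        sel_a = va[(va.index >= ra.start) & (va.index <= ra.end)]
        sel_b = vb[(vb.index >= rb.start) & (vb.index <= rb.end)]
        if sel_a.empty or sel_b.empty:
            raise ValueError(f"region {ra.name} outside profile range")
        ma, mb = float(sel_a.mean()), float(sel_b.mean())
        rows.append(
            {
                "region": ra.name,
                "range_a": f"{ra.start}-{ra.end}",
                "range_b": f"{rb.start}-{rb.end}",
                "mean_zB_a": ma,
                "mean_zB_b": mb,
                "delta": ma - mb,
            }
        )
    return pd.DataFrame(rows)
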