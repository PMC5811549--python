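#!/usr/bin/env python
"""Recompute the comparative structural metrics from the deposited entries.

Fetches the four PDB entries (Ca2+-bound alpha1I/alpha2I and the Mg2+-bound
references) from RCSB, then recomputes with this package:

  * global heavy-atom RMSD, Ca- vs Mg-bound, per I domain (0.90 / 1.17 A)
  * MIDAS-residue heavy-atom RMSDs (0.24 / 0.35 A; alpha1I vs alpha2I 0.41 A)
  * metal displacement Ca vs Mg in alpha2I (1.4 A)
  * S153 OG - Ca distance in alpha2I (3.7 A) and S153 OG displacement (0.7 A)
  * mean alpha1I Ca-ligand bond distance (~2.4 A)
  * coordination shells (alpha1I: 3 residues + 4 waters, CN 7)

Network access is required (the entries are fetched on demand and cached
under scratch/pdb).  This script is deliberately separate from the unit
test suite, which runs fully offline on generated fixtures.

Usage:  python scripts/reproduce_deposited.py [--cache DIR] [--out report.json]
"""

from __future__ import annotations

import argparse
import json
import urllib.request
from pathlib import Path

import numpy as np

from midaskit import metalsite, superpose, structio

ENTRIES = {
    "5HGJ": "alpha1I + Ca2+",
    "1QCY": "alpha1I + Mg2+",
    "5HJ2": "alpha2I + Ca2+",
    "1AOX": "alpha2I + Mg2+",
}

# MIDAS residues, author numbering (alpha1I / alpha2I)
MIDAS_A1 = [150, 152, 154, 220, 253]
MIDAS_A2 = [151, 153, 155, 221, 254]
A2_CHAINS = ("A", "B", "C", "D")  # E, F excluded (disordered/partial metal)

REJECT = (2.0, 5)  # iterative outlier rejection: sigma, max cycles


def fetch(pdb_id: str, cache: Path) -> Path:
    cache.mkdir(parents=True, exist_ok=True)
    path = cache / f"{pdb_id.lower()}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        print(f"fetching {url}")
        urllib.request.urlretrieve(url, path)
    return path


def global_rmsd(sa, sb, chain_a="A", chain_b="A"):
    p = superpose.pair_atoms(sa, sb, atom_policy="all-heavy",
                             chain_a=chain_a, chain_b=chain_b)
    return superpose.superpose(p, reject=REJECT), p


def midas_fit(sa, sb, map_ab, chain_a, chain_b):
    p = superpose.pair_atoms(sa, sb, residue_map=map_ab, atom_policy="all-heavy",
                             chain_a=chain_a, chain_b=chain_b)
    return superpose.superpose(p)


def chain_metal(s, chain):
    for m in metalsite.find_metal_sites(s, {"Ca", "Mg"}):
        if m.chain_id == chain:
            return m
    return None


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cache", type=Path, default=Path("scratch/pdb"))
    ap.add_argument("--out", type=Path, default=Path("scratch/reproduction.json"))
    args = ap.parse_args()

    structs = {pid: structio.read_structure(fetch(pid, args.cache))
               for pid in ENTRIES}
    a1ca, a1mg = structs["5HGJ"], structs["1QCY"]
    a2ca, a2mg = structs["5HJ2"], structs["1AOX"]
    report: dict = {}

    # --- global RMSDs (chain A vs chain A) -------------------------------
    fit_a1, _ = global_rmsd(a1ca, a1mg)
    fit_a2, _ = global_rmsd(a2ca, a2mg)
    report["global_rmsd_a1_CaVsMg_A"] = round(fit_a1.rmsd, 3)
    report["global_rmsd_a2_CaVsMg_A"] = round(fit_a2.rmsd, 3)

    # --- MIDAS RMSDs ------------------------------------------------------
    m11 = {r: r for r in MIDAS_A1}
    m22 = {r: r for r in MIDAS_A2}
    m12 = dict(zip(MIDAS_A1, MIDAS_A2))
    report["midas_rmsd_a1_CaVsMg_A"] = round(
        midas_fit(a1ca, a1mg, m11, "A", "A").rmsd, 3)
    report["midas_rmsd_a2_CaVsMg_A"] = round(
        np.mean([midas_fit(a2ca, a2mg, m22, ch, "A").rmsd
                 for ch in A2_CHAINS]), 3)
    report["midas_rmsd_a1_vs_a2_Ca_A"] = round(
        midas_fit(a1ca, a2ca, m12, "A", "A").rmsd, 3)

    # --- metal displacement in alpha2I (chains A-D averaged) -------------
    moves, s153_og_metal, s153_disp = [], [], []
    mg_metal = chain_metal(a2mg, "A")
    for ch in A2_CHAINS:
        fit, _ = global_rmsd(a2ca, a2mg, chain_a=ch, chain_b="A")
        ca_metal = chain_metal(a2ca, ch)
        if ca_metal is None or mg_metal is None:
            continue
        # fit maps B (Mg structure) onto A (Ca structure)
        moves.append(superpose.metal_displacement(fit, ca_metal, mg_metal))
        og = next((a for a in a2ca.atoms if a.chain_id == ch
                   and a.residue_number == 153 and a.name == "OG"), None)
        if og is not None:
            s153_og_metal.append(float(np.linalg.norm(og.xyz - ca_metal.xyz)))
        try:
            s153_disp.append(superpose.displacement(fit, 153, "OG", chain="A"))
        except KeyError:
            pass
    report["metal_displacement_a2_CaVsMg_A"] = round(float(np.mean(moves)), 3)
    report["s153_og_to_ca_distance_A"] = round(float(np.mean(s153_og_metal)), 3)
    report["s153_og_displacement_A"] = round(float(np.mean(s153_disp)), 3)

    # --- alpha1I coordination shell and bond distances -------------------
    shells = []
    for ch in ("A", "B"):
        m = chain_metal(a1ca, ch)
        if m is None:
            continue
        site = metalsite.coordination_shell(a1ca, m)
        shells.append(site)
    cn = [s.coordination_number for s in shells]
    protein_direct = [s.n_protein_direct for s in shells]
    water_direct = [s.n_water_direct for s in shells]
    bond_d = [c.distance for s in shells for c in s.direct
              if c.residue_role == "protein"]
    report["a1_coordination_number"] = cn
    report["a1_protein_direct"] = protein_direct
    report["a1_water_direct"] = water_direct
    report["a1_mean_protein_bond_A"] = round(float(np.mean(bond_d)), 3)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=1))
    print(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
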