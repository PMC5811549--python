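# midaskit

Structural and thermodynamic analysis of divalent-metal binding at integrin
I-domain MIDAS sites.

Collagen-binding integrins α1β1 and α2β1 recognize their ligands through an
inserted (I) domain whose metal-ion-dependent adhesion site (MIDAS) chelates
a divalent cation (Mg²⁺ or Ca²⁺) via the conserved DxSxS…Thr…Asp motif.
Whether Ca²⁺ can substitute for Mg²⁺ differs between the two domains, and
the structural correlates are subtle: sub-ångström shifts of the ion and of
individual hydroxyl oxygens, a switch from direct to water-mediated
coordination, loop-flexibility differences read from crystallographic
B-factors, and a single non-conserved Glu–Arg salt bridge. `midaskit`
packages every quantitative step of that comparison — for structural
biologists who want to run the same analysis on their own coordinate files
or on synthetic controls.

## What it computes

- **`midaskit.structio`** — PDB/mmCIF reading and PDB writing (via gemmi),
  an atom-selection mini-language, and Matthews-coefficient arithmetic:
  `V_m = V_cell / (Z·n_AU·M)` and solvent fraction `1 − 1.23/V_m`.
- **`midaskit.superpose`** — Kabsch least-squares superposition with
  optional iterative outlier rejection; heavy-atom RMSD, per-residue
  displacements, and the displacement of a metal measured in the
  protein-frame fit (the metal never enters the fit).
- **`midaskit.metalsite`** — coordination shells: direct O/N donors within
  3.0 Å, water-mediated second-shell donors within 3.5 Å of a first-shell
  water; denticity; coordination-polyhedron classification (octahedral,
  pentagonal bipyramidal, cubic, …) by exhaustive vertex-permutation
  matching of ligand–metal–ligand angles; ionic-sphere areas
  `4π(r_ion + 1.4 Å)²`.
- **`midaskit.flexibility`** — residue-averaged B-factor profiles
  (main-chain / side-chain / all), per-chain z-score normalization, and
  loop-region comparisons between structures.
- **`midaskit.interactions`** — Asp/Glu–Arg/Lys/His salt-bridge detection
  (4.0 Å heavy-atom cutoff) and conservation of residue pairs across a
  multiple sequence alignment.
- **`midaskit.itc`** — one-site (Wiseman) titration isotherms with the
  perfusion-cell displaced-volume correction: simulation with seeded noise,
  least-squares fitting of (K, ΔH) with n fixed at 1, derived
  ΔG° = −RT ln K, ΔS° = (ΔH − ΔG°)/T, K_d = 1/K, and 1:1 buffer–metal
  competition (e.g. ACES, log K 3.38 for Ca²⁺ / 3.55 for Mg²⁺).
- **`midaskit.synthdata`** — deterministic synthetic fixtures with JSON
  ground truth: ideal coordination polyhedra with protein/water donor
  mixes, water bridges, B-factor patterns, salt bridges, rigidly displaced
  structure pairs, and alignments with pinned columns.
- **`midaskit.pipeline`** — one-shot comparison reports and X-ray
  fluorescence Kα1/Kβ1 peak assignment (elements Na–Zn).

## Worked example

Build a heptacoordinate Ca²⁺ site (three protein donors + four waters on a
pentagonal bipyramid, 2.4 Å bonds), then characterize it:

```sh
$ midaskit fixtures --geometry pentagonal_bipyramidal --metal Ca \
    --n-protein 3 --n-waters 4 --bond-length 2.4 --out site.pdb
$ midaskit coordination site.pdb
{
 "metal": "Ca M:501",
 "coordination_number": 7,
 "n_protein_direct": 3,
 "n_water_direct": 4,
 "geometry": ["pentagonal_bipyramidal", 0.0033]
}
```

The site is recovered exactly as generated: coordination number 7 with a
3 + 4 protein/water donor split, classified as pentagonal bipyramidal with
an angular RMSD of 0.003° (the residual comes from the 3-decimal coordinate
precision of the PDB format).

Simulate a low-c metal titration (100 µM cell, 20 mM syringe, 35 × 2 µL
injections, 20 °C) with 1 µcal noise and fit it back:

```sh
$ midaskit itc-sim --k 1e5 --dh -4.0 --noise-sd 1.0 --seed 7 --out t.tsv
$ midaskit itc-fit t.tsv --cell-conc 100e-6 --syringe-conc 20e-3
{
 "K_per_M": 96693.6,
 "dH_kcal_mol": -4.024,
 "n": 1.0,
 "Kd_M": 1.034e-05,
 "dG_kcal_mol": -6.687,
 "dS_cal_mol_K": 9.08,
 ...
}
```

The fit recovers the generating K = 1 × 10⁵ M⁻¹ within 3.5% and
ΔH = −4.0 kcal/mol within 0.6%; K_d lands in the micromolar range and the
derived ΔG°/ΔS° satisfy ΔG° = −RT ln K and ΔS° = (ΔH − ΔG°)/T exactly.

As a library:

```python
from midaskit import superpose, metalsite, structio
a = structio.read_structure("ca_bound.pdb")
b = structio.read_structure("mg_bound.pdb")
fit = superpose.superpose(superpose.pair_atoms(a, b), reject=(2.0, 5))
print(fit.rmsd)                       # heavy-atom RMSD, outliers rejected
ion = metalsite.find_metal_sites(a, {"Ca"})[0]
print(metalsite.coordination_shell(a, ion).to_records())
```

## Selection mini-language

`select_atoms(structure, query)` takes clauses joined by `and`:
`chain A`, `resi 150-154,220`, `resn ASP SER`, `name OG`, `element Ca`,
`record hetatm`, `altloc A`. Without an `altloc` clause, only the
highest-occupancy variant of each atom is kept (ties broken by altloc
letter).

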