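# Methods

This note records the models, conventions and numerical choices behind
`midaskit`, in the spirit of a package manual: what each analysis assumes,
which knobs matter, and what the synthetic fixtures do and do not emulate.

## Superposition and displacement metrics

Rigid-body fits use the Kabsch algorithm: SVD of the cross-covariance of
the centered paired coordinates, with the determinant-sign correction so the
returned rotation is always proper (no reflections). RMSD is reported over
the pairs used and satisfies `rmsd² = mean(per-pair displacement²)` by
construction.

Published structure comparisons rarely state their superposition protocol;
molecular-graphics "align" commands typically iterate outlier rejection.
We therefore expose both: a plain fit, and `reject=(sigma, max_cycles)`
which drops pairs whose residual displacement exceeds
`mean + sigma·sd` of the current displacement distribution, refits, and
repeats until convergence or `max_cycles` (defaults 2.0 and 5; at least
three pairs are always retained). Robust and plain RMSDs bracket most
protocol variants; reports should state which was used.

Atom pairing is by explicit residue map (used for MIDAS comparisons, where
author numbering differs by one between the two I domains:
150↔151, 152↔153, 154↔155, 220↔221, 253↔254) or by global sequence
alignment (BLOSUM62, affine gaps 10/0.5 through Biopython). Only
identically named atoms within paired residues are matched; "heavy atom"
means all non-hydrogen polymer atoms, waters and metals excluded.

Metal displacement is defined in the protein frame: the fit is computed on
protein atoms only, and the distance between metal A and the transformed
metal B reports how far the ion moved inside the site. The function
refuses metals that took part in the pairing. Multi-copy crystals are
summarized by the arithmetic mean of per-chain scalars; for the
six-copy α2I crystal form the default averaging set is chains A–D, with E
(incompletely hydrated metal) and F (metal and waters not locatable)
excluded and the exclusions logged in reports.

## Coordination shells

Direct contacts are O/N atoms (protein or water oxygen) within
`direct_cutoff` of the metal, default **3.0 Å**: crystallographic
metal–donor bonds cluster at 2.1–2.4 Å, while a hydroxyl at 3.7 Å is
unambiguously non-bonded, so 3.0 Å separates the two populations with
margin on both sides. Water-mediated contacts are protein O/N donors
within `water_hbond_cutoff` (default **3.5 Å**, a standard hydrogen-bond
ceiling) of a first-shell water; when several waters bridge the same donor
the shortest bridge is kept. The coordination number counts direct
contacts only; partial-occupancy waters are included. Sulfur is not
accepted as a donor by default (none occurs in these sites). Denticity
counts a residue's side-chain chelating oxygens among the direct shell:
0 → none, 1 → monodentate, 2 → bidentate.

Geometry classification compares the observed ligand–metal–ligand angle
matrix against ideal templates of the same coordination number
(tetrahedron; octahedron and trigonal prism; pentagonal bipyramid and
capped octahedron; square antiprism and cube), minimizing the RMS angle
difference over all vertex permutations. The search is exhaustive —
at most 8! = 40 320 permutations per template, evaluated vectorized — so
the reported label/angular-RMSD pair is a global optimum and is invariant
under ligand relabeling. Ionic radii default to the Shannon six-coordinate
values Mg²⁺ 0.65 Å and Ca²⁺ 0.99 Å; `sphere_area(r, 1.4)` uses the 1.4 Å
water-oxygen radius to express how much more first-shell surface the
larger ion must service (≈72 vs ≈53 Ų, a 26% difference), which is the
geometric root of Mg²⁺'s strict octahedral preference versus Ca²⁺'s
tolerance of coordination numbers 6–8.

## B-factor (flexibility) profiles

Per-residue means are computed over main-chain (N, CA, C, O, OXT),
side-chain (remaining heavy) and all heavy atoms; hydrogens, waters and
hetero atoms are excluded; means are unweighted by occupancy (configurable
in principle, silent in most deposition metadata). Because absolute B
scales differ between crystals (resolution, refinement restraints, Wilson
B), cross-structure comparison first z-scores each profile per chain;
region (loop) means of the normalized profiles are then compared directly,
with positive delta meaning "more flexible in A". Loop boundaries for the
two I domains ship as editable defaults estimated from the secondary-
structure annotation (e.g. βA–α1 ≈ 148–158/149–159, α3–α4 ≈ 215–225/
216–226); they are estimates, and every report restates the ranges used.

## Salt bridges and conservation

A salt bridge is any Asp/Glu carboxylate oxygen within **4.0 Å** (standard
convention) of an Arg/Lys/His charged nitrogen, intra-chain, reported once
per residue pair with the minimum atom–atom distance. Histidine counts as
basic by default because its protonation state is unknown at typical pH;
a flag excludes it. Conservation of a residue pair maps author residue
numbers through the gapped reference row of an alignment (FASTA or Clustal
via Biopython) to columns, then scores every other row for carrying the
required letters; the fraction is over non-reference rows. Externally
built alignments are accepted as-is; the bundled global aligner exists for
fixture construction, not to reproduce any particular alignment program.

## One-site ITC model

Cumulative heat follows the Wiseman isotherm for 1:1 binding,

    Q(i) = (n·Mt·ΔH·V0/2)·[θ − √(θ² − 4Xt/(n·Mt))],
    θ = 1 + Xt/(n·Mt) + 1/(n·K·Mt),

with the displaced-volume bookkeeping of a fixed-volume perfusion cell
(cumulative injected volume dV, f = dV/2V0): Mt = Mt⁰(1−f)/(1+f),
Xt = X_syr(dV/V0)/(1+f), and measured per-injection heat
q(i) = Q(i) − Q(i−1) + (v_i/V0)(Q(i)+Q(i−1))/2. Units are µcal for heats,
kcal/mol for ΔH/ΔG°, cal mol⁻¹ K⁻¹ for ΔS°, with R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹ and T defaulting to 293.15 K. Defaults mirror a VP-ITC
protocol on an I domain: 1.4 mL cell, 100 µM macromolecule, 20 mM titrant,
35 × 2 µL injections — the low-c regime (c = n·K·Mt ≈ 1 for K ≈ 10⁴ M⁻¹).

Fitting estimates (K, ΔH) by Levenberg–Marquardt least squares (lmfit)
with K parameterized as log₁₀K for conditioning; the stoichiometry is
fixed at n = 1 by default (one MIDAS per domain; fewer free parameters,
tighter uncertainties), optionally floated. ΔG°, ΔS° and K_d are derived
from the fitted parameters through the exact identities, and K's 1-σ
uncertainty is propagated from the log-scale standard error. A flag
excludes the first injection (the usual diffusion artifact remedy).
Buffer–metal competition is available as `free_metal` (1:1 complexation
quadratic, stable root) but is reported alongside rather than applied to
fits by default: matched buffers make raw constants directly comparable.

Parameter-recovery behavior, measured by seeded Monte-Carlo at fixed
absolute noise, is U-shaped in c with its optimum near c ≈ 1: below that
the isotherm flattens and K degrades (median |K̂/K−1| ≈ 0.08 at c = 0.1 vs
≈ 0.025 at c = 1 for 1 µcal noise), while far above it the curve
degenerates toward a step and K is again ill-constrained (≈ 0.07 at
c = 100). The test suite asserts the monotone improvement on the low-c
side, which is the regime these experiments occupy.

## Synthetic fixtures

The generator builds exactly what the analyses measure: donors on ideal
polyhedron vertices at a stated bond length (2.1 Å for Mg²⁺, 2.4 Å for
Ca²⁺ fixtures), a chosen protein/water donor mix (e.g. the 3 + 4 split of
a heptacoordinate site), second-shell donors placed 2.8 Å behind a
first-shell water, an Asp–Arg pair at a stated O–N distance, and a
poly-Ala scaffold carrying a per-region B-factor pattern. Ligand residues
use standard atom names with idealized local geometry; internal bond
angles beyond the coordination shell are cosmetic. Optional coordinate
jitter is isotropic Gaussian and, like every other stochastic element, is
deterministic under the spec's seed; each fixture carries a JSON
ground-truth sidecar.

What the fixtures do **not** emulate: real packing environments, altloc
disorder, anisotropic displacement, occupancy gradients, solvent networks
beyond the deliberate bridges, or realistic backbone stereochemistry.
Passing the property suite therefore demonstrates that the *measurements*
are correct on known ground truth — not that any particular biological
conclusion follows for a real crystal; for that, run the pipeline on
deposited coordinates (see `scripts/reproduce_deposited.py`).

## Numerical conventions and degenerate inputs

- Altlocs: highest occupancy wins, ties broken by altloc letter order,
  unless an altloc is named explicitly.
- Element assignment trusts the element column; bare metal HETATMs with a
  blank element fall back to residue name (CA → Ca, MG → Mg) — an atom
  *named* CA is never assumed to be calcium.
- Superposition refuses < 3 pairs and collinear point sets; geometry
  classification refuses coordination numbers outside 4–8; normalization
  refuses flat B profiles; the fit refuses all-zero thermograms and
  < 5 informative injections.
- The binding quadratic's discriminant is clipped at zero only within
  numerical round-off; a genuinely negative discriminant raises.
- Matthews solvent content uses the 1.23 ų/Da protein constant
  (0.74 cm³/g partial specific volume), configurable for sensitivity
  checks.
- Problem sizes in the test suite (100 random point sets, 100 seeded
  coordination fixtures, 30-replicate Monte-Carlo per c value, 35-injection
  thermograms) were chosen to make the property checks statistically
  meaningful while keeping the whole suite interactive-fast.

## Known limitations

- No symmetry expansion or biological-assembly generation: analyses see
  the asymmetric unit as deposited.
- The geometry classifier assumes a single best template; genuinely
  intermediate sites get the nearest label plus a large angular RMSD
  rather than an "intermediate" call.
- Water-mediated detection requires the bridging water to be modeled;
  unmodeled solvent silently lowers apparent coordination.
- The ITC module implements one-site binding only; multi-site or
  sequential schemes are out of scope, as is raw power-trace integration
  (heats arrive pre-integrated).
- Absolute fitted thermodynamic constants for the original titration
  experiments are not reproduced (the raw thermograms are not distributed);
  the module's guarantees are its internal identities and its
  parameter-recovery behavior on simulated data.
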