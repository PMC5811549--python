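"""Superposition: Kabsch vs an independent quaternion oracle, invariances."""

import numpy as np
import pytest

from midaskit import superpose as sp
from midaskit.synthdata import SiteSpec, make_displaced_pair, make_site_structure

from conftest import make_atom, random_coords, random_rigid_motion


def quaternion_rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    """Independent oracle: optimal-superposition RMSD via the quaternion
    characteristic matrix (Horn's method), no SVD involved."""
    a = xa - xa.mean(axis=0)
    b = xb - xb.mean(axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    ga = float(np.sum(a * a))
    gb = float(np.sum(b * b))
    msd = max((ga + gb - 2.0 * lam) / len(a), 0.0)
    return float(np.sqrt(msd))


def atoms_from_coords(coords, chain="A", kind="atom"):
    return [
        make_atom(serial=i + 1, name="CA", element="C", resname="GLY", resnum=i + 1,
                  chain=chain, pos=c, kind=kind)
        for i, c in enumerate(coords)
    ]


def pairing_from_coords(xa, xb):
    pa = atoms_from_coords(xa)
    pb = atoms_from_coords(xb)
    return sp.AtomPairing(pairs=list(zip(pa, pb)), method="identity", coverage=1.0)


class TestKabschCore:
    def test_rigid_copy_has_zero_rmsd(self):
        rng = np.random.default_rng(1)
        xa = random_coords(rng, 8)
        r, t = random_rigid_motion(rng)
        fit = sp.superpose(pairing_from_coords(xa, xa @ r.T + t))
        assert fit.rmsd < 1e-6
        assert np.allclose(fit.rotation @ fit.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_matches_quaternion_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(4, 11)
            xa = random_coords(rng, int(n))
            xb = random_coords(rng, int(n))
            fit = sp.superpose(pairing_from_coords(xa, xb))
            assert fit.rmsd == pytest.approx(quaternion_rmsd(xa, xb), abs=1e-9)

    def test_one_atom_offset_matches_oracle(self):
        rng = np.random.default_rng(3)
        xa = random_coords(rng, 4)
        xb = xa.copy()
        xb[2] += np.array([1.0, 0.0, 0.0])
        fit = sp.superpose(pairing_from_coords(xa, xb))
        assert fit.rmsd == pytest.approx(quaternion_rmsd(xa, xb), abs=1e-9)

    def test_rmsd_is_symmetric(self):
        rng = np.random.default_rng(11)
        xa = random_coords(rng, 9)
        xb = random_coords(rng, 9)
        f_ab = sp.superpose(pairing_from_coords(xa, xb))
        f_ba = sp.superpose(pairing_from_coords(xb, xa))
        assert f_ab.rmsd == pytest.approx(f_ba.rmsd, abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(13)
        xa = random_coords(rng, 10)
        xb = random_coords(rng, 10)
        base = sp.superpose(pairing_from_coords(xa, xb)).rmsd
        for _ in range(5):
            r, t = random_rigid_motion(rng)
            moved = sp.superpose(pairing_from_coords(xa, xb @ r.T + t)).rmsd
            assert moved == pytest.approx(base, abs=1e-8)

    def test_rmsd_equals_rms_of_per_pair_displacements(self):
        rng = np.random.default_rng(17)
        xa = random_coords(rng, 12)
        xb = random_coords(rng, 12)
        fit = sp.superpose(pairing_from_coords(xa, xb))
        assert fit.rmsd == pytest.approx(
            float(np.sqrt(np.mean(fit.per_pair_displacement**2))), abs=1e-12
        )

    def test_too_few_pairs_rejected(self):
        xa = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            sp.superpose(pairing_from_coords(xa, xa))

    def test_collinear_geometry_rejected(self):
        xa = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            sp.superpose(pairing_from_coords(xa, xa))


class TestOutlierRejection:
    def test_rejection_never_increases_rmsd(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            xa = random_coords(rng, 15)
            xb = xa + rng.normal(0, 0.1, xa.shape)
            xb[0] += 5.0  # one gross outlier
            p = pairing_from_coords(xa, xb)
            plain = sp.superpose(p)
            robust = sp.superpose(p, reject=(2.0, 5))
            assert robust.rmsd <= plain.rmsd + 1e-12

    def test_outlier_is_identified(self):
        rng = np.random.default_rng(23)
        xa = random_coords(rng, 15)
        xb = xa + rng.normal(0, 0.02, xa.shape)
        xb[4] += 4.0
        robust = sp.superpose(pairing_from_coords(xa, xb), reject=(2.0, 5))
        rejected_resnums = {p[0].residue_number for p in robust.rejected}
        assert 5 in rejected_resnums
        assert robust.n_pairs_used >= 3


class TestPairing:
    def test_identity_pairing_covers_all_heavy_atoms(self, twelve_atom_structure):
        p = sp.pair_atoms(twelve_atom_structure, twelve_atom_structure)
        assert len(p) == 12
        assert p.coverage == pytest.approx(1.0)

    def test_explicit_residue_map(self):
        spec = SiteSpec(geometry="octahedral", metal="Ca", n_protein_ligands=3,
                        n_waters=3)
        s, _ = make_site_structure(spec)
        p = sp.pair_atoms(s, s, residue_map={150: 150, 152: 152, 154: 154})
        resnums = {a.residue_number for a, _ in p.pairs}
        assert resnums == {150, 152, 154}

    def test_explicit_map_missing_residue_raises(self, twelve_atom_structure):
        with pytest.raises(KeyError):
            sp.pair_atoms(twelve_atom_structure, twelve_atom_structure,
                          residue_map={99: 99})

    def test_sequence_alignment_skips_insertion(self):
        """A two-residue insertion in B leaves a gap: A fully paired to the
        matching flanks, coverage of B < 1, mapping as enumerated."""
        names = ["GLY", "ALA", "SER", "THR", "TYR", "TRP", "LEU", "LYS"]
        coords = np.arange(len(names))[:, None] * [3.8, 0.0, 0.0]
        a_atoms = []
        for i, (nm, c) in enumerate(zip(names, coords)):
            a_atoms.append(make_atom(serial=i + 1, name="CA", element="C",
                                     resname=nm, resnum=i + 1, pos=c))
        ins = names[:4] + ["PRO", "PRO"] + names[4:]
        b_atoms = []
        for i, nm in enumerate(ins):
            b_atoms.append(make_atom(serial=i + 1, name="CA", element="C",
                                     resname=nm, resnum=i + 1,
                                     pos=(3.8 * i, 0.0, 0.0)))
        from midaskit.structio import Structure

        p = sp.pair_atoms(Structure(id="a", atoms=a_atoms),
                          Structure(id="b", atoms=b_atoms))
        mapping = {aa.residue_number: ab.residue_number for aa, ab in p.pairs}
        assert mapping == {1: 1, 2: 2, 3: 3, 4: 4, 5: 7, 6: 8, 7: 9, 8: 10}

    def test_backbone_policy_restricts_names(self, octahedral_mg_site):
        s, _ = octahedral_mg_site
        p = sp.pair_atoms(s, s, atom_policy="backbone")
        assert {a.name for a, _ in p.pairs} <= {"N", "CA", "C", "O"}


class TestDisplacements:
    def test_identical_structures_zero_everywhere(self, octahedral_mg_site):
        s, _ = octahedral_mg_site
        fit = sp.superpose(sp.pair_atoms(s, s))
        assert sp.displacement(fit, 150, "OG") == pytest.approx(0.0, abs=1e-9)

    def test_constructed_og_offset_recovered(self):
        spec = SiteSpec(geometry="octahedral", metal="Ca", n_protein_ligands=3,
                        n_waters=3, scaffold_length=60)
        a, b, meta = make_displaced_pair(spec, residue_offsets={(150, "OG"): 0.70})
        fit = sp.superpose(sp.pair_atoms(a, b))
        assert sp.displacement(fit, 150, "OG") == pytest.approx(0.70, abs=0.01)

    def test_metal_offset_recovered_and_metal_excluded_from_fit(self):
        spec = SiteSpec(geometry="pentagonal_bipyramidal", metal="Ca",
                        n_protein_ligands=3, n_waters=4, scaffold_length=60)
        a, b, meta = make_displaced_pair(spec, metal_offset=1.4)
        fit = sp.superpose(sp.pair_atoms(a, b))
        ma = next(x for x in a.atoms if x.element == "Ca")
        mb = next(x for x in b.atoms if x.element == "Ca")
        assert sp.metal_displacement(fit, ma, mb) == pytest.approx(1.4, abs=0.01)

    def test_same_structure_metal_displacement_zero(self, octahedral_mg_site):
        s, _ = octahedral_mg_site
        fit = sp.superpose(sp.pair_atoms(s, s))
        m = next(x for x in s.atoms if x.element == "Mg")
        assert sp.metal_displacement(fit, m, m) == pytest.approx(0.0, abs=1e-9)

    def test_polymer_atom_rejected_as_metal(self, octahedral_mg_site):
        s, _ = octahedral_mg_site
        fit = sp.superpose(sp.pair_atoms(s, s))
        protein_atom = next(x for x in s.atoms if x.record_kind == "atom")
        with pytest.raises(ValueError):
            sp.metal_displacement(fit, protein_atom, protein_atom)

    def test_unresolvable_selector(self, octahedral_mg_site):
        s, _ = octahedral_mg_site
        fit = sp.superpose(sp.pair_atoms(s, s))
        with pytest.raises(KeyError):
            sp.displacement(fit, 999, "OG")


class TestSerialization:
    def test_pairing_tsv_round_trip(self, octahedral_mg_site, tmp_path):
        s, _ = octahedral_mg_site
        p = sp.pair_atoms(s, s)
        path = tmp_path / "pairs.tsv"
        sp.pairing_to_tsv(p, path)
        back = sp.pairing_from_tsv(s, s, path)
        assert [(a.serial, b.serial) for a, b in back.pairs] == [
            (a.serial, b.serial) for a, b in p.pairs
        ]
        assert sp.superpose(back).rmsd == pytest.approx(sp.superpose(p).rmsd)

    def test_result_json_dict_consistent(self, octahedral_mg_site):
        s, _ = octahedral_mg_site
        fit = sp.superpose(sp.pair_atoms(s, s))
        d = sp.result_to_json_dict(fit)
        assert d["n_pairs_used"] == fit.n_pairs_used
        assert len(d["per_pair_displacement_A"]) == fit.n_pairs_used
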