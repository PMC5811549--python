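"""Coordination shells, denticity, geometry classification, sphere areas."""

import itertools
import math

import numpy as np
import pytest

from midaskit.metalsite import (
    IDEAL_GEOMETRIES,
    classify_geometry,
    coordination_shell,
    denticity,
    find_metal_sites,
    sphere_area,
)
from midaskit.structio import Structure
from midaskit.synthdata import SiteSpec, make_site_structure

from conftest import make_atom


def oracle_angular_rmsd(vecs, template):
    """Independent oracle: plain-Python exhaustive permutation search over
    ligand-metal-ligand angle differences."""

    def angles(vs):
        out = {}
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                vi = vs[i] / np.linalg.norm(vs[i])
                vj = vs[j] / np.linalg.norm(vs[j])
                out[(i, j)] = math.degrees(
                    math.acos(max(-1.0, min(1.0, float(np.dot(vi, vj)))))
                )
        return out

    obs = angles(vecs)
    tmpl = angles(template)
    best = math.inf
    n = len(vecs)
    for perm in itertools.permutations(range(n)):
        total = 0.0
        for (i, j), ang in obs.items():
            pi, pj = perm[i], perm[j]
            key = (pi, pj) if pi < pj else (pj, pi)
            total += (ang - tmpl[key]) ** 2
        rmsd = math.sqrt(total / len(obs))
        best = min(best, rmsd)
    return best


def perturbed_site(label, noise_deg, rng):
    """Ideal template vertices rotated by per-vertex angular noise."""
    base = IDEAL_GEOMETRIES[label]
    out = []
    for v in base:
        axis = rng.normal(size=3)
        axis -= axis.dot(v) * v / v.dot(v)
        axis /= np.linalg.norm(axis)
        ang = math.radians(rng.normal(0, noise_deg))
        vrot = (
            v * math.cos(ang)
            + np.cross(axis, v) * math.sin(ang)
            + axis * axis.dot(v) * (1 - math.cos(ang))
        )
        out.append(vrot * rng.uniform(2.0, 2.6))
    return np.array(out)


class TestFindMetals:
    def test_single_site_found(self, octahedral_mg_site):
        s, _ = octahedral_mg_site
        hits = find_metal_sites(s, {"Mg"})
        assert len(hits) == 1
        assert hits[0].element == "Mg"

    def test_metal_free_structure_empty(self, twelve_atom_structure):
        assert find_metal_sites(twelve_atom_structure, {"Ca", "Mg"}) == []

    def test_wrong_element_not_matched(self, octahedral_mg_site):
        s, _ = octahedral_mg_site
        assert find_metal_sites(s, {"Ca"}) == []


class TestCoordinationShell:
    def test_ideal_octahedron_cn6_no_mediation(self, octahedral_mg_site):
        s, meta = octahedral_mg_site
        m = find_metal_sites(s, {"Mg"})[0]
        site = coordination_shell(s, m)
        assert site.coordination_number == 6
        assert site.n_protein_direct == 3
        assert site.n_water_direct == 3
        assert site.water_mediated == []
        assert site.geometry[0] == "octahedral"
        assert site.geometry[1] == pytest.approx(0.0, abs=1e-6)

    def test_heptacoordinate_ca_with_bridges(self, heptacoordinate_ca_site):
        """Three protein + four water first-shell donors; two residues reach
        the metal only through a bridging water."""
        s, meta = heptacoordinate_ca_site
        m = find_metal_sites(s, {"Ca"})[0]
        site = coordination_shell(s, m)
        assert site.coordination_number == 7
        assert site.n_protein_direct == 3
        assert site.n_water_direct == 4
        mediated = {(c.atom.residue_name, c.atom.name) for c in site.water_mediated}
        assert mediated == {("ASP", "OD1"), ("THR", "OG1")}
        for c in site.water_mediated:
            assert c.bridging_water is not None
            assert c.bridging_water.is_water
        assert site.geometry[0] == "pentagonal_bipyramidal"

    def test_direct_and_mediated_sets_disjoint(self, heptacoordinate_ca_site):
        s, _ = heptacoordinate_ca_site
        m = find_metal_sites(s, {"Ca"})[0]
        site = coordination_shell(s, m)
        d = {(c.atom.residue_key, c.atom.name) for c in site.direct}
        w = {(c.atom.residue_key, c.atom.name) for c in site.water_mediated}
        assert d.isdisjoint(w)

    def test_cn_nondecreasing_in_cutoff(self, heptacoordinate_ca_site):
        s, _ = heptacoordinate_ca_site
        m = find_metal_sites(s, {"Ca"})[0]
        cns = [
            coordination_shell(s, m, direct_cutoff=c, classify=False).coordination_number
            for c in (2.0, 2.5, 3.0, 3.5, 4.0)
        ]
        assert cns == sorted(cns)

    def test_distant_hydroxyl_is_not_direct(self):
        """A Ser OG at 3.7 A is beyond any plausible direct bond."""
        spec = SiteSpec(geometry="octahedral", metal="Ca", n_protein_ligands=3,
                        n_waters=3)
        s, _ = make_site_structure(spec)
        m = find_metal_sites(s, {"Ca"})[0]
        moved = []
        for a in s.atoms:
            if a.residue_number == 150 and a.name == "OG":
                u = (a.xyz - m.xyz) / np.linalg.norm(a.xyz - m.xyz)
                moved.append(a.moved_to(m.xyz + 3.7 * u))
            else:
                moved.append(a)
        s2 = Structure(id="moved", atoms=moved)
        m2 = find_metal_sites(s2, {"Ca"})[0]
        site = coordination_shell(s2, m2, classify=False)
        direct_names = {(c.atom.residue_number, c.atom.name) for c in site.direct}
        assert (150, "OG") not in direct_names
        assert site.coordination_number == 5

    def test_metal_not_in_structure(self, octahedral_mg_site, twelve_atom_structure):
        s, _ = octahedral_mg_site
        m = find_metal_sites(s, {"Mg"})[0]
        with pytest.raises(LookupError):
            coordination_shell(twelve_atom_structure, m)


class TestDenticity:
    def _site_with_asp(self, d1, d2):
        atoms = [
            make_atom(serial=1, name="CA", element="Ca", resname="CA", resnum=501,
                      chain="M", pos=(0, 0, 0), kind="hetatm"),
            make_atom(serial=2, name="OD1", element="O", resname="ASP", resnum=10,
                      pos=(d1, 0, 0)),
            make_atom(serial=3, name="OD2", element="O", resname="ASP", resnum=10,
                      pos=(0, d2, 0)),
            make_atom(serial=4, name="CG", element="C", resname="ASP", resnum=10,
                      pos=(d1 + 1, d2 + 1, 0)),
        ]
        s = Structure(id="asp", atoms=atoms)
        m = find_metal_sites(s, {"Ca"})[0]
        return coordination_shell(s, m, classify=False)

    def test_monodentate(self):
        assert denticity(self._site_with_asp(2.3, 4.5), 10) == "monodentate"

    def test_bidentate(self):
        assert denticity(self._site_with_asp(2.4, 2.4), 10) == "bidentate"

    def test_noncoordinating_residue_is_none(self):
        assert denticity(self._site_with_asp(2.3, 4.5), 99) == "none"


class TestGeometryClassification:
    @pytest.mark.parametrize("label", sorted(IDEAL_GEOMETRIES))
    def test_ideal_templates_self_classify(self, label):
        vecs = IDEAL_GEOMETRIES[label] * 2.3
        got, rmsd = classify_geometry(vecs)
        assert got == label
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        vecs = perturbed_site("octahedral", 4.0, rng)
        base = classify_geometry(vecs)
        for _ in range(5):
            perm = rng.permutation(len(vecs))
            assert classify_geometry(vecs[perm]) == pytest.approx(base)

    def test_noisy_octahedron_matches_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            vecs = perturbed_site("octahedral", 5.0, rng)
            label, rmsd = classify_geometry(vecs)
            assert label == "octahedral"
            oracle = min(
                oracle_angular_rmsd(vecs, IDEAL_GEOMETRIES[l])
                for l in ("octahedral", "trigonal_prismatic")
            )
            assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_unsupported_cn(self):
        with pytest.raises(ValueError):
            classify_geometry(np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1]]))


class TestSphereArea:
    def test_mg_shell_area(self):
        """Mg2+ (0.65 A) + water oxygen (1.4 A): ~53 A^2 shell sphere."""
        assert sphere_area(0.65, 1.4) == pytest.approx(52.81, abs=0.01)
        assert round(sphere_area(0.65, 1.4)) == 53

    def test_ca_shell_area(self):
        """Ca2+ (0.99 A) + water oxygen (1.4 A): ~72 A^2 shell sphere."""
        assert sphere_area(0.99, 1.4) == pytest.approx(71.78, abs=0.01)
        assert round(sphere_area(0.99, 1.4)) == 72

    def test_ca_sphere_is_26_percent_larger(self):
        mg = sphere_area(0.65, 1.4)
        ca = sphere_area(0.99, 1.4)
        assert ca / mg == pytest.approx(1.36, abs=0.005)
        assert (ca - mg) / ca * 100 == pytest.approx(26, abs=0.5)

    def test_degenerate_and_invalid(self):
        assert sphere_area(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            sphere_area(-0.1, 1.4)


def test_site_tsv_export(tmp_path, heptacoordinate_ca_site):
    from midaskit.metalsite import site_to_tsv

    s, _ = heptacoordinate_ca_site
    m = find_metal_sites(s, {"Ca"})[0]
    site = coordination_shell(s, m)
    p = tmp_path / "site.tsv"
    site_to_tsv(site, p)
    lines = p.read_text().splitlines()
    assert lines[0].startswith("chain\tresidue")
    assert len(lines) == 1 + len(site.contacts)
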