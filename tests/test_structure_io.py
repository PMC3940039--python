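import math

import numpy as np
import pytest

from conformeq.errors import GeometryError, MappingError, ParseError, TopologyError
from conformeq.structure_io import (
    AtomRecord,
    ProbeSite,
    Structure,
    bond_vector_angle,
    build_methyl_protons,
    build_planar_proton,
    load_structure,
    methyl_probe_geometry,
    methyl_proton_names,
    place_atom,
    probe_from_structure,
)

from conftest import axial_probe, random_rotation
from oracles import dihedral_deg, staggered_phase_scan

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       3.000   3.400   3.250  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB AALA A   1       1.000   0.000   0.000  0.71  0.00           C
ATOM      3  CB BALA A   1       2.000   0.000   0.000  0.29  0.00           C
END
"""


class TestLoadStructure:
    def test_reads_back_coordinates(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        st = load_structure(path)
        assert len(st) == 3
        np.testing.assert_allclose(
            st.find("A", 1, "CB").pos, [3.0, 3.4, 3.25], atol=1e-3
        )

    def test_empty_file_is_a_parse_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises((ParseError, Exception)):
            load_structure(path)

    def test_missing_model_raises(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        with pytest.raises(IndexError):
            load_structure(path, model_index=3)

    def test_altloc_highest_occupancy_keeps_major_conformer(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        st = load_structure(path, altloc="highest-occupancy")
        assert len(st) == 2
        np.testing.assert_allclose(st.find("A", 1, "CB").pos, [1.0, 0.0, 0.0])

    def test_altloc_error_policy_refuses(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        with pytest.raises(ValueError, match="altloc"):
            load_structure(path, altloc="error")

    def test_write_read_round_trip(self, scene, tmp_path):
        path = tmp_path / "scene.pdb"
        scene.conformer_a.write_pdb(path)
        st = load_structure(path)
        orig = {(a.resnum, a.name): a.pos for a in scene.conformer_a.atoms}
        for a in st.atoms:
            np.testing.assert_allclose(a.pos, orig[(a.resnum, a.name)], atol=1e-3)


class TestMethylBuilding:
    def test_ideal_tetrahedral_geometry(self, valine_fragment):
        groups = build_methyl_protons(valine_fragment, "A:5:CG1")
        assert len(groups) == 1
        m = groups[0]
        ch = np.linalg.norm(m.protons - m.carbon, axis=1)
        np.testing.assert_allclose(ch, 1.09, atol=1e-6)
        hh = [np.linalg.norm(m.protons[i] - m.protons[j])
              for i, j in ((0, 1), (0, 2), (1, 2))]
        np.testing.assert_allclose(hh, 1.780, atol=1e-3)
        # all three H-C-antecedent angles identical
        u = m.protons - m.carbon
        v = m.antecedent - m.carbon
        cosang = (u @ v) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v))
        assert np.ptp(np.degrees(np.arccos(cosang))) < 1e-4

    def test_rotation_equivariance(self, valine_fragment):
        rng = np.random.default_rng(7)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        built = build_methyl_protons(valine_fragment, "A:5:CG1")[0]
        rotated = valine_fragment.transformed(R, t)
        built_rotated = build_methyl_protons(rotated, "A:5:CG1")[0]
        np.testing.assert_allclose(
            built_rotated.protons, built.protons @ R.T + t, atol=1e-9
        )

    def test_staggered_rotor_dihedrals(self, valine_fragment):
        m = build_methyl_protons(valine_fragment, "A:5:CG1")[0]
        ca = valine_fragment.find("A", 5, "CA").pos
        cg2 = valine_fragment.find("A", 5, "CG2").pos
        # exact against the phasing reference; the other substituent inherits
        # a ~0.002 deg offset from the 109.47 vs arccos(-1/3) convention
        for sub, tol in ((ca, 1e-3), (cg2, 1e-2)):
            for h in m.protons:
                d = dihedral_deg(h, m.carbon, m.antecedent, sub)
                nearest = min(abs(abs(d) - 60.0), abs(abs(d) - 180.0))
                assert nearest < tol

    def test_phase_matches_min_eclipse_oracle(self, valine_fragment):
        """The fixed stagger phase equals the brute-force anti-eclipse optimum."""
        cb = valine_fragment.find("A", 5, "CB").pos
        ca = valine_fragment.find("A", 5, "CA").pos
        cg1 = valine_fragment.find("A", 5, "CG1").pos
        cg2 = valine_fragment.find("A", 5, "CG2").pos

        def build(phase):
            return [place_atom(ca, cb, cg1, 1.09, 109.47, phase + k)
                    for k in (0.0, 120.0, 240.0)]

        # substituents of CB seen from CG1: CA and CG2 (120 deg apart)
        phase_opt = staggered_phase_scan(cg1, cb, ca, [ca, cg2], build, n_grid=7200)
        built = build_methyl_protons(valine_fragment, "A:5:CG1")[0]
        d_built = dihedral_deg(built.protons[0], cg1, cb, ca) % 120.0
        assert abs((phase_opt % 120.0) - d_built) < 0.1

    def test_explicit_protons_used_verbatim(self, valine_fragment):
        built = build_methyl_protons(valine_fragment, "A:5:CG1")[0]
        extra = [
            AtomRecord("A", 5, "VAL", name, pos)
            for name, pos in zip(methyl_proton_names("CG1"), built.protons)
        ]
        augmented = valine_fragment.with_atoms(extra)
        reread = build_methyl_protons(augmented, "A:5:CG1", use_explicit=True)[0]
        assert reread.provenance == "read-from-file"
        np.testing.assert_allclose(reread.protons, built.protons, atol=1e-9)

    def test_missing_antecedent_is_topology_error(self):
        st = Structure("broken", [AtomRecord("A", 5, "VAL", "CG1", np.zeros(3))])
        with pytest.raises(TopologyError, match="antecedent"):
            build_methyl_protons(st, "A:5:CG1")


class TestProbeGeometry:
    def test_axial_probe_symmetry(self, ideal_methyl):
        g = methyl_probe_geometry(ideal_methyl, axial_probe(5.0))
        assert np.ptp(g.distances) < 1e-9
        off_diag = g.angles[~np.eye(3, dtype=bool)]
        assert np.ptp(off_diag) < 1e-9
        np.testing.assert_allclose(g.angles, g.angles.T)
        np.testing.assert_allclose(np.diag(g.angles), 0.0)

    def test_right_angle_construction(self):
        from conformeq.structure_io import MethylGroup

        protons = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        m = MethylGroup(("A", 1, "VAL"), "CG1", np.zeros(3), np.array([0, 0, -1.0]),
                        protons)
        probe = ProbeSite(("A", 2, "TRP"), "HE1", np.zeros(3), np.array([0, 0, -0.98]))
        g = methyl_probe_geometry(m, probe)
        np.testing.assert_allclose(g.angles[0, 1], 90.0, atol=1e-9)

    def test_angles_match_dot_product_oracle(self, scene):
        probe = scene.probe_a
        for m in build_methyl_protons(scene.conformer_a):
            g = methyl_probe_geometry(m, probe)
            for i in range(3):
                for j in range(3):
                    vi = m.protons[i] - probe.pos
                    vj = m.protons[j] - probe.pos
                    expect = math.degrees(
                        math.acos(
                            np.clip(vi @ vj / (np.linalg.norm(vi) * np.linalg.norm(vj)),
                                    -1, 1)
                        )
                    )
                    if i == j:
                        expect = 0.0
                    assert abs(g.angles[i, j] - expect) < 1e-9

    def test_coincident_probe_raises(self, ideal_methyl):
        p = ProbeSite(("A", 2, "TRP"), "HE1", ideal_methyl.protons[0],
                      ideal_methyl.protons[0] + np.array([0, 0, 1.0]))
        with pytest.raises(GeometryError):
            methyl_probe_geometry(ideal_methyl, p)

    def test_rigid_body_invariance(self, valine_fragment):
        """Distances and angle matrices are invariant to global motion."""
        rng = np.random.default_rng(11)
        m0 = build_methyl_protons(valine_fragment, "A:5:CG1")[0]
        probe_pos = np.array([3.0, 1.0, 4.0])
        p0 = ProbeSite(("A", 9, "TRP"), "HE1", probe_pos, probe_pos + [0, 0, 0.98])
        g0 = methyl_probe_geometry(m0, p0)
        for _ in range(25):
            R = random_rotation(rng)
            t = rng.uniform(-50, 50, 3)
            moved = valine_fragment.transformed(R, t)
            m1 = build_methyl_protons(moved, "A:5:CG1")[0]
            p1 = ProbeSite(("A", 9, "TRP"), "HE1", R @ probe_pos + t,
                           R @ (probe_pos + np.array([0, 0, 0.98])) + t)
            g1 = methyl_probe_geometry(m1, p1)
            np.testing.assert_allclose(g1.distances, g0.distances, atol=1e-9)
            np.testing.assert_allclose(g1.angles, g0.angles, atol=1e-9)


class TestBondVectorAngle:
    @staticmethod
    def _site(pos, heavy):
        return ProbeSite(("A", 1, "TRP"), "HE1", np.asarray(pos, float),
                         np.asarray(heavy, float))

    def test_identical_structures_give_zero(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        s = self._site([0, 0, 0.98], [0, 0, 0])
        assert bond_vector_angle(s, s, ref, ref) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_right_angle(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        a = self._site([0, 0, 0.98], [0, 0, 0])
        b = self._site([0.98, 0, 0], [0, 0, 0])
        assert bond_vector_angle(a, b, ref, ref) == pytest.approx(90.0, abs=1e-9)

    def test_unequal_reference_sets_raise(self):
        s = self._site([0, 0, 0.98], [0, 0, 0])
        with pytest.raises(MappingError):
            bond_vector_angle(s, s, np.zeros((3, 3)), np.zeros((4, 3)))

    def test_superposition_removes_global_rotation(self, scene):
        """A globally rotated copy of conformer B yields the same flip angle."""
        rng = np.random.default_rng(3)
        R = random_rotation(rng)
        t = np.array([5.0, -3.0, 8.0])
        ra, rb = scene.reference_coords()
        moved = scene.conformer_b.transformed(R, t)
        pb = probe_from_structure(moved, "A:1:HE1", "A:1:NE1")
        rb_moved = rb @ R.T + t
        ang_moved = bond_vector_angle(scene.probe_a, pb, ra, rb_moved)
        ang = bond_vector_angle(scene.probe_a, scene.probe_b, ra, rb)
        assert ang_moved == pytest.approx(ang, abs=1e-6)


def test_planar_proton_lies_on_exterior_bisector():
    heavy = np.array([0.0, 0.0, 0.0])
    n1 = np.array([1.23, 0.0, -0.55])
    n2 = np.array([-1.23, 0.0, -0.55])
    h = build_planar_proton(heavy, n1, n2, length=0.98)
    assert np.linalg.norm(h - heavy) == pytest.approx(0.98, abs=1e-9)
    assert h[0] == pytest.approx(0.0, abs=1e-9)
    assert h[2] > 0  # opposite side from the neighbors


def test_probe_bond_length_validated():
    with pytest.raises(ValueError, match="bond length"):
        ProbeSite(("A", 1, "TRP"), "HE1", np.array([0, 0, 2.0]), np.zeros(3))
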