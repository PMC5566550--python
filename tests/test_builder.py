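"""Structure building: Z-matrix placement, the idealised mannopyranose
template, dimethyl phosphate and disaccharide assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from phoslink import geometry as geom
from phoslink.builder import (
    BOND_LENGTHS,
    InternalCoordinateTemplate,
    Structure,
    TorsionDefinition,
    ZMatrixEntry,
    build_dimethyl_phosphate,
    build_disaccharide,
    build_mannose,
    dimethyl_phosphate_template,
    disaccharide_torsion_definitions,
    place_atoms,
)
from phoslink.rotamers import ConformerSpec, LinkerConformer, RotamerState as R

GP, GM, T = R.GAUCHE_PLUS, R.GAUCHE_MINUS, R.TRANS

angles_st = st.floats(-179.9, 180.0)


def spec_for(linkage, z1=GP, z2=GP, rot=60.0, anomeric=60.0):
    return ConformerSpec(linkage, LinkerConformer(z1, z2), rot, anomeric_torsion=anomeric)


class TestPlaceAtoms:
    @given(z1=angles_st, z2=angles_st)
    @settings(max_examples=60, deadline=None)
    def test_dimethyl_phosphate_torsion_round_trip(self, z1, z2):
        s = build_dimethyl_phosphate(z1, z2)
        t = dimethyl_phosphate_template()
        m1 = s.measure_torsion(t.torsion_definitions["zeta1"])
        m2 = s.measure_torsion(t.torsion_definitions["zeta2"])
        assert abs(geom.normalize_angle(m1 - z1)) < 1e-4
        assert abs(geom.normalize_angle(m2 - z2)) < 1e-4

    def test_four_atom_chain_anti_is_coplanar(self):
        tmpl = InternalCoordinateTemplate(
            (
                ZMatrixEntry("A", "C", "methyl"),
                ZMatrixEntry("B", "C", "methyl", ("A",), 1.5),
                ZMatrixEntry("C", "C", "methyl", ("B", "A"), 1.5, 109.5),
                ZMatrixEntry("D", "C", "methyl", ("C", "B", "A"), 1.5, 109.5, 180.0),
            ),
            (),
        )
        s = place_atoms(tmpl)
        assert abs(s.coords[3][2]) < 1e-12  # coplanar with the anchor plane
        assert s.measure_torsion(("A", "B", "C", "D")) == pytest.approx(180.0)

    def test_template_bond_lengths_reproduced_exactly(self):
        s = build_dimethyl_phosphate(74.0, -131.0)
        assert s.measure_distance("OA", "P") == pytest.approx(BOND_LENGTHS["PO_ester"], abs=1e-9)
        assert s.measure_distance("P", "OP1") == pytest.approx(BOND_LENGTHS["PO_anionic"], abs=1e-9)
        assert s.measure_distance("CB", "OB") == pytest.approx(BOND_LENGTHS["CO"], abs=1e-9)

    def test_missing_free_torsion_is_an_error(self):
        with pytest.raises(ValueError, match="missing free torsions"):
            place_atoms(dimethyl_phosphate_template(), {"zeta1": 60.0})

    def test_template_referencing_unplaced_atom_is_an_error(self):
        with pytest.raises(ValueError, match="unplaced"):
            InternalCoordinateTemplate(
                (
                    ZMatrixEntry("A", "C", "methyl"),
                    ZMatrixEntry("B", "C", "methyl", ("Z",), 1.5),
                ),
                (),
            )


class TestMannose:
    def test_ring_closes_within_tolerance(self):
        m = build_mannose()
        closure = m.measure_distance("C1", "O5")
        assert abs(closure - BOND_LENGTHS["CO"]) / BOND_LENGTHS["CO"] < 0.10

    def test_h1_h2_distance_near_gauche_reference(self):
        # closed-form oracle: gauche H-C-C-H distance from ideal geometry
        lcc, lch, theta = 1.52, 1.09, math.radians(109.47122)
        tau = 60.0
        h1 = np.array([lch * math.cos(theta), lch * math.sin(theta), 0.0])
        h2_perp = lch * math.sin(theta)
        h2 = np.array(
            [
                lcc - lch * math.cos(theta),
                h2_perp * math.cos(math.radians(tau)),
                h2_perp * math.sin(math.radians(tau)),
            ]
        )
        oracle = float(np.linalg.norm(h1 - h2))
        m = build_mannose()
        d = m.measure_distance("H1", "H2")
        # ring torsion deviates from +/-60, so allow a modest band
        assert d == pytest.approx(oracle, abs=0.15)
        assert 2.4 <= d <= 2.8

    def test_h1_h2_matches_embedded_conformer_oracle(self):
        """Independent geometry oracle: an ETKDG/MMFF conformer of methyl
        alpha-D-mannopyranoside gives the same intra-residue H1-H2
        distance to within a tenth of an angstrom."""
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import AllChem

        smi = "CO[C@H]1O[C@H](CO)[C@@H](O)[C@H](O)[C@@H]1O"
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        params = AllChem.ETKDGv3()
        params.randomSeed = 7
        AllChem.EmbedMolecule(mol, params)
        AllChem.MMFFOptimizeMolecule(mol)
        pos = mol.GetConformer().GetPositions()
        h_on = lambda ci: [n.GetIdx() for n in mol.GetAtomWithIdx(ci).GetNeighbors() if n.GetSymbol() == "H"][0]
        d_ref = float(np.linalg.norm(pos[h_on(2)] - pos[h_on(11)]))  # C1, C2
        d = build_mannose().measure_distance("H1", "H2")
        assert d == pytest.approx(d_ref, abs=0.15)

    def test_primed_names_and_residue_assignment(self):
        m = build_mannose(primed=True)
        assert "C1'" in m.names and "H6a'" in m.names
        assert set(m.residues) == {"Man_nonred"}

    def test_methyl_aglycon(self):
        m = build_mannose(aglycon="OMe")
        assert {"CM", "HM1", "HM2", "HM3"} <= set(m.names)
        with pytest.raises(ValueError):
            build_mannose(aglycon="OEt")

    def test_all_bond_lengths_within_20_percent_of_templates(self):
        m = build_mannose(aglycon="OMe")
        ref = {
            ("C", "C"): BOND_LENGTHS["CC"],
            ("C", "O"): BOND_LENGTHS["CO"],
            ("C", "H"): BOND_LENGTHS["CH"],
            ("H", "O"): BOND_LENGTHS["OH"],
        }
        for a, b in m.bonds:
            key = tuple(sorted((m.elements[a], m.elements[b])))
            d = geom.distance(m.coords[a], m.coords[b])
            assert abs(d - ref[key]) / ref[key] < 0.20


class TestDisaccharide:
    @pytest.mark.parametrize("linkage", ["1->3", "1->4", "1->6"])
    @pytest.mark.parametrize(
        "z1,z2,rot,anomeric",
        [(GP, GP, 60.0, 60.0), (GM, T, 180.0, 60.0), (T, T, -60.0, -74.0)],
    )
    def test_set_torsions_round_trip(self, linkage, z1, z2, rot, anomeric):
        s = build_disaccharide(spec_for(linkage, z1, z2, rot, anomeric))
        defs = disaccharide_torsion_definitions(linkage)
        expected = {
            "anomeric": anomeric,
            "zeta1": z1.center_angle,
            "zeta2": z2.center_angle,
            "reducing_end": rot,
        }
        for label, want in expected.items():
            got = s.measure_torsion(defs[label])
            assert abs(geom.normalize_angle(got - want)) < 1e-4, label

    def test_one_six_omega_round_trip_and_extra_torsion(self):
        s = build_disaccharide(spec_for("1->6"), omega=74.0)
        defs = disaccharide_torsion_definitions("1->6")
        assert abs(geom.normalize_angle(s.measure_torsion(defs["omega"]) - 74.0)) < 1e-4
        # the P-O6-C6-C5 torsion of the flexible arm is measurable
        assert np.isfinite(s.measure_torsion(("P", "O6", "C6", "C5")))

    @pytest.mark.parametrize("linkage", ["1->3", "1->4", "1->6"])
    def test_single_phosphorus_bonded_to_four_oxygens(self, linkage):
        s = build_disaccharide(spec_for(linkage))
        assert s.elements.count("P") == 1
        nbrs = s.bonded_neighbors("P")
        assert len(nbrs) == 4
        assert all(s.elements[s.index(n)] == "O" for n in nbrs)

    @pytest.mark.parametrize("linkage", ["1->3", "1->4", "1->6"])
    def test_reference_h1p_h2p_distance(self, linkage):
        s = build_disaccharide(spec_for(linkage))
        assert s.measure_distance("H1'", "H2'") == pytest.approx(2.6, abs=0.2)

    def test_bridging_oxygen_matches_linkage(self):
        for linkage, ox in [("1->3", "O3"), ("1->4", "O4"), ("1->6", "O6")]:
            s = build_disaccharide(spec_for(linkage))
            assert ox in s.bonded_neighbors("P")
            # the bridging hydroxyl proton is gone
            assert f"HO{ox[-1]}" not in s.names

    def test_rigid_motion_leaves_measurements_unchanged(self, rng):
        s = build_disaccharide(spec_for("1->3"))
        Rm = Rotation.random(rng=rng).as_matrix()
        moved = s.transformed(rotation=Rm, translation=rng.normal(size=3) * 7)
        defs = disaccharide_torsion_definitions("1->3")
        for d in defs.values():
            assert abs(
                geom.normalize_angle(moved.measure_torsion(d) - s.measure_torsion(d))
            ) < 1e-6
        assert moved.measure_distance("H1'", "H3") == pytest.approx(
            s.measure_distance("H1'", "H3"), abs=1e-9
        )

    def test_requires_conformer_spec(self):
        with pytest.raises(TypeError):
            build_disaccharide("1->3")


class TestStructure:
    def test_measure_distance_examples(self):
        s = Structure(["A", "B"], ["C", "C"], ["methyl"] * 2, [[0, 0, 0], [3, 4, 0]], [(0, 1)])
        assert s.measure_distance("A", "B") == pytest.approx(5.0)
        assert s.measure_distance("A", "A") == 0.0
        assert s.measure_distance("B", "A") == s.measure_distance("A", "B")

    def test_missing_atom_is_an_error(self):
        s = Structure(["A"], ["C"], ["methyl"], [[0, 0, 0]], [])
        with pytest.raises(KeyError, match="no atom named"):
            s.position("Q")

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Structure(["A", "A"], ["C", "C"], ["methyl"] * 2, np.zeros((2, 3)), [])

    def test_drop_reindexes_bonds(self):
        s = build_mannose()
        smaller = s.drop(["HO2"])
        for a, b in smaller.bonds:
            assert geom.distance(smaller.coords[a], smaller.coords[b]) < 2.0

    def test_torsion_definition_requires_distinct_atoms(self):
        with pytest.raises(ValueError):
            TorsionDefinition(("A", "B", "A", "C"))
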