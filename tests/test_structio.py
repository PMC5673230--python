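"""Structure I/O, chirality assignment, mirroring and interface detection."""

import numpy as np
import pytest

from mirrorbind import structio
from mirrorbind.structio import (
    Atom,
    InterfaceSet,
    PDBParseError,
    Residue,
    Structure,
    StructureError,
    assign_chirality,
    find_interface,
    mirror,
    prepare_complex,
    read_structure,
    write_structure,
)

PDB_TWO_ATOM = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
END
"""

PDB_WITH_WATER = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
HETATM    2  O   HOH W   1       8.000   8.000   8.000  1.00  0.00           O
HETATM    3 NA    NA I   1       9.000   1.000   1.000  1.00  0.00          NA
END
"""


def _bead(chain, resseq, xyz, name="CA", name3="ALA", element="C"):
    return Residue(chain_id=chain, resseq=resseq, name3=name3,
                   atoms=[Atom(serial=1, name=name, element=element,
                               coords=np.array(xyz, float))])


class TestReadWrite:
    def test_two_atom_fixture(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(PDB_TWO_ATOM)
        s = read_structure(p)
        assert s.n_models == 1
        assert len(s.chain_ids(0)) == 1
        assert len(s.residues(0)) == 1
        assert len(s.residues(0)[0].atoms) == 2

    def test_roundtrip_preserves_coordinates(self, tmp_path, planted_toy):
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        write_structure(planted_toy, p1)
        s1 = read_structure(p1)
        write_structure(s1, p2)
        s2 = read_structure(p2)
        for r1, r2 in zip(s1.residues(0), s2.residues(0)):
            assert (r1.chain_id, r1.resseq, r1.name3) == (r2.chain_id, r2.resseq, r2.name3)
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert a1.name == a2.name
                np.testing.assert_allclose(a1.coords, a2.coords, atol=5e-4)

    def test_water_and_ion_classification(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(PDB_WITH_WATER)
        s = read_structure(p)
        classes = {r.name3: r.atoms[0].record_class for r in s.residues(0)}
        assert classes["HOH"] == "solvent"
        assert classes["NA"] == "ion"
        assert classes["ALA"] == "polymer"

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000\n"
            "ATOM      2  CB  ALA A   1       XXXXX   2.000   3.000\n"
        )
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(PDBParseError):
            read_structure(p)


class TestPrepareComplex:
    def _fixture(self):
        lig1 = [_bead("L", i, [float(i), 0, 0], name3="DPP") for i in range(1, 3)]
        lig2 = [_bead("M", i, [float(i), 5, 0], name3="DPP") for i in range(1, 3)]
        target = [_bead("A", i, [float(i), 10, 0]) for i in range(1, 4)]
        waters = [
            Residue(chain_id="W", resseq=i, name3="HOH",
                    atoms=[Atom(serial=1, name="O", element="O",
                                coords=np.array([i, 20.0, 0]),
                                record_class="solvent")])
            for i in range(1, 6)
        ]
        return Structure(models=[target + lig1 + lig2 + waters])

    def test_dedup_and_solvent_removal(self):
        s = self._fixture()
        out = prepare_complex(s, keep_chains={"A", "L", "M"}, drop_duplicate_ligand=True)
        chains = out.chains(0)
        assert set(chains) == {"A", "L"}
        assert all(r.name3 != "HOH" for r in out.residues(0))
        assert len(out.metadata["preparation_log"]) >= 6  # 5 waters + 1 chain

    def test_identity_when_nothing_to_remove(self):
        target = [_bead("A", i, [float(i), 0, 0]) for i in range(1, 4)]
        s = Structure(models=[target])
        out = prepare_complex(s, keep_chains={"A"})
        assert [r.resseq for r in out.residues(0)] == [1, 2, 3]

    def test_absent_chain_errors(self):
        s = self._fixture()
        with pytest.raises(StructureError, match="absent"):
            prepare_complex(s, keep_chains={"Z"})


class TestChirality:
    def test_ideal_l_alanine(self, ideal_ala_residue, dihedral_oracle):
        r = ideal_ala_residue
        ang = dihedral_oracle(
            r.atom("N").coords, r.atom("CA").coords,
            r.atom("C").coords, r.atom("CB").coords,
        )
        assert -125 < ang < -115  # about -120 degrees for ideal geometry
        assert assign_chirality(r) == "L"

    def test_z_negation_flips_to_d(self, ideal_ala_residue):
        import copy

        r = copy.deepcopy(ideal_ala_residue)
        for a in r.atoms:
            a.coords = a.coords * np.array([1, 1, -1.0])
        assert assign_chirality(r) == "D"

    def test_glycine_achiral(self):
        gly = Residue(chain_id="A", resseq=1, name3="GLY", atoms=[
            Atom(serial=1, name="N", element="N", coords=[0, 0, 0]),
            Atom(serial=2, name="CA", element="C", coords=[1.5, 0, 0]),
            Atom(serial=3, name="C", element="C", coords=[2.0, 1.4, 0]),
        ])
        assert assign_chirality(gly) == "achiral"

    def test_missing_backbone_unknown(self):
        r = Residue(chain_id="A", resseq=1, name3="ALA", atoms=[
            Atom(serial=1, name="CA", element="C", coords=[0, 0, 0]),
            Atom(serial=2, name="CB", element="C", coords=[1.5, 0, 0]),
        ])
        assert assign_chirality(r) == "unknown"


class TestMirror:
    def test_involution_bit_identical(self, planted_toy):
        back = mirror(mirror(planted_toy))
        for r1, r2 in zip(planted_toy.residues(0), back.residues(0)):
            assert r1.chirality == r2.chirality
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.array_equal(a1.coords, a2.coords)

    def test_l_alanine_becomes_d(self, ideal_ala_residue, dihedral_oracle):
        s = Structure(models=[[ideal_ala_residue]])
        s.models[0][0].chirality = assign_chirality(ideal_ala_residue)
        m = mirror(s)
        r = m.residues(0)[0]
        assert r.chirality == "D"
        # recompute the improper on the reflected coordinates independently
        ang = dihedral_oracle(
            r.atom("N").coords, r.atom("CA").coords,
            r.atom("C").coords, r.atom("CB").coords,
        )
        assert ang > 0
        assert assign_chirality(r) == "D"

    def test_glycine_stays_achiral(self):
        gly = Residue(chain_id="A", resseq=1, name3="GLY", chirality="achiral", atoms=[
            Atom(serial=1, name="CA", element="C", coords=[0, 0, 1.0]),
        ])
        s = Structure(models=[[gly]])
        assert mirror(s).residues(0)[0].chirality == "achiral"


class TestFindInterface:
    def test_distant_chains_empty(self):
        a = [_bead("A", 1, [0, 0, 0])]
        b = [_bead("B", 1, [10.0, 0, 0])]
        s = Structure(models=[a + b])
        assert len(find_interface([s], "B", {"A"}, 5.0)) == 0

    def test_single_contact_distance(self):
        # brute-force oracle: one CB exactly 4.2 A from the target bead
        res = Residue(chain_id="B", resseq=7, name3="ALA", atoms=[
            Atom(serial=1, name="CA", element="C", coords=[0, 0, 6.0]),
            Atom(serial=2, name="CB", element="C", coords=[0, 0, 4.2]),
        ])
        far = _bead("B", 8, [30.0, 0, 6.0])
        tgt = _bead("A", 1, [0, 0, 0])
        s = Structure(models=[[tgt, res, far]])
        iset = find_interface([s], "B", {"A"}, 5.0)
        assert iset.positions == [("B", 7)]
        assert iset.entries[0][2] == pytest.approx(4.2, abs=1e-12)

    def test_zero_cutoff_empty(self, planted_toy):
        assert len(find_interface([planted_toy], "B", {"A"}, 0.0)) == 0

    def test_union_over_ensemble_members(self):
        tgt = _bead("A", 1, [0, 0, 0])
        near = Structure(models=[[tgt, _bead("B", 1, [0, 0, 4.0])]])
        far = Structure(models=[[tgt, _bead("B", 1, [0, 0, 9.0])]])
        members = [near, far]
        union = find_interface(members, "B", {"A"}, 5.0)
        per_member = set()
        for m in members:
            per_member |= set(find_interface([m], "B", {"A"}, 5.0).positions)
        assert set(union.positions) == per_member
        assert union.entries[0][2] == pytest.approx(4.0)

    def test_empty_ensemble_errors(self):
        with pytest.raises(StructureError):
            find_interface([], "B", {"A"})

    def test_duplicate_entries_rejected(self):
        with pytest.raises(StructureError):
            InterfaceSet(entries=[("B", 1, 3.0), ("B", 1, 2.0)], cutoff=5.0)
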