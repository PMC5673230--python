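"""Side-chain construction, rotamer expansion, repacking and scanning."""

import itertools

import numpy as np
import pytest

from mirrorbind import ffmodel, mutscan, structio, toyfactory
from mirrorbind.mutscan import (
    MutscanError,
    ResidueLibrary,
    Rotamer,
    build_sidechain,
    expand_rotamers,
    make_logo,
    mutate_residue,
    repack,
    scan,
)
from mirrorbind.structio import assign_chirality, find_interface


class TestBuildSidechain:
    def test_rebuild_native_sidechain_is_exact(self, lib):
        bb = toyfactory.ideal_backbone(1, "B", 0.0, 6.0)
        built = build_sidechain(bb, lib.template("SER"), [180.0], chirality="D")
        rebuilt = build_sidechain(built, lib.template("SER"), [180.0], chirality="D")
        for a, b in zip(built.atoms, rebuilt.atoms):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-10)

    def test_chi1_rotation_moves_only_distal_atoms(self, lib):
        bb = toyfactory.ideal_backbone(1, "B", 0.0, 6.0)
        a = build_sidechain(bb, lib.template("HSE"), [60.0, 180.0], chirality="D")
        b = build_sidechain(bb, lib.template("HSE"), [180.0, 180.0], chirality="D")
        np.testing.assert_allclose(a.atom("CB").coords, b.atom("CB").coords, atol=1e-10)
        assert np.linalg.norm(a.atom("CG").coords - b.atom("CG").coords) > 0.5
        assert np.linalg.norm(a.atom("OH").coords - b.atom("OH").coords) > 0.5

    @pytest.mark.parametrize("code", ["SER", "DPP", "LYS", "26P", "PHE"])
    def test_built_chirality_matches_request(self, lib, code):
        bb = toyfactory.ideal_backbone(1, "B", 0.0, 6.0)
        tmpl = lib.template(code)
        for chir in ("L", "D"):
            res = build_sidechain(bb, tmpl, [180.0] * tmpl.n_chi, chirality=chir)
            assert assign_chirality(res) == chir

    def test_d_build_is_mirror_of_l_build(self, lib, dihedral_oracle):
        bb = toyfactory.ideal_backbone(1, "B", 0.0, 6.0)
        tmpl = lib.template("DPP")
        l = build_sidechain(bb, tmpl, [-60.0], chirality="L")
        d = build_sidechain(bb, tmpl, [-60.0], chirality="D")
        chi_l = dihedral_oracle(l.atom("N").coords, l.atom("CA").coords,
                                l.atom("CB").coords, l.atom("NG").coords)
        chi_d = dihedral_oracle(d.atom("N").coords, d.atom("CA").coords,
                                d.atom("CB").coords, d.atom("NG").coords)
        assert chi_l == pytest.approx(-chi_d, abs=1e-6)

    def test_missing_backbone_errors(self, lib):
        res = structio.Residue(chain_id="B", resseq=1, name3="GLY", atoms=[
            structio.Atom(serial=1, name="CA", element="C", coords=[0, 0, 0]),
        ])
        with pytest.raises(MutscanError, match="backbone"):
            build_sidechain(res, lib.template("ALA"), [])

    def test_wrong_chi_count_errors(self, lib):
        bb = toyfactory.ideal_backbone(1, "B", 0.0, 6.0)
        with pytest.raises(MutscanError, match="chi"):
            build_sidechain(bb, lib.template("SER"), [])


class TestExpandRotamers:
    def _lib(self, rotamers, n_chi=1):
        names = ["N", "CA", "CB", "XX"][: 2 + n_chi + 1]
        tmpl = mutscan.ResidueTemplate(
            name3="ZZZ", category="NCAA", hydro_class="polar", size_class="small",
            chi_definitions=[("N", "CA", "CB", "XX")] * n_chi,
        )
        return ResidueLibrary(templates={"ZZZ": tmpl}, rotamers={"ZZZ": rotamers},
                              expansion_mode="2sigma")

    def test_one_chi_two_base_gives_six(self):
        lib = self._lib([Rotamer((-60,), (9,)), Rotamer((180,), (9,))])
        assert len(expand_rotamers(lib, "ZZZ")) == 6

    def test_two_chi_one_base_gives_nine(self):
        lib = self._lib([Rotamer((-60, 180), (9, 9))], n_chi=2)
        out = expand_rotamers(lib, "ZZZ")
        assert len(out) == 9
        assert (-60 - 18, 180 - 18) in out and (-60, 180) in out

    def test_expansion_off_keeps_base(self):
        lib = self._lib([Rotamer((-60,), (9,)), Rotamer((180,), (9,))])
        lib.expansion_mode = "none"
        assert expand_rotamers(lib, "ZZZ") == [(-60,), (180,)]

    def test_unknown_code_errors(self, lib):
        with pytest.raises(MutscanError):
            expand_rotamers(lib, "XYZ")


class TestRepack:
    @pytest.fixture()
    def toy(self, ff, lib):
        spec = toyfactory.ToySystemSpec(
            n_host_beads=6, n_ligand_res=4, seed=5, scaffold_code="SER",
            planted_interactions=[{"kind": "salt_bridge", "position": 2, "code": "DPP"}],
        )
        s, _ = toyfactory.make_toy_complex(spec, ff=ff, lib=lib)
        return s

    def _exhaustive(self, s, positions, ff, lib):
        cands = [expand_rotamers(lib, "SER") for _ in positions]
        best = (np.inf, None)
        for assign in itertools.product(*[range(len(c)) for c in cands]):
            m = s
            for p, ai in zip(positions, assign):
                m = mutate_residue(m, p, "SER", lib, chis=cands[0][ai])
            e = ffmodel.energy(mutscan.structure_system(m, ff, lib)).total
            if e < best[0]:
                best = (e, assign)
        return best[0]

    def test_matches_exhaustive_enumeration(self, toy, ff, lib):
        positions = [("B", i) for i in range(1, 5)]  # 4 positions x 3 rotamers
        oracle = self._exhaustive(toy, positions, ff, lib)
        for seed in (0, 1):
            _, e = repack(toy, ff, positions, lib, seed=seed, n_restarts=6)
            assert e == pytest.approx(oracle, abs=1e-9)

    def test_single_position_picks_minimum(self, toy, ff, lib):
        oracle = self._exhaustive(toy, [("B", 2)], ff, lib)
        _, e = repack(toy, ff, [("B", 2)], lib, seed=0)
        assert e == pytest.approx(oracle, abs=1e-9)

    def test_empty_positions_identity(self, toy, ff, lib):
        out, e = repack(toy, ff, [], lib, seed=0)
        sys_ = mutscan.structure_system(toy, ff, lib)
        assert e == pytest.approx(ffmodel.energy(sys_).total, abs=1e-12)
        assert out is toy

    def test_position_without_rotamers_errors(self, toy, ff, lib):
        with pytest.raises((MutscanError, structio.StructureError)):
            repack(toy, ff, [("B", 99)], lib, seed=0)


class TestScan:
    @pytest.fixture()
    def scan_setup(self, ff, lib, planted_toy):
        iface = find_interface([planted_toy], "B", {"A"}, 5.0)
        return planted_toy, iface

    def test_self_mutation_near_zero(self, scan_setup, ff, lib):
        s, iface = scan_setup
        res = scan([s], iface, ["ALA"], ff, lib, n_repeats=5, seed=0)
        for (pos, code), e in res.entries.items():
            assert abs(e.mean) <= max(2 * e.sd, 1e-6)

    def test_planted_code_ranks_first(self, scan_setup, ff, lib):
        s, iface = scan_setup
        alphabet = ["GLY", "ALA", "SER", "ASP", "LYS", "PHE", "DPP", "ABA"]
        res = scan([s], iface, alphabet, ff, lib, n_repeats=2, seed=0)
        assert res.ranking(2)[0][0] == "DPP"

    def test_entry_bookkeeping(self, scan_setup, ff, lib):
        s, iface = scan_setup
        res = scan([s], iface, ["SER"], ff, lib, n_repeats=2, seed=0)
        assert len(res.entries) == len(iface)

    def test_invariant_to_ensemble_ordering(self, ff, lib, planted_toy):
        other = planted_toy.copy()
        for r in other.models[0]:
            for a in r.atoms:
                a.coords = a.coords + np.array([0.05, 0.0, 0.0])
        iface = find_interface([planted_toy, other], "B", {"A"}, 5.0)
        a = scan([planted_toy, other], iface, ["DPP"], ff, lib, n_repeats=2, seed=0)
        b = scan([other, planted_toy], iface, ["DPP"], ff, lib, n_repeats=2, seed=0)
        for key in a.entries:
            assert a.entries[key].best == pytest.approx(b.entries[key].best, abs=1e-9)
            assert sorted(a.entries[key].per_backbone) == pytest.approx(
                sorted(b.entries[key].per_backbone), abs=1e-9)

    def test_empty_interface_errors(self, ff, lib, planted_toy):
        empty = structio.InterfaceSet(entries=[], cutoff=5.0)
        with pytest.raises(MutscanError):
            scan([planted_toy], empty, ["ALA"], ff, lib, n_repeats=1, seed=0)


class TestMakeLogo:
    def _result(self, entries):
        return mutscan.ScanResult(
            entries={k: mutscan.ScanEntry(mean=v, sd=0.0, best=v, per_backbone=[v], n=1)
                     for k, v in entries.items()},
            chain_id="B", alphabet=sorted({c for _, c in entries}),
        )

    def test_proportional_heights(self):
        logo = make_logo(self._result({(1, "DPP"): -2.0, (1, "SER"): -1.0}))
        assert logo.columns[1]["DPP"] == pytest.approx(1.0)
        assert logo.columns[1]["SER"] == pytest.approx(0.5)

    def test_non_negative_column_empty(self):
        logo = make_logo(self._result({(1, "DPP"): 0.5, (1, "SER"): 0.0}))
        assert logo.columns[1] == {}

    def test_plot_logo_writes_image(self, tmp_path):
        logo = make_logo(self._result({(1, "DPP"): -2.0, (2, "SER"): -1.0}))
        out = tmp_path / "logo.png"
        mutscan.plot_logo(logo, out, title="toy scan")
        assert out.exists() and out.stat().st_size > 0

    def test_max_height_is_one(self):
        logo = make_logo(self._result({
            (1, "DPP"): -3.0, (1, "SER"): -0.4, (2, "ASP"): -0.1,
        }))
        for col in logo.columns.values():
            if col:
                assert max(col.values()) == pytest.approx(1.0)
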