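import numpy as np
import pytest

from mirrorbind import mutscan, structio, toyfactory


@pytest.fixture(scope="session")
def lib():
    return mutscan.default_library()


@pytest.fixture(scope="session")
def ff():
    return mutscan.default_forcefield()


@pytest.fixture(scope="session")
def ideal_ala_residue():
    """Ideal L-alanine heavy-atom residue from the bundled chemical
    component dictionary (independent of the package's templates)."""
    import biotite.structure.info as info

    arr = info.residue("ALA")
    atoms = [
        structio.Atom(serial=i + 1, name=str(n), element=str(arr.element[i]),
                      coords=arr.coord[i])
        for i, n in enumerate(arr.atom_name)
        if str(n) in ("N", "CA", "C", "O", "CB")
    ]
    return structio.Residue(chain_id="A", resseq=1, name3="ALA", atoms=atoms)


@pytest.fixture()
def planted_toy(ff, lib):
    """Toy complex with a salt-bridge plant whose optimum mutation is DPP."""
    spec = toyfactory.ToySystemSpec(
        n_host_beads=5,
        n_ligand_res=3,
        planted_interactions=[{"kind": "salt_bridge", "position": 2, "code": "DPP"}],
        preferred_mutation=(2, "DPP"),
        seed=1,
        alphabet=["GLY", "ALA", "SER", "ASP", "LYS", "PHE", "DPP", "ABA"],
    )
    s, _ = toyfactory.make_toy_complex(spec, ff=ff, lib=lib)
    return s


def biotite_dihedral(p1, p2, p3, p4):
    """Independent dihedral oracle (biotite implementation)."""
    import biotite.structure as bst

    return float(np.degrees(bst.dihedral(
        np.asarray(p1, float), np.asarray(p2, float),
        np.asarray(p3, float), np.asarray(p4, float),
    )))


@pytest.fixture(scope="session")
def dihedral_oracle():
    return biotite_dihedral
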