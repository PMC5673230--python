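"""Synthetic host-guest toy systems and analytic free-energy oracles.

The generator stands in, at desk scale, for a real receptor-inhibitor
complex: a rigid "host" chain of beads and a short "guest" peptide whose
side chains are built from the packaged residue templates.  Planted
interactions (salt bridge, hydrogen bond, hydrophobic patch) place a
complementary host bead where a chosen mutation's side chain can reach it;
at generation time the preferred mutation is verified by exhaustive
evaluation to be the global optimum of the interface score at its position,
so scan-recovery tests have a known ground truth.

Oracle systems provide exact reference free energies for the TI engine:

* ``harmonic_spring`` - dG = (kT/2) ln(k_B/k_A) per coupled degree of freedom;
* ``fixed_pair_charging`` - dG = k_C * delta(q1 q2) / r at frozen geometry;
* ``grid_quadrature``   - dG = -kT ln(Z(1)/Z(0)) with Z evaluated by dense
  numerical integration over a low-dimensional configuration space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import ffmodel, mutscan
from .ffmodel import (
    AlchemicalTopology,
    ForceField,
    TypedSystem,
    coupled_potential,
    AlchemicalState,
)
from .alchemy import AlchemicalSystem, GAS_CONSTANT_KCAL
from .structio import Atom, Residue, Structure
from .mutscan import ResidueLibrary, expand_rotamers, build_sidechain

__all__ = [
    "ToySystemSpec",
    "OracleSystem",
    "ToyFactoryError",
    "make_toy_complex",
    "exact_dG",
    "HarmonicMorphSystem",
    "LinearMixSystem",
    "make_charge_flip_toy",
    "ideal_backbone",
]


class ToyFactoryError(RuntimeError):
    pass


@dataclass
class ToySystemSpec:
    n_host_beads: int = 6
    n_ligand_res: int = 3
    # planted interactions: dicts with kind in {salt_bridge, hbond,
    # hydrophobic_patch} and a ligand position index
    planted_interactions: list[dict] = field(default_factory=list)
    preferred_mutation: tuple[int, str] | None = None   # (resseq, code)
    seed: int = 0
    gap: float = 5.5          # host plane to ligand CA plane, Angstrom
    host_spacing: float = 4.5
    scaffold_code: str = "ALA"           # guest scaffold residue type
    alphabet: list[str] | None = None    # verification alphabet
    min_bead_separation: float = 2.0


# ---------------------------------------------------------------------------
# toy complex construction
# ---------------------------------------------------------------------------

def ideal_backbone(resseq: int, chain_id: str, x0: float, z: float,
                   chirality: str = "D") -> Residue:
    """One residue of an idealised extended strand lying in the y=0 plane."""
    # strand orientation chosen so that D side chains point toward -z (the host)
    n = np.array([x0 - 1.2, -0.8, z])
    ca = np.array([x0, 0.0, z])
    c = np.array([x0 + 1.2, -0.8, z])
    o = np.array([x0 + 1.2, -2.0, z])
    atoms = [
        Atom(serial=1, name="N", element="N", coords=n),
        Atom(serial=2, name="CA", element="C", coords=ca),
        Atom(serial=3, name="C", element="C", coords=c),
        Atom(serial=4, name="O", element="O", coords=o),
    ]
    return Residue(chain_id=chain_id, resseq=resseq, name3="GLY",
                   atoms=atoms, chirality=chirality)


_PLANT_BEADS = {
    "salt_bridge": {"positive": "HBM", "negative": "HBP"},  # complement by sign
    "hbond": "HBM",
    "hydrophobic_patch": "HBH",
}

_PLANT_DISTANCE = {"salt_bridge": 3.0, "hbond": 3.0, "hydrophobic_patch": 4.2}


def _terminal_atom(res: Residue) -> Atom:
    side = [a for a in res.atoms if a.name not in ("N", "CA", "C", "O")]
    if not side:
        raise ToyFactoryError("planted position has no side-chain atoms")
    ca = res.atom("CA").coords
    return max(side, key=lambda a: np.linalg.norm(a.coords - ca))


def _best_interface_score(
    s: Structure, position: tuple[str, int], code: str,
    ff: ForceField, lib: ResidueLibrary,
) -> float:
    """Best (lowest) interface score over the code's rotamers at a position,
    all other residues left as-is."""
    best = np.inf
    for chis in expand_rotamers(lib, code):
        mut = mutscan.mutate_residue(s, position, code, lib, chis=chis)
        sys_ = mutscan.structure_system(mut, ff, lib)
        best = min(best, ffmodel.interface_score(sys_))
    return best


def make_toy_complex(
    spec: ToySystemSpec,
    ff: ForceField | None = None,
    lib: ResidueLibrary | None = None,
) -> tuple[Structure, ForceField]:
    """Deterministic toy host-guest complex.

    Host beads (chain A) lie on a line in the z=0 plane; the guest peptide
    (chain B, D-chirality, glycine scaffold) runs parallel at ``gap``.
    Planted beads are positioned complementary to the preferred mutation's
    extended side chain and the plant is verified to be the score optimum.
    """
    ff = ff or mutscan.default_forcefield()
    lib = lib or mutscan.default_library()
    rng = np.random.default_rng(spec.seed)

    residues: list[Residue] = []
    # guest peptide along x, CA spacing 3.8, D chirality, scaffold side chains
    tmpl = lib.template(spec.scaffold_code)
    chis0 = lib.rotamers[spec.scaffold_code][0].chi_means
    for i in range(spec.n_ligand_res):
        bb = ideal_backbone(i + 1, "B", 3.8 * i, spec.gap)
        residues.append(build_sidechain(bb, tmpl, chis0, chirality="D"))

    s = Structure(models=[[]])
    # host beads along x at z=0, jittered slightly for generality
    host: list[Residue] = []
    for i in range(spec.n_host_beads):
        x = spec.host_spacing * i - 0.5 * spec.host_spacing * (spec.n_host_beads - spec.n_ligand_res)
        jitter = rng.normal(0.0, 0.15, size=3) * np.array([1, 1, 0])
        coords = np.array([x, 0.0, 0.0]) + jitter
        host.append(
            Residue(
                chain_id="A", resseq=i + 1, name3="BEA",
                atoms=[Atom(serial=1, name="HBN", element="C", coords=coords)],
            )
        )
    s.models[0] = host + residues

    # plant interactions
    plant_serial = spec.n_host_beads
    for plant in spec.planted_interactions:
        kind = plant["kind"]
        resseq = plant["position"]
        code = plant.get("code") or (
            spec.preferred_mutation[1]
            if spec.preferred_mutation and spec.preferred_mutation[0] == resseq
            else None
        )
        if code is None:
            raise ToyFactoryError(f"plant at {resseq} needs a residue code")
        # build the target side chain extended to find the complement site
        probe = mutscan.mutate_residue(s, ("B", resseq), code, lib)
        res = next(r for r in probe.residues(0) if (r.chain_id, r.resseq) == ("B", resseq))
        tip = _terminal_atom(res)
        ca = res.atom("CA").coords
        direction = tip.coords - ca
        direction /= np.linalg.norm(direction)
        site = tip.coords + direction * _PLANT_DISTANCE[kind]
        if kind == "salt_bridge":
            tmpl = lib.template(code)
            tip_type = ff.atom_types.get(
                next(a.type_key for a in tmpl.atoms if a.name == tip.name)
            )
            bead = "HBM" if tip_type and tip_type.formal_charge > 0 else "HBP"
        elif kind == "hbond":
            bead = _PLANT_BEADS["hbond"]
        else:
            bead = _PLANT_BEADS["hydrophobic_patch"]
        plant_serial += 1
        host_bead = Residue(
            chain_id="A", resseq=plant_serial, name3="BEA",
            atoms=[Atom(serial=1, name=bead, element="X", coords=site)],
        )
        s.models[0] = [host_bead] + s.models[0]

    # physical realisability: no overlapping beads
    pts = np.array([a.coords for r in s.residues(0) for a in r.atoms])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # neighbouring bonded backbone atoms are close by construction; only
    # check host beads against everything else
    n_host_atoms = len([a for r in s.residues(0) if r.chain_id == "A" for a in r.atoms])
    if np.min(d[:n_host_atoms]) < spec.min_bead_separation:
        raise ToyFactoryError("unrealisable geometry: overlapping beads")

    # verify the planted mutation is the global optimum at its position
    if spec.preferred_mutation is not None:
        resseq, code = spec.preferred_mutation
        alphabet = spec.alphabet or (mutscan.CAA_CODES + mutscan.NCAA_CODES)
        scores = {
            c: _best_interface_score(s, ("B", resseq), c, ff, lib) for c in alphabet
        }
        best_code = min(scores, key=lambda c: scores[c])
        if best_code != code:
            raise ToyFactoryError(
                f"planted mutation {code} at {resseq} is not optimal "
                f"(best is {best_code}: {scores[best_code]:.3f} vs {scores[code]:.3f})"
            )
    s.metadata["toy_spec"] = spec
    return s, ff


# ---------------------------------------------------------------------------
# oracle systems
# ---------------------------------------------------------------------------

@dataclass
class OracleSystem:
    kind: str                      # harmonic_spring | fixed_pair_charging | grid_quadrature
    params: dict
    temperature: float = 300.0

    @property
    def kT(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature


def exact_dG(oracle: OracleSystem) -> float:
    """Closed-form or brute-force reference free energy for an oracle system."""
    kT = oracle.kT
    p = oracle.params
    if oracle.kind == "harmonic_spring":
        ndim = p.get("ndim", 1)
        return 0.5 * kT * np.log(p["k_B"] / p["k_A"]) * ndim
    if oracle.kind == "fixed_pair_charging":
        kC = p.get("coulomb_constant", ffmodel.COULOMB_CONSTANT)
        dqq = p["q1_B"] * p["q2"] - p["q1_A"] * p["q2"]
        return kC * dqq / p["r"]
    if oracle.kind == "grid_quadrature":
        u_a: Callable = p["u_A"]
        u_b: Callable = p["u_B"]
        grid = p["grid"]             # 1-D array or tuple of 1-D arrays
        measure = p.get("measure")   # optional weight, e.g. 4*pi*r^2
        if isinstance(grid, tuple):
            xs = np.meshgrid(*grid, indexing="ij")
            za = np.exp(-u_a(*xs) / kT)
            zb = np.exp(-u_b(*xs) / kT)
            if measure is not None:
                w = measure(*xs)
                za, zb = za * w, zb * w
            for axis_vals in reversed(grid):
                za = np.trapezoid(za, axis_vals, axis=-1)
                zb = np.trapezoid(zb, axis_vals, axis=-1)
        else:
            za = np.exp(-u_a(grid) / kT)
            zb = np.exp(-u_b(grid) / kT)
            if measure is not None:
                w = measure(grid)
                za, zb = za * w, zb * w
            za = np.trapezoid(za, grid)
            zb = np.trapezoid(zb, grid)
        return float(-kT * np.log(zb / za))
    raise ToyFactoryError(f"unsupported oracle kind {oracle.kind!r}")


# ---------------------------------------------------------------------------
# coupled systems for the TI engine
# ---------------------------------------------------------------------------

class HarmonicMorphSystem:
    """Single particle, harmonic spring k(lambda) = k_A + lambda (k_B - k_A)
    acting on the first ``ndim`` coordinates; uncoupled coordinates are
    restrained by a fixed unit spring so the walk stays bounded."""

    def __init__(self, k_a: float, k_b: float, ndim: int = 1):
        self.k_a, self.k_b, self.ndim = k_a, k_b, ndim
        self.coords = np.zeros((1, 3))
        self.movable = None

    def u_and_dudl(self, coords: np.ndarray, stage: str, lam: float):
        x = np.asarray(coords, float).ravel()
        act = x[: self.ndim]
        rest = x[self.ndim:]
        k = self.k_a + lam * (self.k_b - self.k_a)
        u = 0.5 * k * float(np.sum(act**2)) + 0.5 * float(np.sum(rest**2))
        dudl = 0.5 * (self.k_b - self.k_a) * float(np.sum(act**2))
        return u, dudl


class LinearMixSystem:
    """Single-stage linear mixing U = (1-lambda) U_A + lambda U_B of the two
    endpoint topologies of a dual-topology mutation (no softcore); valid when
    the endpoints have no steric clash."""

    def __init__(self, topo: AlchemicalTopology, coords: np.ndarray, movable=None):
        self.topo = topo
        self.coords = np.array(coords, float)
        self.movable = movable

    def _endpoints(self, coords):
        ua, _ = coupled_potential(coords, self.topo, AlchemicalState("decharge", 0.0))
        ub, _ = coupled_potential(coords, self.topo, AlchemicalState("recharge", 1.0))
        return ua, ub

    def u_and_dudl(self, coords: np.ndarray, stage: str, lam: float):
        ua, ub = self._endpoints(coords)
        return (1.0 - lam) * ua + lam * ub, ub - ua


def make_charge_flip_toy(
    q_a: float = 0.3,
    q_b: float = -0.3,
    host_charge: float = -0.5,
    r0: float = 3.2,
    k_tether: float = 10.0,
    environment: str = "complex",
    ff: ForceField | None = None,
) -> tuple[AlchemicalSystem, OracleSystem]:
    """A fully computable binding toy: one mobile guest bead tethered at r0
    from a fixed host bead, mutating its charge q_A -> q_B.

    In the ``complex`` environment the host carries ``host_charge``; in the
    ``free`` environment it is an uncharged tether anchor.  Both alchemical
    beads share LJ parameters and tether, so dummy contributions cancel and
    the exact mutation free energy reduces to a radial one-dimensional
    partition-function ratio, returned as a grid-quadrature oracle.
    """
    ff = ff or mutscan.default_forcefield()
    host_q = host_charge if environment == "complex" else 0.0
    bead = ff.atom_types["HBN"]
    eps_hh = np.sqrt(bead.epsilon * bead.epsilon)
    sig_hh = bead.sigma

    sys_ = TypedSystem(
        coords=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0], [r0, 0.0, 0.0]]),
        type_keys=["HBN", "HBN", "HBN"],
        eps=np.array([bead.epsilon] * 3),
        sig=np.array([bead.sigma] * 3),
        charge=np.array([host_q, q_a, q_b]),
        chain_ids=["A", "B", "B"],
        ff=ff,
        restraints=[(0, 1, k_tether, r0), (0, 2, k_tether, r0)],
        labels=["host", "guest_A", "guest_B"],
    )
    topo = AlchemicalTopology(system=sys_, vanishing={1}, appearing={2})
    asys = AlchemicalSystem(topo=topo, coords=sys_.coords.copy(),
                            movable=np.array([1, 2]))

    kC = ff.coulomb_constant

    def radial_u(q):
        def u(r):
            x = (sig_hh / r) ** 6
            lj = 4.0 * eps_hh * (x * x - x)
            return k_tether * (r - r0) ** 2 + kC * q * host_q / r + lj
        return u

    oracle = OracleSystem(
        kind="grid_quadrature",
        params={
            "u_A": radial_u(q_a),
            "u_B": radial_u(q_b),
            "grid": np.linspace(1.5, 8.0, 4000),
            "measure": lambda r: 4.0 * np.pi * r**2,
        },
    )
    return asys, oracle
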