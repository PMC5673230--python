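"""Simplified molecular-mechanics energy model with alchemical coupling.

The model is a united-heavy-atom force field: harmonic bonds and angles,
cosine torsions, 12-6 Lennard-Jones with Lorentz-Berthelot combination and
plain Coulomb electrostatics (constant or distance-dependent dielectric),
both truncated at a hard cutoff (default 12 Angstrom, no long-range
correction).  Energies are in kcal/mol, distances in Angstrom, charges in
elementary charge units; the Coulomb constant is 332.0636 kcal*A/(mol*e^2).

Alchemical transformations use a dual topology (common + vanishing +
appearing atom sets) traversed in three stages:

1. ``decharge``  - vanishing-atom charges scaled by (1 - lambda);
2. ``vdw``       - softcore Lennard-Jones with the vanishing atoms coupled by
                   (1 - lambda) and the appearing atoms by lambda, while all
                   mutating-atom charges are zero;
3. ``recharge``  - appearing-atom charges scaled by lambda.

Charges are scaled only while van der Waals spheres are intact, so plain
(linear) Coulomb suffices and only the vdW stage needs a softcore form.  The
separation-shifted softcore used here is

    V(r) = 4 eps c [ (a(1-c) + x)^-2 - (a(1-c) + x)^-1 ],  x = (r/sigma)^6,

with per-pair coupling c (product of the two atoms' couplings) and softcore
parameter a = alpha (default 0.5).  At c = 1 this is exactly standard LJ; for
c < 1 it is finite at r = 0.  ``coupled_potential`` returns the analytic
d U / d lambda alongside U.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .structio import Structure

__all__ = [
    "COULOMB_CONSTANT",
    "AtomType",
    "ForceField",
    "SoftcoreParams",
    "AlchemicalTopology",
    "AlchemicalState",
    "TypedSystem",
    "EnergyTerms",
    "FFError",
    "load_forcefield",
    "energy",
    "interface_score",
    "softcore_lj",
    "coupled_potential",
]

COULOMB_CONSTANT = 332.0636  # kcal*Angstrom/(mol*e^2)

STAGES = ("decharge", "vdw", "recharge")


class FFError(ValueError):
    """Raised for force-field contract violations (untyped atoms, bad lambda)."""


@dataclass(frozen=True)
class AtomType:
    key: str
    epsilon: float  # kcal/mol
    sigma: float    # Angstrom
    charge: float   # e
    formal_charge: int = 0
    hydro_class: str = "polar"   # hydrophobic | polar | charged
    size_class: str = "medium"   # small | medium | large
    hb_donor: bool = False
    hb_acceptor: bool = False

    def __post_init__(self):
        if self.epsilon < 0:
            raise FFError(f"type {self.key}: epsilon must be >= 0")
        if self.sigma <= 0:
            raise FFError(f"type {self.key}: sigma must be > 0")


@dataclass
class ForceField:
    atom_types: dict[str, AtomType] = field(default_factory=dict)
    bond_params: dict[frozenset, tuple[float, float]] = field(default_factory=dict)   # (k, r0)
    angle_params: dict[tuple, tuple[float, float]] = field(default_factory=dict)      # (k, theta0 deg)
    torsion_params: dict[tuple, tuple[float, int, float]] = field(default_factory=dict)  # (A, n, phase deg)
    nonbonded_cutoff: float = 12.0
    dielectric_model: str = "constant"  # constant | distance-dependent
    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        if self.nonbonded_cutoff <= 0:
            raise FFError("cutoff must be > 0")

    def type_of(self, key: str) -> AtomType:
        try:
            return self.atom_types[key]
        except KeyError:
            raise FFError(f"untyped atom: no atom type {key!r}") from None

    def bond(self, t1: str, t2: str) -> tuple[float, float]:
        return self.bond_params.get(frozenset((t1, t2)), (300.0, 1.53))


@dataclass(frozen=True)
class SoftcoreParams:
    alpha: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0:
            raise FFError("softcore alpha must be > 0")


@dataclass(frozen=True)
class AlchemicalState:
    stage: str  # decharge | vdw | recharge
    lam: float

    def __post_init__(self):
        if self.stage not in STAGES:
            raise FFError(f"unknown stage {self.stage!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise FFError(f"lambda {self.lam} outside [0, 1]")


class EnergyTerms(NamedTuple):
    bonded: float
    lj: float
    coulomb: float

    @property
    def total(self) -> float:
        return self.bonded + self.lj + self.coulomb


# ---------------------------------------------------------------------------
# typed systems
# ---------------------------------------------------------------------------

@dataclass
class TypedSystem:
    """A fully typed configuration: parallel per-atom parameter arrays plus
    bonded terms and nonbonded exclusions (1-2 and 1-3 pairs)."""

    coords: np.ndarray                 # (n, 3)
    type_keys: list[str]
    eps: np.ndarray
    sig: np.ndarray
    charge: np.ndarray
    chain_ids: list[str]
    ff: ForceField
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)      # i, j, k, r0
    # harmonic distance restraints: same form as bonds but generating no
    # nonbonded exclusions (tethers for dummy atoms etc.)
    restraints: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)  # i, j, k, kth, th0
    torsions: list[tuple[int, int, int, int, float, int, float]] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)   # e.g. "B:5:CB" for bookkeeping
    exclusions: set[frozenset] = field(default_factory=set)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.n = len(self.type_keys)
        if not self.labels:
            self.labels = [f"atom{i}" for i in range(self.n)]
        self._rebuild_exclusions()

    def _rebuild_exclusions(self) -> None:
        self._pair_cache = None
        excl: set[frozenset] = set(self.exclusions)
        neigh: dict[int, set[int]] = {}
        for i, j, _, _ in self.bonds:
            excl.add(frozenset((i, j)))
            neigh.setdefault(i, set()).add(j)
            neigh.setdefault(j, set()).add(i)
        for j, partners in neigh.items():
            for i in partners:
                for k in partners:
                    if i < k:
                        excl.add(frozenset((i, k)))
        self.exclusions = excl

    def pair_mask(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle index pairs minus exclusions (cached)."""
        if getattr(self, "_pair_cache", None) is None:
            iu, ju = np.triu_indices(self.n, k=1)
            if self.exclusions:
                keep = np.array(
                    [frozenset((int(i), int(j))) not in self.exclusions
                     for i, j in zip(iu, ju)]
                )
                iu, ju = iu[keep], ju[keep]
            self._pair_cache = (iu, ju)
        return self._pair_cache

    def subsystem(self, indices) -> "TypedSystem":
        indices = list(indices)
        remap = {old: new for new, old in enumerate(indices)}
        sel = np.array(indices, dtype=int)
        return TypedSystem(
            coords=self.coords[sel],
            type_keys=[self.type_keys[i] for i in indices],
            eps=self.eps[sel],
            sig=self.sig[sel],
            charge=self.charge[sel],
            chain_ids=[self.chain_ids[i] for i in indices],
            ff=self.ff,
            bonds=[(remap[i], remap[j], k, r0) for i, j, k, r0 in self.bonds
                   if i in remap and j in remap],
            restraints=[(remap[i], remap[j], k, r0) for i, j, k, r0 in self.restraints
                        if i in remap and j in remap],
            angles=[(remap[i], remap[j], remap[k], kt, t0)
                    for i, j, k, kt, t0 in self.angles
                    if i in remap and j in remap and k in remap],
            torsions=[(remap[i], remap[j], remap[k], remap[l], a, n, p)
                      for i, j, k, l, a, n, p in self.torsions
                      if all(x in remap for x in (i, j, k, l))],
            labels=[self.labels[i] for i in indices],
        )


def system_from_structure(
    s: Structure,
    ff: ForceField,
    type_map=None,
    bonds: list[tuple[str, str]] | None = None,
    model: int = 0,
) -> TypedSystem:
    """Build a TypedSystem from a Structure.

    ``type_map`` maps (residue name3, atom name) or atom name to a type key;
    by default the atom name itself is the type key.  ``bonds`` is a list of
    (label, label) pairs using "chain:resseq:atom" labels.
    """
    coords, keys, chains, labels = [], [], [], []
    index: dict[str, int] = {}
    for r in s.residues(model):
        for a in r.atoms:
            if type_map is None:
                key = a.name
            else:
                key = type_map.get((r.name3, a.name)) or type_map.get(a.name) or a.name
            ff.type_of(key)  # raises on untyped atom
            lab = f"{r.chain_id}:{r.resseq}:{a.name}"
            index[lab] = len(coords)
            coords.append(a.coords)
            keys.append(key)
            chains.append(r.chain_id)
            labels.append(lab)
    bond_terms = []
    for la, lb in bonds or []:
        i, j = index[la], index[lb]
        k, r0 = ff.bond(keys[i], keys[j])
        bond_terms.append((i, j, k, r0))
    types = [ff.type_of(k) for k in keys]
    return TypedSystem(
        coords=np.array(coords),
        type_keys=keys,
        eps=np.array([t.epsilon for t in types]),
        sig=np.array([t.sigma for t in types]),
        charge=np.array([t.charge for t in types]),
        chain_ids=chains,
        ff=ff,
        bonds=bond_terms,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# plain energy
# ---------------------------------------------------------------------------

def _coulomb_factor(ff: ForceField, r: np.ndarray) -> np.ndarray:
    """k / (eps_r * r); distance-dependent dielectric uses eps_r = r."""
    if ff.dielectric_model == "distance-dependent":
        return ff.coulomb_constant / (r * r)
    return ff.coulomb_constant / (ff.dielectric * r)


def _bonded_energy(sys_: TypedSystem, coords: np.ndarray) -> float:
    e = 0.0
    for i, j, k, r0 in sys_.bonds + sys_.restraints:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e += k * (r - r0) ** 2
    for i, j, k, kth, th0 in sys_.angles:
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        cos = np.clip(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0
        )
        e += kth * (np.degrees(np.arccos(cos)) - th0) ** 2 * (np.pi / 180.0) ** 2
    for i, j, k, l, a, n, phase in sys_.torsions:
        from .structio import dihedral_angle

        phi = dihedral_angle(coords[i], coords[j], coords[k], coords[l])
        e += a * (1.0 + np.cos(np.radians(n * phi - phase)))
    return float(e)


def energy(sys_: TypedSystem, coords: np.ndarray | None = None) -> EnergyTerms:
    """Decomposed energy (bonded, LJ, Coulomb) of a typed configuration."""
    coords = sys_.coords if coords is None else np.asarray(coords, float)
    iu, ju = sys_.pair_mask()
    lj = coul = 0.0
    if len(iu):
        d = coords[iu] - coords[ju]
        r = np.linalg.norm(d, axis=1)
        mask = r < sys_.ff.nonbonded_cutoff
        if np.any(mask):
            r = r[mask]
            i, j = iu[mask], ju[mask]
            eps = np.sqrt(sys_.eps[i] * sys_.eps[j])
            sig = 0.5 * (sys_.sig[i] + sys_.sig[j])
            x = (sig / r) ** 6
            lj = float(np.sum(4.0 * eps * (x * x - x)))
            qq = sys_.charge[i] * sys_.charge[j]
            coul = float(np.sum(qq * _coulomb_factor(sys_.ff, r)))
    return EnergyTerms(bonded=_bonded_energy(sys_, coords), lj=lj, coulomb=coul)


def interface_score(sys_: TypedSystem, coords: np.ndarray | None = None) -> float:
    """Binding-oriented score: E(complex) - sum of E(isolated chains) at the
    same coordinates, which equals the cross-chain nonbonded energy.
    Negative means a favourable interface."""
    if len(set(sys_.chain_ids)) < 2:
        raise FFError("interface_score requires >= 2 chains")
    coords = sys_.coords if coords is None else np.asarray(coords, float)
    iu, ju = sys_.pair_mask()
    chains = np.array(sys_.chain_ids)
    cross = chains[iu] != chains[ju]
    iu, ju = iu[cross], ju[cross]
    if len(iu) == 0:
        return 0.0
    d = coords[iu] - coords[ju]
    r = np.linalg.norm(d, axis=1)
    mask = r < sys_.ff.nonbonded_cutoff
    if not np.any(mask):
        return 0.0
    r = r[mask]
    i, j = iu[mask], ju[mask]
    eps = np.sqrt(sys_.eps[i] * sys_.eps[j])
    sig = 0.5 * (sys_.sig[i] + sys_.sig[j])
    x = (sig / r) ** 6
    lj = np.sum(4.0 * eps * (x * x - x))
    coul = np.sum(sys_.charge[i] * sys_.charge[j] * _coulomb_factor(sys_.ff, r))
    return float(lj + coul)


# ---------------------------------------------------------------------------
# softcore Lennard-Jones
# ---------------------------------------------------------------------------

def softcore_lj(r, lam_couple, eps, sigma, sc: SoftcoreParams = SoftcoreParams()):
    """Separation-shifted softcore LJ; reduces to standard LJ at full
    coupling (lam_couple = 1) and stays finite at r = 0 for coupling < 1."""
    r = np.asarray(r, dtype=float)
    c = float(lam_couple)
    x = (r / sigma) ** 6
    s = sc.alpha * (1.0 - c) + x
    v = 4.0 * eps * c * (s ** -2 - s ** -1)
    return float(v) if np.isscalar(lam_couple) and v.ndim == 0 else v


def _softcore_and_dcoupling(r, c, eps, sig, alpha):
    """Vectorised softcore value and its derivative w.r.t. the pair coupling."""
    x = (r / sig) ** 6
    s = alpha * (1.0 - c) + x
    inv1 = 1.0 / s
    inv2 = inv1 * inv1
    v = 4.0 * eps * c * (inv2 - inv1)
    dv_dc = 4.0 * eps * (inv2 - inv1) + 4.0 * eps * c * alpha * (2.0 * inv2 * inv1 - inv2)
    return v, dv_dc


# ---------------------------------------------------------------------------
# alchemical topology and coupled potential
# ---------------------------------------------------------------------------

@dataclass
class AlchemicalTopology:
    """Dual-topology description of a mutation on a union TypedSystem.

    ``system`` holds the union of common, vanishing (state A only) and
    appearing (state B only) atoms.  Common atoms must carry identical
    parameters in both endpoint states; vanishing-appearing pairs never
    interact.  Bonded terms involving vanishing (appearing) atoms belong to
    state A (B) and tether the dummy atoms while decoupled; their free-energy
    contribution is environment-independent and cancels in ddG.
    """

    system: TypedSystem
    vanishing: frozenset[int]
    appearing: frozenset[int]

    def __post_init__(self):
        self.vanishing = frozenset(int(i) for i in self.vanishing)
        self.appearing = frozenset(int(i) for i in self.appearing)
        if self.vanishing & self.appearing:
            raise FFError("vanishing and appearing sets must be disjoint")
        # vanishing-appearing pairs never see each other
        for i in self.vanishing:
            for j in self.appearing:
                self.system.exclusions.add(frozenset((i, j)))
        n = self.system.n
        self.common = frozenset(range(n)) - self.vanishing - self.appearing

    # -- endpoint (plain) topologies -------------------------------------
    def endpoint_indices(self, state: str) -> list[int]:
        drop = self.appearing if state == "A" else self.vanishing
        return [i for i in range(self.system.n) if i not in drop]

    def endpoint_system(self, state: str) -> TypedSystem:
        """Plain wild-type ('A') or mutant ('B') topology."""
        return self.system.subsystem(self.endpoint_indices(state))

    # -- per-stage active sets -------------------------------------------
    def _active(self, stage: str) -> np.ndarray:
        if stage == "decharge":
            keep = self.common | self.vanishing
        elif stage == "recharge":
            keep = self.common | self.appearing
        else:
            keep = self.common | self.vanishing | self.appearing
        mask = np.zeros(self.system.n, dtype=bool)
        mask[list(keep)] = True
        return mask

    def _stage_cache(self, stage: str) -> dict:
        """Lambda-independent pair data for a stage (computed once)."""
        cache = getattr(self, "_cache", None)
        if cache is None:
            cache = self._cache = {}
        if stage not in cache:
            sys_ = self.system
            active = self._active(stage)
            iu, ju = sys_.pair_mask()
            keep = active[iu] & active[ju]
            iu, ju = iu[keep], ju[keep]
            van = np.zeros(sys_.n, dtype=bool)
            van[list(self.vanishing)] = True
            app = np.zeros(sys_.n, dtype=bool)
            app[list(self.appearing)] = True
            bonded = [
                t for t in sys_.bonds + sys_.restraints
                if active[t[0]] and active[t[1]]
            ]
            angles = [
                t for t in sys_.angles if active[t[0]] and active[t[1]] and active[t[2]]
            ]
            cache[stage] = {
                "active": active,
                "iu": iu,
                "ju": ju,
                "eps": np.sqrt(sys_.eps[iu] * sys_.eps[ju]),
                "sig": 0.5 * (sys_.sig[iu] + sys_.sig[ju]),
                "van": van,
                "app": app,
                "bonded": bonded,
                "angles": angles,
            }
        return cache[stage]


def coupled_potential(
    coords: np.ndarray,
    topo: AlchemicalTopology,
    state: AlchemicalState,
    sc: SoftcoreParams = SoftcoreParams(),
) -> tuple[float, float]:
    """(U, dU/dlambda) of the staged coupled potential at ``coords``.

    Endpoint identities: decharge at lambda=0 equals the plain state-A
    energy; recharge at lambda=1 equals the plain state-B energy.
    """
    sys_ = topo.system
    coords = np.asarray(coords, float)
    lam = state.lam
    cache = topo._stage_cache(state.stage)

    # bonded terms among active atoms only (state-A bonds in decharge,
    # state-B bonds in recharge, both in vdw)
    e_bond = 0.0
    for i, j, k, r0 in cache["bonded"]:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e_bond += k * (r - r0) ** 2
    for i, j, kk, kth, th0 in cache["angles"]:
        v1 = coords[i] - coords[j]
        v2 = coords[kk] - coords[j]
        cos = np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
        e_bond += kth * (np.arccos(cos) - np.radians(th0)) ** 2

    iu, ju = cache["iu"], cache["ju"]
    d = coords[iu] - coords[ju]
    r = np.linalg.norm(d, axis=1)
    in_cut = r < sys_.ff.nonbonded_cutoff
    iu, ju, r = iu[in_cut], ju[in_cut], r[in_cut]
    eps = cache["eps"][in_cut]
    sig = cache["sig"][in_cut]
    kfac = _coulomb_factor(sys_.ff, r)
    van, app = cache["van"], cache["app"]

    if state.stage in ("decharge", "recharge"):
        # plain LJ among active atoms
        x = (sig / r) ** 6
        e_lj = float(np.sum(4.0 * eps * (x * x - x)))
        q = sys_.charge.copy()
        dq = np.zeros_like(q)
        if state.stage == "decharge":
            q[van.nonzero()[0]] *= (1.0 - lam)
            dq[van.nonzero()[0]] = -sys_.charge[van.nonzero()[0]]
        else:
            q[app.nonzero()[0]] *= lam
            dq[app.nonzero()[0]] = sys_.charge[app.nonzero()[0]]
        e_coul = float(np.sum(q[iu] * q[ju] * kfac))
        # d/dlam of bilinear form q_i q_j
        dU = float(np.sum((dq[iu] * q[ju] + q[iu] * dq[ju]) * kfac))
        return e_bond + e_lj + e_coul, dU

    # vdw stage: softcore LJ with per-atom couplings, mutating charges zero
    c_atom = np.ones(sys_.n)
    c_atom[van] = 1.0 - lam
    c_atom[app] = lam
    dc_atom = np.zeros(sys_.n)
    dc_atom[van] = -1.0
    dc_atom[app] = 1.0

    c_pair = c_atom[iu] * c_atom[ju]
    dc_pair = dc_atom[iu] * c_atom[ju] + c_atom[iu] * dc_atom[ju]

    full = c_pair >= 1.0 - 1e-15
    e_lj = 0.0
    dU = 0.0
    if np.any(full):
        x = (sig[full] / r[full]) ** 6
        e_lj += float(np.sum(4.0 * eps[full] * (x * x - x)))
        # fully coupled pairs may still have dc != 0 only if both atoms common
        # (never the case); no derivative contribution
    soft = ~full
    if np.any(soft):
        v, dv_dc = _softcore_and_dcoupling(
            r[soft], c_pair[soft], eps[soft], sig[soft], sc.alpha
        )
        e_lj += float(np.sum(v))
        dU += float(np.sum(dv_dc * dc_pair[soft]))

    q = sys_.charge.copy()
    q[van | app] = 0.0
    e_coul = float(np.sum(q[iu] * q[ju] * kfac))
    return e_bond + e_lj + e_coul, dU


def make_energy_fn(sys_: TypedSystem):
    """Plain potential as a coords -> float callable (for the sampler)."""

    def fn(coords: np.ndarray) -> float:
        return energy(sys_, coords).total

    return fn


def make_coupled_fn(topo: AlchemicalTopology, state: AlchemicalState,
                    sc: SoftcoreParams = SoftcoreParams()):
    """U(coords) at a fixed alchemical state, plus the dU/dlambda observer."""

    def u(coords: np.ndarray) -> float:
        return coupled_potential(coords, topo, state, sc)[0]

    def dudl(coords: np.ndarray) -> float:
        return coupled_potential(coords, topo, state, sc)[1]

    return u, dudl


# ---------------------------------------------------------------------------
# force-field parameter files
# ---------------------------------------------------------------------------

def load_forcefield(path) -> ForceField:
    """Read the plain-text line-oriented force-field format.

    Records::

        type KEY eps SIGMA CHARGE FORMAL HYDRO SIZE DONOR ACCEPTOR
        bond T1 T2 K R0
        option cutoff 12.0
        option dielectric_model constant
        option dielectric 1.0
    """
    ff = ForceField()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            try:
                if tok[0] == "type":
                    ff.atom_types[tok[1]] = AtomType(
                        key=tok[1],
                        epsilon=float(tok[2]),
                        sigma=float(tok[3]),
                        charge=float(tok[4]),
                        formal_charge=int(tok[5]),
                        hydro_class=tok[6],
                        size_class=tok[7],
                        hb_donor=bool(int(tok[8])),
                        hb_acceptor=bool(int(tok[9])),
                    )
                elif tok[0] == "bond":
                    ff.bond_params[frozenset((tok[1], tok[2]))] = (float(tok[3]), float(tok[4]))
                elif tok[0] == "option":
                    if tok[1] == "cutoff":
                        ff.nonbonded_cutoff = float(tok[2])
                    elif tok[1] == "dielectric_model":
                        ff.dielectric_model = tok[2]
                    elif tok[1] == "dielectric":
                        ff.dielectric = float(tok[2])
                    elif tok[1] == "coulomb_constant":
                        ff.coulomb_constant = float(tok[2])
                else:
                    raise ValueError(f"unknown record {tok[0]!r}")
            except (IndexError, ValueError) as exc:
                raise FFError(f"{path} line {lineno}: {exc}") from exc
    return ff
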