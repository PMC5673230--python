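"""Automated curation filters and interaction-geometry detectors.

These filters encode, as reproducible geometric rules, the screening that a
structural modeller performs by eye on mutation candidates before committing
to expensive free-energy calculations: large hydrophobic mutations whose
side chain never approaches the target are discarded, and glycine/alanine
candidates are flagged (scan scoring functions tend to favour them simply
because removing a side chain removes clashes).

Hydrogen bonds use a donor-acceptor heavy-atom distance plus (when an H is
present) a D-H...A angle criterion; salt bridges pair opposite formal
charges within a distance cap.  The geometric thresholds (3.5 A / 120 deg,
4.0 A) are standard structural-biology conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Structure, StructureError
from .mutscan import ResidueLibrary, BACKBONE

__all__ = [
    "CurationConfig",
    "Candidate",
    "CurationReport",
    "HBond",
    "SaltBridge",
    "detect_hbonds",
    "detect_salt_bridges",
    "curate",
]


@dataclass(frozen=True)
class CurationConfig:
    contact_cutoff: float = 5.0    # Angstrom
    hbond_da_max: float = 3.5
    hbond_angle_min: float = 120.0  # degrees
    saltbridge_max: float = 4.0
    auto_remove: frozenset = frozenset({"no_contact_large_hydrophobic", "gly_ala_flag"})

    def __post_init__(self):
        for v in (self.contact_cutoff, self.hbond_da_max, self.saltbridge_max):
            if v <= 0:
                raise ValueError("curation distances must be > 0")


@dataclass
class Candidate:
    position: tuple[str, int]      # (chain, resseq)
    code: str                      # mutant residue code
    delta_score: float
    structure: Structure | None    # built mutant structure


@dataclass
class CurationReport:
    kept: list[Candidate]
    removed: list[tuple[Candidate, str]]
    removal_fraction: float        # percent

    def __post_init__(self):
        n = len(self.kept) + len(self.removed)
        expect = 100.0 * len(self.removed) / n if n else 0.0
        if abs(self.removal_fraction - expect) > 1e-9:
            raise ValueError("inconsistent removal fraction")


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str]     # (chain, resseq, atom)
    acceptor: tuple[str, int, str]
    distance: float
    angle: float | None             # None when no H present


@dataclass(frozen=True)
class SaltBridge:
    positive: tuple[str, int, str]
    negative: tuple[str, int, str]
    distance: float


def _typed_atoms(s: Structure, ff, lib: ResidueLibrary, model: int = 0):
    tmap = lib.type_map()
    out = []
    for r in s.residues(model):
        for a in r.atoms:
            key = tmap.get((r.name3, a.name)) or tmap.get(a.name) or a.name
            if key in ff.atom_types:
                out.append((r, a, ff.atom_types[key]))
    return out


def detect_hbonds(s: Structure, ff, lib: ResidueLibrary,
                  cfg: CurationConfig = CurationConfig(), model: int = 0) -> list[HBond]:
    """Donor-acceptor contacts: heavy-atom D-A distance <= hbond_da_max and,
    when a hydrogen on the donor is present, D-H...A angle >= hbond_angle_min."""
    atoms = _typed_atoms(s, ff, lib, model)
    donors = [(r, a) for r, a, t in atoms if t.hb_donor and a.is_heavy]
    acceptors = [(r, a) for r, a, t in atoms if t.hb_acceptor and a.is_heavy]
    out = []
    for rd, d in donors:
        hydros = [
            h for h in rd.atoms
            if not h.is_heavy and np.linalg.norm(h.coords - d.coords) < 1.3
        ]
        for ra, acc in acceptors:
            if rd.key == ra.key and d.name == acc.name:
                continue
            if rd.key == ra.key:
                continue  # intra-residue contacts are not hydrogen bonds here
            dist = float(np.linalg.norm(d.coords - acc.coords))
            if dist > cfg.hbond_da_max:
                continue
            angle = None
            if hydros:
                h = min(hydros, key=lambda h: np.linalg.norm(h.coords - d.coords))
                v1 = d.coords - h.coords
                v2 = acc.coords - h.coords
                cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cos, -1, 1))))
                if angle < cfg.hbond_angle_min:
                    continue
            out.append(HBond(
                donor=(rd.chain_id, rd.resseq, d.name),
                acceptor=(ra.chain_id, ra.resseq, acc.name),
                distance=dist, angle=angle,
            ))
    return out


def detect_salt_bridges(s: Structure, ff, lib: ResidueLibrary,
                        cfg: CurationConfig = CurationConfig(),
                        model: int = 0) -> list[SaltBridge]:
    """Opposite-formal-charge N/O pairs within saltbridge_max."""
    atoms = _typed_atoms(s, ff, lib, model)
    charged = [
        (r, a, t.formal_charge) for r, a, t in atoms
        if t.formal_charge != 0 and a.is_heavy
    ]
    out = []
    for i, (r1, a1, q1) in enumerate(charged):
        for r2, a2, q2 in charged[i + 1:]:
            if q1 * q2 >= 0 or r1.key == r2.key:
                continue
            dist = float(np.linalg.norm(a1.coords - a2.coords))
            if dist <= cfg.saltbridge_max:
                pos, neg = ((r1, a1), (r2, a2)) if q1 > 0 else ((r2, a2), (r1, a1))
                out.append(SaltBridge(
                    positive=(pos[0].chain_id, pos[0].resseq, pos[1].name),
                    negative=(neg[0].chain_id, neg[0].resseq, neg[1].name),
                    distance=dist,
                ))
    return out


def curate(
    candidates: list[Candidate],
    lib: ResidueLibrary,
    target_chains,
    cfg: CurationConfig = CurationConfig(),
) -> CurationReport:
    """Apply the automated removal rules.  Each removal records exactly one
    primary reason code; rules are checked in a fixed order
    (gly_ala_flag first, then no_contact_large_hydrophobic)."""
    targets = set(target_chains)
    kept: list[Candidate] = []
    removed: list[tuple[Candidate, str]] = []
    for cand in candidates:
        if cand.structure is None:
            raise StructureError(f"candidate {cand.position}->{cand.code} has no structure")
        reason = None
        if "gly_ala_flag" in cfg.auto_remove and cand.code in ("GLY", "ALA"):
            reason = "gly_ala_flag"
        elif "no_contact_large_hydrophobic" in cfg.auto_remove:
            tmpl = lib.template(cand.code)
            if tmpl.size_class == "large" and tmpl.hydro_class == "hydrophobic":
                if _min_sidechain_distance(cand, targets) >= cfg.contact_cutoff:
                    reason = "no_contact_large_hydrophobic"
        if reason is None:
            kept.append(cand)
        else:
            removed.append((cand, reason))
    n = len(candidates)
    frac = 100.0 * len(removed) / n if n else 0.0
    return CurationReport(kept=kept, removed=removed, removal_fraction=frac)


def _min_sidechain_distance(cand: Candidate, targets: set) -> float:
    s = cand.structure
    chain, resseq = cand.position
    side = []
    tgt = []
    for r in s.residues(0):
        if (r.chain_id, r.resseq) == (chain, resseq):
            side.extend(a.coords for a in r.heavy_atoms() if a.name not in BACKBONE)
        elif r.chain_id in targets:
            tgt.extend(a.coords for a in r.heavy_atoms())
    if not side or not tgt:
        return np.inf
    side, tgt = np.array(side), np.array(tgt)
    return float(np.min(np.linalg.norm(side[:, None, :] - tgt[None, :, :], axis=-1)))
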