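"""Rotamer-based interface mutation scanning over a backbone ensemble.

Side chains are rebuilt from internal-coordinate residue templates (NeRF
chain extension) on the existing backbone; requesting D chirality negates
every side-chain dihedral, producing the mirror geometry.  Rotamers come
from a backbone-independent library of chi means and standard deviations;
the optional expansion adds variants at +/- 2 sigma around each mean chi
(3^k variants per base rotamer for k chi angles).

Repacking is an iterated stochastic descent over discrete rotamer
assignments (random restarts + greedy sweeps); on small instances it matches
exhaustive enumeration.  The scan mutates every interface position to every
alphabet code on every backbone, repacks all interface side chains, and
scores the interface; Delta-score = mutant - native on the same backbone,
aggregated as mean +/- sd over repeats.  Per (position, code) both the mean
over backbones and the best (lowest) backbone value are recorded; the best
value is the ranking statistic, since a single conducive backbone suffices
for design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structio import Atom, Residue, Structure, StructureError, InterfaceSet
from . import ffmodel
from .ffmodel import ForceField, TypedSystem

__all__ = [
    "TemplateAtom",
    "ResidueTemplate",
    "Rotamer",
    "ResidueLibrary",
    "ScanEntry",
    "ScanResult",
    "LogoMatrix",
    "MutscanError",
    "load_library",
    "default_library",
    "place_atom",
    "build_sidechain",
    "mutate_residue",
    "expand_rotamers",
    "structure_system",
    "repack",
    "scan",
    "make_logo",
    "CAA_CODES",
    "NCAA_CODES",
]

BACKBONE = ("N", "CA", "C", "O")
BACKBONE_TYPES = {"N": "NBB", "CA": "CAB", "C": "CBB", "O": "OBB"}

CAA_CODES = [
    "GLY", "ALA", "SER", "CYS", "THR", "VAL", "LEU", "ILE", "MET", "PRO",
    "PHE", "TYR", "TRP", "HIS", "ASP", "GLU", "ASN", "GLN", "LYS", "ARG",
]
NCAA_CODES = ["DPP", "IGL", "004", "D4P", "NAL", "26P", "HSE", "DAB", "ALC", "ABA"]


class MutscanError(ValueError):
    pass


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    type_key: str
    bond_ref: str
    bond_len: float
    angle_ref: str
    angle: float          # degrees
    dih_ref: str
    dih: float | None     # fixed dihedral in degrees, or None if chi-driven
    chi_index: int = 0    # 1-based chi index when chi-driven
    chi_offset: float = 0.0


@dataclass
class ResidueTemplate:
    name3: str
    category: str          # CAA | NCAA
    hydro_class: str
    size_class: str
    atoms: list[TemplateAtom] = field(default_factory=list)
    chi_definitions: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def n_chi(self) -> int:
        return len(self.chi_definitions)

    def sidechain_names(self) -> list[str]:
        return [a.name for a in self.atoms]


@dataclass(frozen=True)
class Rotamer:
    chi_means: tuple[float, ...]
    chi_sigmas: tuple[float, ...]


@dataclass
class ResidueLibrary:
    """Residue templates plus their rotamer library."""

    templates: dict[str, ResidueTemplate]
    rotamers: dict[str, list[Rotamer]]
    expansion_mode: str = "none"   # none | 2sigma

    def template(self, code: str) -> ResidueTemplate:
        try:
            return self.templates[code]
        except KeyError:
            raise MutscanError(f"no template for residue code {code!r}") from None

    def type_map(self) -> dict:
        m: dict = dict(BACKBONE_TYPES)
        for tmpl in self.templates.values():
            for a in tmpl.atoms:
                m[(tmpl.name3, a.name)] = a.type_key
        return m


# ---------------------------------------------------------------------------
# template / rotamer file parsing
# ---------------------------------------------------------------------------

def _parse_dih(token: str) -> tuple[float | None, int, float]:
    if token.startswith("@"):
        body = token[1:]
        for sep in ("+", "-"):
            k = body.find(sep, 1)
            if k > 0:
                return None, int(body[:k]), float(body[k:])
        return None, int(body), 0.0
    return float(token), 0, 0.0


def load_library(residues_path, rotamers_path, expansion_mode: str = "none") -> ResidueLibrary:
    templates: dict[str, ResidueTemplate] = {}
    current: ResidueTemplate | None = None
    with open(residues_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] == "template":
                opts = dict(t.split("=", 1) for t in tok[2:])
                current = ResidueTemplate(
                    name3=tok[1],
                    category=opts.get("category", "CAA"),
                    hydro_class=opts.get("hydro", "polar"),
                    size_class=opts.get("size", "medium"),
                )
            elif tok[0] == "atom":
                assert current is not None, f"line {lineno}: atom outside template"
                # atom NAME TYPE bond REF LEN angle REF ANG dih REF DIH
                dih, chi_idx, chi_off = _parse_dih(tok[11])
                current.atoms.append(
                    TemplateAtom(
                        name=tok[1], type_key=tok[2],
                        bond_ref=tok[4], bond_len=float(tok[5]),
                        angle_ref=tok[7], angle=float(tok[8]),
                        dih_ref=tok[10], dih=dih,
                        chi_index=chi_idx, chi_offset=chi_off,
                    )
                )
            elif tok[0] == "chi":
                assert current is not None
                current.chi_definitions.append(tuple(tok[1:5]))
            elif tok[0] == "end":
                templates[current.name3] = current
                current = None
            else:
                raise MutscanError(f"{residues_path} line {lineno}: unknown record {tok[0]!r}")

    rotamers: dict[str, list[Rotamer]] = {}
    with open(rotamers_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] != "rot":
                raise MutscanError(f"{rotamers_path} line {lineno}: unknown record")
            vals = [float(t) for t in tok[2:]]
            means = tuple(vals[0::2])
            sigmas = tuple(vals[1::2])
            if any(s < 0 for s in sigmas):
                raise MutscanError(f"{rotamers_path} line {lineno}: negative sigma")
            rotamers.setdefault(tok[1], []).append(Rotamer(means, sigmas))
    # residues without chi angles carry a single null rotamer
    for code, tmpl in templates.items():
        if tmpl.n_chi == 0:
            rotamers.setdefault(code, [Rotamer((), ())])
        elif code in rotamers:
            for r in rotamers[code]:
                if len(r.chi_means) != tmpl.n_chi:
                    raise MutscanError(
                        f"rotamer for {code} has {len(r.chi_means)} chis, template defines {tmpl.n_chi}"
                    )
    return ResidueLibrary(templates=templates, rotamers=rotamers, expansion_mode=expansion_mode)


def default_library(expansion_mode: str = "none") -> ResidueLibrary:
    """The packaged template/rotamer set (20 CAAs + 10 NCAAs)."""
    base = resources.files("mirrorbind") / "data"
    return load_library(base / "residues.txt", base / "rotamers.txt", expansion_mode)


def default_forcefield() -> ForceField:
    base = resources.files("mirrorbind") / "data"
    return ffmodel.load_forcefield(base / "toyff.txt")


# ---------------------------------------------------------------------------
# side-chain construction (NeRF)
# ---------------------------------------------------------------------------

def place_atom(a, b, c, bond: float, angle_deg: float, dih_deg: float) -> np.ndarray:
    """Position of atom X given references A (bonded), B, C such that
    |X-A| = bond, angle(X,A,B) = angle_deg and torsion(X,A,B,C) = dih_deg."""
    a, b, c = (np.asarray(v, float) for v in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(dih_deg)
    ab = a - b
    ab /= np.linalg.norm(ab)
    cb = b - c
    n = np.cross(cb, ab)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        # B and C collinear with A: pick any perpendicular (dihedral undefined)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, ab)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(ab, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, ab)
    d = (
        -bond * np.cos(theta) * ab
        + bond * np.sin(theta) * np.cos(phi) * m
        + bond * np.sin(theta) * np.sin(phi) * n
    )
    return a + d


def build_sidechain(
    res: Residue,
    tmpl: ResidueTemplate,
    chis,
    chirality: str = "L",
) -> Residue:
    """Rebuild a residue's side chain from template internal coordinates on
    its existing backbone.  ``chis`` supplies one angle per template chi.
    Chirality D mirrors the side-chain geometry (all dihedrals negated)."""
    chis = list(chis)
    if len(chis) != tmpl.n_chi:
        raise MutscanError(
            f"{tmpl.name3}: expected {tmpl.n_chi} chi angles, got {len(chis)}"
        )
    for name in ("N", "CA", "C"):
        if res.atom(name) is None:
            raise MutscanError(f"missing backbone atom {name}")
    sign = -1.0 if chirality == "D" else 1.0

    pos: dict[str, np.ndarray] = {
        a.name: a.coords.copy() for a in res.atoms if a.name in BACKBONE
    }
    new_atoms = [a for a in res.atoms if a.name in BACKBONE]
    serial = max((a.serial for a in res.atoms), default=0)
    for ta in tmpl.atoms:
        if ta.dih is not None:
            dih = sign * ta.dih
        else:
            dih = sign * (chis[ta.chi_index - 1] + ta.chi_offset)
        for ref in (ta.bond_ref, ta.angle_ref, ta.dih_ref):
            if ref not in pos:
                raise MutscanError(f"{tmpl.name3}.{ta.name}: undefined reference atom {ref}")
        xyz = place_atom(
            pos[ta.bond_ref], pos[ta.angle_ref], pos[ta.dih_ref],
            ta.bond_len, ta.angle, dih,
        )
        pos[ta.name] = xyz
        serial += 1
        new_atoms.append(
            Atom(serial=serial, name=ta.name, element=ta.type_key[0], coords=xyz)
        )
    out = Residue(
        chain_id=res.chain_id, resseq=res.resseq, icode=res.icode,
        name3=tmpl.name3, atoms=new_atoms, chirality=chirality,
    )
    return out


def mutate_residue(
    s: Structure, position: tuple[str, int], code: str, lib: ResidueLibrary,
    chis=None, model: int = 0,
) -> Structure:
    """Replace the residue at (chain, resseq) with ``code`` built from its
    template (first base rotamer unless ``chis`` given), preserving the
    residue's chirality."""
    tmpl = lib.template(code)
    if chis is None:
        chis = lib.rotamers[code][0].chi_means
    out = s.copy()
    for i, r in enumerate(out.models[model]):
        if (r.chain_id, r.resseq) == tuple(position):
            chir = r.chirality if r.chirality in ("L", "D") else "L"
            out.models[model][i] = build_sidechain(r, tmpl, chis, chirality=chir)
            return out
    raise StructureError(f"position {position} not found")


# ---------------------------------------------------------------------------
# rotamer expansion
# ---------------------------------------------------------------------------

def expand_rotamers(lib: ResidueLibrary, code: str) -> list[tuple[float, ...]]:
    """Concrete chi-angle tuples for ``code``.  With 2-sigma expansion every
    base rotamer spawns the {-2s, 0, +2s} grid per chi (3^k variants)."""
    if code not in lib.rotamers:
        raise MutscanError(f"unknown residue code {code!r}")
    base = lib.rotamers[code]
    if lib.expansion_mode != "2sigma":
        return [r.chi_means for r in base]
    out: list[tuple[float, ...]] = []
    for r in base:
        if not r.chi_means:
            out.append(())
            continue
        grids = [(-2.0 * s, 0.0, 2.0 * s) for s in r.chi_sigmas]
        for offsets in itertools.product(*grids):
            out.append(tuple(m + o for m, o in zip(r.chi_means, offsets)))
    return out


# ---------------------------------------------------------------------------
# structure -> typed system
# ---------------------------------------------------------------------------

def structure_system(s: Structure, ff: ForceField, lib: ResidueLibrary,
                     model: int = 0) -> TypedSystem:
    """TypedSystem with bonds from backbone connectivity plus template
    side-chain connectivity; non-templated residues become isolated beads."""
    sys_ = ffmodel.system_from_structure(s, ff, type_map=lib.type_map(), model=model)
    index = {lab: i for i, lab in enumerate(sys_.labels)}
    bonds: list[tuple[int, int, float, float]] = []

    def add(la: str, lb: str, r0: float, k: float = 300.0):
        if la in index and lb in index:
            bonds.append((index[la], index[lb], k, r0))

    prev: Residue | None = None
    for r in s.residues(model):
        pre = f"{r.chain_id}:{r.resseq}:"
        if r.name3 in lib.templates:
            add(pre + "N", pre + "CA", 1.458)
            add(pre + "CA", pre + "C", 1.525)
            add(pre + "C", pre + "O", 1.231)
            for ta in lib.templates[r.name3].atoms:
                add(pre + ta.name, pre + ta.bond_ref, ta.bond_len)
            if prev is not None and prev.chain_id == r.chain_id:
                add(f"{prev.chain_id}:{prev.resseq}:C", pre + "N", 1.329)
        prev = r
    sys_.bonds = bonds
    sys_._rebuild_exclusions()
    return sys_


# ---------------------------------------------------------------------------
# repacking
# ---------------------------------------------------------------------------

def repack(
    s: Structure,
    ff: ForceField,
    positions,
    lib: ResidueLibrary,
    seed: int = 0,
    n_restarts: int = 8,
    objective: str = "total",
    model: int = 0,
) -> tuple[Structure, float]:
    """Iterated stochastic descent over discrete rotamer assignments at
    ``positions`` ((chain, resseq) pairs).  Ties break toward the lowest
    rotamer index, so results are deterministic given the seed."""
    positions = [tuple(p) for p in positions]
    if not positions:
        sys0 = structure_system(s, ff, lib, model=model)
        e = ffmodel.energy(sys0).total if objective == "total" else ffmodel.interface_score(sys0)
        return s, float(e)

    residues = {(r.chain_id, r.resseq): r for r in s.residues(model)}
    candidates: list[list[tuple[float, ...]]] = []
    for p in positions:
        if p not in residues:
            raise StructureError(f"position {p} not found")
        code = residues[p].name3
        if code not in lib.rotamers or code not in lib.templates:
            raise MutscanError(f"position {p}: residue {code} has no rotamers")
        candidates.append(expand_rotamers(lib, code))

    work = s.copy()
    model_res = {(r.chain_id, r.resseq): i for i, r in enumerate(work.models[model])}

    def set_rotamer(p, chis):
        i = model_res[p]
        r = work.models[model][i]
        chir = r.chirality if r.chirality in ("L", "D") else "L"
        work.models[model][i] = build_sidechain(
            r, lib.template(r.name3), chis, chirality=chir
        )

    def score() -> float:
        sys_ = structure_system(work, ff, lib, model=model)
        if objective == "interface":
            return ffmodel.interface_score(sys_)
        return ffmodel.energy(sys_).total

    rng = np.random.default_rng(seed)
    best_choice = None
    best_e = np.inf
    n_pos = len(positions)
    for restart in range(n_restarts):
        if restart == 0:
            choice = [0] * n_pos
        else:
            choice = [int(rng.integers(len(c))) for c in candidates]
        for pi, p in enumerate(positions):
            set_rotamer(p, candidates[pi][choice[pi]])
        current = score()
        improved = True
        while improved:
            improved = False
            order = rng.permutation(n_pos)
            for pi in order:
                p = positions[pi]
                best_local, best_ci = current, choice[pi]
                for ci, chis in enumerate(candidates[pi]):
                    if ci == choice[pi]:
                        continue
                    set_rotamer(p, chis)
                    e = score()
                    if e < best_local - 1e-12 or (
                        abs(e - best_local) <= 1e-12 and ci < best_ci
                    ):
                        best_local, best_ci = e, ci
                if best_ci != choice[pi]:
                    choice[pi] = best_ci
                    improved = True
                set_rotamer(p, candidates[pi][choice[pi]])
                current = best_local
        if current < best_e - 1e-12 or (
            best_choice is not None
            and abs(current - best_e) <= 1e-12
            and choice < best_choice
        ):
            best_e, best_choice = current, list(choice)

    for pi, p in enumerate(positions):
        set_rotamer(p, candidates[pi][best_choice[pi]])
    return work, float(best_e)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass
class ScanEntry:
    mean: float                 # mean Delta-score over repeats, averaged over backbones
    sd: float
    best: float                 # lowest per-backbone mean (ranking statistic)
    per_backbone: list[float]
    n: int


@dataclass
class ScanResult:
    entries: dict[tuple[int, str], ScanEntry]   # (resseq, code) -> entry
    chain_id: str
    alphabet: list[str]

    def positions(self) -> list[int]:
        return sorted({p for p, _ in self.entries})

    def ranking(self, position: int) -> list[tuple[str, float]]:
        rows = [(c, e.best) for (p, c), e in self.entries.items() if p == position]
        return sorted(rows, key=lambda t: t[1])


@dataclass
class LogoMatrix:
    columns: dict[int, dict[str, float]]   # position -> code -> height in [0, 1]


def scan(
    ensemble: list[Structure],
    interface: InterfaceSet,
    alphabet,
    ff: ForceField,
    lib: ResidueLibrary,
    n_repeats: int = 100,
    seed: int = 0,
    n_restarts: int = 4,
) -> ScanResult:
    """Mutate every interface position to every alphabet code on every
    backbone; repack all interface side chains; Delta-score = mutant
    interface score - native interface score on the same backbone/repeat."""
    if len(interface) == 0:
        raise MutscanError("empty interface")
    alphabet = list(alphabet)
    for code in alphabet:
        lib.template(code)
    positions = interface.positions
    chain = positions[0][0]

    per_bb: dict[tuple[int, str], list[float]] = {}
    all_reps: dict[tuple[int, str], list[float]] = {}
    seq = np.random.SeedSequence(seed)
    rep_seeds = seq.generate_state(n_repeats * (len(ensemble) + 1)).tolist()
    si = 0
    for b, backbone in enumerate(ensemble):
        native_scores = []
        nat_seeds = []
        for rep in range(n_repeats):
            rs = rep_seeds[si % len(rep_seeds)]
            si += 1
            nat_seeds.append(rs)
            _, e = repack(backbone, ff, positions, lib, seed=rs,
                          n_restarts=n_restarts, objective="interface")
            native_scores.append(e)
        for (c_id, resseq) in positions:
            for code in alphabet:
                deltas = []
                for rep in range(n_repeats):
                    mut = mutate_residue(backbone, (c_id, resseq), code, lib)
                    _, e = repack(mut, ff, positions, lib, seed=nat_seeds[rep],
                                  n_restarts=n_restarts, objective="interface")
                    deltas.append(e - native_scores[rep])
                key = (resseq, code)
                per_bb.setdefault(key, []).append(float(np.mean(deltas)))
                all_reps.setdefault(key, []).extend(deltas)

    entries = {}
    for key, bb_means in per_bb.items():
        reps = np.array(all_reps[key])
        entries[key] = ScanEntry(
            mean=float(np.mean(reps)),
            sd=float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0,
            best=float(np.min(bb_means)),
            per_backbone=[float(v) for v in bb_means],
            n=len(reps),
        )
    return ScanResult(entries=entries, chain_id=chain, alphabet=alphabet)


def make_logo(result: ScanResult, statistic: str = "best") -> LogoMatrix:
    """Logo heights: per position, |Delta-score| of the codes with negative
    Delta-score, normalised so the largest height in each column is 1.
    Positions with no negative Delta-score yield empty columns."""
    cols: dict[int, dict[str, float]] = {}
    for (pos, code), e in result.entries.items():
        v = getattr(e, statistic)
        cols.setdefault(pos, {})
        if v < 0:
            cols[pos][code] = abs(v)
    for pos, col in cols.items():
        if col:
            top = max(col.values())
            cols[pos] = {c: v / top for c, v in col.items()}
    return LogoMatrix(columns=cols)


def plot_logo(logo: LogoMatrix, path, title: str = "") -> None:
    """Render a simple stacked-letter logo (one column per position, letter
    height proportional to the normalised |Delta-score|)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    positions = sorted(logo.columns)
    fig, ax = plt.subplots(figsize=(max(2, 0.9 * len(positions)), 3))
    for xi, pos in enumerate(positions):
        base = 0.0
        for code, h in sorted(logo.columns[pos].items(), key=lambda kv: kv[1]):
            ax.text(xi, base + h / 2, code, ha="center", va="center",
                    fontsize=6 + 14 * h, alpha=0.9)
            base += h
    ax.set_xticks(range(len(positions)))
    ax.set_xticklabels([str(p) for p in positions])
    ax.set_ylim(0, max(1.0, max((sum(c.values()) for c in logo.columns.values()),
                                default=1.0)))
    ax.set_xlim(-0.5, max(0.5, len(positions) - 0.5))
    ax.set_xlabel("position")
    ax.set_ylabel("relative improvement")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def logo_vector(logo: LogoMatrix, position: int, alphabet) -> np.ndarray:
    """Column as a dense vector over ``alphabet`` (absent codes -> 0)."""
    col = logo.columns.get(position, {})
    return np.array([col.get(code, 0.0) for code in alphabet])
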