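"""Molecular structure I/O and chirality handling.

Structures are stored as a light hierarchy (Structure > model > Residue >
Atom) that carries the attributes the design pipeline needs: author (PDB)
residue numbering, per-residue chirality labels (L / D / achiral / unknown)
and a record class separating polymer, solvent, ion and hetero-ligand atoms.
PDB reading/writing is delegated to biotite; multi-model PDB files double as
the trajectory interchange format.

Chirality is assigned from the sign of the improper dihedral N-CA-C-CB:
values in (-180, 0) degrees are labelled L, values in (0, 180) are labelled
D.  Ideal L-alanine gives about -120 degrees under this convention.  Mirror
images are produced by reflecting coordinates through the xy-plane
(z -> -z), which flips the label L <-> D.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "InterfaceSet",
    "StructureError",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "prepare_complex",
    "mirror",
    "assign_chirality",
    "find_interface",
    "dihedral_angle",
]

SOLVENT_NAMES = {"HOH", "WAT", "DOD", "H2O", "SOL", "TIP", "TIP3"}
ION_NAMES = {
    "NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "BR", "IOD",
    "CS", "LI", "NI", "CD", "SO4", "PO4",
}


class StructureError(ValueError):
    """Raised for violated structural contracts (missing chains, ...)."""


class PDBParseError(StructureError):
    """Raised when a PDB file cannot be parsed; names the offending line."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    partial_charge: float | None = None
    record_class: str = "polymer"  # polymer | solvent | ion | heteroligand

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    resseq: int
    name3: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    chirality: str = "unknown"  # L | D | achiral | unknown

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(
                f"residue {self.name3} {self.chain_id}{self.resseq}: duplicate atom names"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)


@dataclass
class Structure:
    """Hierarchical molecular model; ``models`` holds one residue list per model."""

    models: list[list[Residue]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.metadata.setdefault("preparation_log", [])

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residues(self, model: int = 0) -> list[Residue]:
        return self.models[model]

    def chains(self, model: int = 0) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.models[model]:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def chain_ids(self, model: int = 0) -> list[str]:
        seen: list[str] = []
        for r in self.models[model]:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def log(self, message: str) -> None:
        self.metadata["preparation_log"].append(message)


@dataclass
class InterfaceSet:
    """Residues of the designed chain within ``cutoff`` of any target chain."""

    entries: list[tuple[str, int, float]]  # (chain_id, resseq, min heavy-atom distance)
    cutoff: float

    def __post_init__(self):
        keys = [(c, r) for c, r, _ in self.entries]
        if len(keys) != len(set(keys)):
            raise StructureError("duplicate interface entries")
        for c, r, d in self.entries:
            if not d < self.cutoff:
                raise StructureError(
                    f"interface entry {c}{r}: distance {d} not below cutoff {self.cutoff}"
                )

    @property
    def positions(self) -> list[tuple[str, int]]:
        return [(c, r) for c, r, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p4 - p3
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    v = b0 - np.dot(b0, axis) * axis
    w = b1 - np.dot(b1, axis) * axis
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(axis, v), w))
    return float(np.degrees(np.arctan2(y, x)))


def assign_chirality(res: Residue) -> str:
    """Chirality label from the improper dihedral N-CA-C-CB.

    Negative improper -> L, positive -> D; no CB (e.g. glycine) -> achiral;
    missing backbone atom or degenerate geometry -> unknown.
    """
    cb = res.atom("CB")
    if cb is None:
        if res.atom("CA") is not None:
            return "achiral"
        return "unknown"
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        return "unknown"
    try:
        ang = dihedral_angle(n.coords, ca.coords, c.coords, cb.coords)
    except (ZeroDivisionError, FloatingPointError):
        return "unknown"
    if not np.isfinite(ang) or abs(ang) < 1e-9 or abs(abs(ang) - 180.0) < 1e-9:
        return "unknown"
    return "L" if ang < 0 else "D"


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _classify(name3: str, hetero: bool) -> str:
    if name3.strip().upper() in SOLVENT_NAMES:
        return "solvent"
    if name3.strip().upper() in ION_NAMES:
        return "ion"
    if hetero:
        return "heteroligand"
    return "polymer"


def _validate_pdb_lines(path: Path) -> None:
    """Pre-check ATOM/HETATM coordinate fields so errors name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"line {lineno}: truncated coordinate record")
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise PDBParseError(
                            f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                        ) from None


def read_structure(path, strict: bool = True) -> Structure:
    """Read a PDB-dialect file into a :class:`Structure`.

    MODEL blocks become separate models; waters and ions are classified by
    ``record_class``.  With ``strict`` (default) malformed coordinate lines
    raise :class:`PDBParseError` naming the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise PDBParseError(f"{path}: empty file")
    if strict:
        _validate_pdb_lines(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises various parse errors
        raise PDBParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")

    models: list[list[Residue]] = []
    n_atoms = stack.array_length()
    for m in range(stack.stack_depth()):
        coords = stack.coord[m]
        residues: list[Residue] = []
        current: Residue | None = None
        for i in range(n_atoms):
            key = (
                str(stack.chain_id[i]),
                int(stack.res_id[i]),
                str(stack.ins_code[i]) if hasattr(stack, "ins_code") else "",
                str(stack.res_name[i]),
            )
            if current is None or key != current._build_key:  # type: ignore[attr-defined]
                current = Residue(
                    chain_id=key[0], resseq=key[1], icode=key[2], name3=key[3]
                )
                current._build_key = key  # type: ignore[attr-defined]
                residues.append(current)
            current.atoms.append(
                Atom(
                    serial=i + 1,
                    name=str(stack.atom_name[i]),
                    element=str(stack.element[i]) or str(stack.atom_name[i])[0],
                    coords=coords[i],
                    record_class=_classify(str(stack.res_name[i]), bool(stack.hetero[i])),
                )
            )
        for r in residues:
            del r._build_key  # type: ignore[attr-defined]
            r.chirality = assign_chirality(r)
        models.append(residues)
    return Structure(models=models, metadata={"source": str(path), "preparation_log": []})


def _to_atom_array(residues: list[Residue]) -> bst.AtomArray:
    n = sum(len(r.atoms) for r in residues)
    arr = bst.AtomArray(n)
    i = 0
    for r in residues:
        for a in r.atoms:
            arr.chain_id[i] = r.chain_id
            arr.res_id[i] = r.resseq
            arr.ins_code[i] = r.icode
            arr.res_name[i] = r.name3
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.hetero[i] = a.record_class != "polymer"
            arr.coord[i] = a.coords
            i += 1
    return arr


def write_structure(s: Structure, path) -> None:
    """Write a (possibly multi-model) Structure as PDB."""
    arrays = [_to_atom_array(model) for model in s.models]
    if len(arrays) == 1:
        obj = arrays[0]
    else:
        obj = bst.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(obj)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

def prepare_complex(
    s: Structure, keep_chains, drop_duplicate_ligand: bool = False
) -> Structure:
    """Strip solvent/ions, keep only ``keep_chains``, optionally deduplicate
    identical ligand chains (keeping the first copy).  All removals are
    recorded in the preparation log."""
    keep = set(keep_chains)
    if not keep:
        raise StructureError("keep_chains must be non-empty")
    present = set(s.chain_ids(0))
    missing = keep - present
    if missing:
        raise StructureError(f"keep_chains references absent chain(s): {sorted(missing)}")

    out = s.copy()
    for m, model in enumerate(out.models):
        kept: list[Residue] = []
        for r in model:
            if r.atoms and r.atoms[0].record_class in ("solvent", "ion"):
                out.log(f"model {m}: removed {r.atoms[0].record_class} {r.name3} {r.chain_id}{r.resseq}")
                continue
            if r.chain_id not in keep:
                out.log(f"model {m}: removed chain {r.chain_id} residue {r.name3}{r.resseq}")
                continue
            kept.append(r)
        out.models[m] = kept

    if drop_duplicate_ligand:
        # chains with identical residue-name sequences are duplicates; keep first
        sigs: dict[tuple, str] = {}
        drop: set[str] = set()
        for cid, residues in out.chains(0).items():
            sig = tuple(r.name3 for r in residues)
            if sig in sigs:
                drop.add(cid)
                out.log(f"removed duplicate ligand chain {cid} (same sequence as {sigs[sig]})")
            else:
                sigs[sig] = cid
        if drop:
            for m in range(out.n_models):
                out.models[m] = [r for r in out.models[m] if r.chain_id not in drop]
    return out


def mirror(s: Structure) -> Structure:
    """Mirror image: reflect all coordinates through the xy-plane (z -> -z)
    and flip chirality labels L <-> D.  Exact involution."""
    out = s.copy()
    flip = {"L": "D", "D": "L"}
    for model in out.models:
        for r in model:
            for a in r.atoms:
                a.coords = a.coords * np.array([1.0, 1.0, -1.0])
            r.chirality = flip.get(r.chirality, r.chirality)
    out.log("mirrored through xy-plane (z -> -z)")
    return out


# ---------------------------------------------------------------------------
# interface identification
# ---------------------------------------------------------------------------

def find_interface(
    ensemble: list[Structure],
    designed_chain: str,
    target_chains,
    cutoff: float = 5.0,
) -> InterfaceSet:
    """Designed-chain residues with any heavy atom strictly closer than
    ``cutoff`` to any target-chain heavy atom, in ANY ensemble member (or any
    model of a multi-model member).  Records the per-residue minimum distance
    over the whole ensemble."""
    if not ensemble:
        raise StructureError("empty ensemble")
    targets = set(target_chains)
    mind: dict[tuple[str, int], float] = {}
    for s in ensemble:
        for m in range(s.n_models):
            chains = s.chains(m)
            if designed_chain not in chains:
                raise StructureError(f"designed chain {designed_chain!r} absent")
            missing = targets - set(chains)
            if missing:
                raise StructureError(f"target chain(s) absent: {sorted(missing)}")
            tgt = np.array(
                [a.coords for c in targets for r in chains[c] for a in r.heavy_atoms()]
            )
            if tgt.size == 0:
                continue
            for r in chains[designed_chain]:
                pts = np.array([a.coords for a in r.heavy_atoms()])
                if pts.size == 0:
                    continue
                d = float(np.min(np.linalg.norm(pts[:, None, :] - tgt[None, :, :], axis=-1)))
                key = (r.chain_id, r.resseq)
                if key not in mind or d < mind[key]:
                    mind[key] = d
    entries = sorted(
        [(c, i, d) for (c, i), d in mind.items() if d < cutoff], key=lambda e: e[1]
    )
    return InterfaceSet(entries=entries, cutoff=cutoff)
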