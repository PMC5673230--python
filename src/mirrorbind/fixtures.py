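"""Packaged transcriptions of the published TI result tables.

Three TSV fixtures ship with the package: canonical-mutation TI results
(grouped into phage-display libraries 1-4), non-canonical-mutation TI
results (26 filled cells over 11 positions), and the double/triple
combination results.  ``load_tables`` validates file checksums and the
structural invariants before returning; ``query`` distinguishes absent cells
from zero values.

Signed zeros are preserved as printed: +0.0 and -0.0 are stored as such and
neither counts as a binding improvement (improvement requires value < 0,
which IEEE signed zeros never satisfy).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "PaperTables",
    "Combo",
    "FixtureIntegrityError",
    "load_tables",
    "query",
    "is_improvement",
]

_CHECKSUMS = {
    "table1.tsv": "3c527900ce560994505f16c5e0d8eb4e1733fc462bc80f098b48c248f021b44c",
    "table2.tsv": "8ff587e169e830ab0f4cf9438ec96609edd73092fef41e5f5178756817eae296",
    "table3.tsv": "42ccdb9c2e7f572c2920eb04aef3ead429e2c71a12732aab929e9cbddf1c81d7",
}

EXPECTED_TABLE2_CELLS = 26
EXPECTED_TABLE2_POSITIONS = 11


class FixtureIntegrityError(RuntimeError):
    pass


@dataclass(frozen=True)
class Combo:
    kind: str                      # double | triple
    index: int
    members: tuple[tuple[str, str], ...]   # (position label, code)
    value: float


@dataclass
class PaperTables:
    table1: dict[tuple[str, str], float]
    table1_natives: dict[str, str]
    table1_libraries: dict[str, int]
    table2: dict[tuple[str, str], float]
    table3: tuple[Combo, ...]

    def positions2(self) -> list[str]:
        seen: list[str] = []
        for pos, _ in self.table2:
            if pos not in seen:
                seen.append(pos)
        return seen


def is_improvement(value: float) -> bool:
    """Strictly negative binding energy change; signed zeros do not count."""
    return value < 0.0


def _read(name: str) -> pd.DataFrame:
    path = resources.files("mirrorbind") / "data" / name
    blob = path.read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(f"{name}: checksum mismatch ({digest})")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str)


def load_tables() -> PaperTables:
    """Load and validate the packaged result-table fixtures."""
    t1 = _read("table1.tsv")
    table1: dict[tuple[str, str], float] = {}
    natives: dict[str, str] = {}
    libraries: dict[str, int] = {}
    for _, row in t1.iterrows():
        pos, code, val = row["position"], row["code"], row["value"]
        libraries[pos] = int(row["library"])
        if val == "N":
            natives[pos] = code
        else:
            table1[(pos, code)] = float(val)

    t2 = _read("table2.tsv")
    table2 = {
        (row["position"], row["code"]): float(row["value"]) for _, row in t2.iterrows()
    }

    t3 = _read("table3.tsv")
    combos = []
    for _, row in t3.iterrows():
        members = tuple(
            tuple(part.split(":", 1)) for part in row["members"].split("+")
        )
        combos.append(
            Combo(kind=row["kind"], index=int(row["combo"]),
                  members=members, value=float(row["value"]))
        )

    # structural invariants
    if len(table2) != EXPECTED_TABLE2_CELLS:
        raise FixtureIntegrityError(
            f"table2 has {len(table2)} filled cells, expected {EXPECTED_TABLE2_CELLS}"
        )
    pos2 = {p for p, _ in table2}
    if len(pos2) != EXPECTED_TABLE2_POSITIONS:
        raise FixtureIntegrityError(
            f"table2 spans {len(pos2)} positions, expected {EXPECTED_TABLE2_POSITIONS}"
        )
    for v in list(table1.values()) + list(table2.values()):
        if not math.isfinite(v):
            raise FixtureIntegrityError("non-finite fixture value")
    for combo in combos:
        if combo.kind == "double":
            for member in combo.members:
                if member not in table2:
                    raise FixtureIntegrityError(
                        f"table3 double combo {combo.index} references {member}, absent from table2"
                    )
        if not math.isfinite(combo.value):
            raise FixtureIntegrityError("non-finite combo value")
    return PaperTables(
        table1=table1, table1_natives=natives, table1_libraries=libraries,
        table2=table2, table3=tuple(combos),
    )


def query(tables: PaperTables, position: str, code: str) -> float | None:
    """Exact cell lookup across both mutation tables; None for absent cells
    (distinct from stored zeros)."""
    if (position, code) in tables.table2:
        return tables.table2[(position, code)]
    if (position, code) in tables.table1:
        return tables.table1[(position, code)]
    return None
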