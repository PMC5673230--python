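"""Post-TI design logic: combination selection, additivity analysis,
elimination-funnel bookkeeping and logo-similarity benchmarking.

Mutations qualify for combination when their TI binding energy change is
better than -2.0 kcal/mol (strictly below the negated threshold); mutations
at the same position are mutually exclusive in combinations.  A combination
is sub-additive when its combined ddG is less favourable (greater) than the
sum of its members' single-mutation ddG values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "MutationRecord",
    "ComboRecord",
    "FunnelStage",
    "DesignerError",
    "select_for_combination",
    "enumerate_combinations",
    "additivity_report",
    "logo_similarity",
    "funnel_report",
]


class DesignerError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    position: int
    from_code: str
    to_code: str
    ddG: float           # kcal/mol, negative = improved binding
    source: str = "TI"   # scan | TI

    def __post_init__(self):
        if not math.isfinite(self.ddG):
            raise DesignerError("ddG must be finite")

    @property
    def label(self) -> str:
        return f"{self.from_code}{self.position}{self.to_code}"


@dataclass
class ComboRecord:
    members: tuple[MutationRecord, ...]
    ddG: float | None = None
    sum_of_singles: float | None = None
    subadditive: bool | None = None

    def __post_init__(self):
        positions = [m.position for m in self.members]
        if len(positions) != len(set(positions)):
            raise DesignerError("combination members must occupy distinct positions")

    @property
    def label(self) -> str:
        return "+".join(m.label for m in self.members)


def select_for_combination(
    records: list[MutationRecord], threshold: float = 2.0
) -> list[MutationRecord]:
    """Mutations whose negative energy change exceeds the threshold,
    i.e. ddG < -threshold (strict)."""
    return [r for r in records if r.ddG < -threshold]


def enumerate_combinations(selected: list[MutationRecord], order: int) -> list[ComboRecord]:
    """All size-``order`` subsets with pairwise distinct positions."""
    if order not in (2, 3):
        raise DesignerError("combination order must be 2 or 3")
    if not selected:
        raise DesignerError("no selected mutations to combine")
    out = []
    for combo in itertools.combinations(selected, order):
        positions = [m.position for m in combo]
        if len(set(positions)) == order:
            out.append(ComboRecord(members=combo))
    return out


def additivity_report(
    singles: list[MutationRecord], combos: list[ComboRecord]
) -> tuple[list[ComboRecord], dict]:
    """Annotate combos with the sum of their members' single-mutation ddG and
    the (strict) sub-additivity flag; return counts."""
    index = {(m.position, m.to_code): m.ddG for m in singles}
    annotated = []
    n_sub = 0
    for combo in combos:
        if combo.ddG is None:
            raise DesignerError(f"combo {combo.label} has no measured ddG")
        total = 0.0
        for m in combo.members:
            key = (m.position, m.to_code)
            if key not in index:
                raise DesignerError(f"combo member {m.label} missing from singles")
            total += index[key]
        sub = combo.ddG > total  # less negative than the sum -> sub-additive
        annotated.append(
            ComboRecord(members=combo.members, ddG=combo.ddG,
                        sum_of_singles=total, subadditive=sub)
        )
        n_sub += int(sub)
    counts = {"n_combos": len(combos), "n_subadditive": n_sub}
    return annotated, counts


def logo_similarity(predicted, experimental) -> float:
    """Pearson correlation between a predicted logo column and an
    experimental height vector over the same alphabet."""
    p = np.asarray(predicted, float)
    e = np.asarray(experimental, float)
    if p.shape != e.shape:
        raise DesignerError("vectors differ in length")
    if np.std(p) == 0 or np.std(e) == 0:
        raise DesignerError("Pearson correlation undefined for zero-variance input")
    r, _ = _scipy_stats.pearsonr(p, e)
    return float(r)


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_kept: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_kept


def funnel_report(stages: list[tuple[str, int, int]]) -> dict:
    """Elimination-funnel table from (name, n_in, n_kept) rows; checks
    conservation between consecutive stages."""
    rows = [FunnelStage(*s) for s in stages]
    for st in rows:
        if st.n_kept > st.n_in or st.n_kept < 0:
            raise DesignerError(f"stage {st.name}: kept+removed != input")
    for a, b in zip(rows, rows[1:]):
        if b.n_in != a.n_kept:
            raise DesignerError(
                f"stage {b.name}: input {b.n_in} != previous kept {a.n_kept}"
            )
    return {
        "stages": [
            {"stage": st.name, "in": st.n_in, "kept": st.n_kept, "removed": st.n_removed}
            for st in rows
        ],
        "total_removed": sum(st.n_removed for st in rows),
    }
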