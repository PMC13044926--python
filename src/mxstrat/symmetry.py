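"""Point-group and arithmetic-crystal-class algebra for strategy computation.

Strategies are computed for one of the 11 axial (proper rotation) point groups
1, 2, 3, 4, 6, 222, 32, 422, 622, 23 and 432.  Rotation operators act on Miller
indices hkl; the Laue group is obtained by adjoining the inversion (Friedel
operation), which none of the 11 groups contains, so the Laue order is always
twice the number of proper operators.

Because a Bravais lattice does not always determine the point group (a
hexagonal lattice is compatible with 3, 32, 6, 622 ...; point group 32 even
needs to know whether the twofold axes run along or between the cell axes),
symmetry is carried around as an *arithmetic crystal class*: point group +
centring + axis setting.  An indexing solution therefore maps to an ordered
list of candidate classes, and the class a strategy is computed for is chosen
by the "lowest symmetry above monoclinic" rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "PointGroup",
    "ArithmeticCrystalClass",
    "SymmetryCandidates",
    "point_group_operators",
    "get_point_group",
    "expand_equivalents",
    "select_strategy_symmetry",
    "POINT_GROUP_NAMES",
]

# Representative space group (rotation parts only) per point group/setting.
_PG_SPACEGROUP = {
    ("1", ""): "P 1",
    ("2", ""): "P 1 2 1",
    ("3", ""): "P 3",
    ("4", ""): "P 4",
    ("6", ""): "P 6",
    ("222", ""): "P 2 2 2",
    ("32", ""): "P 3 2 1",       # default arithmetic setting: 321
    ("32", "321"): "P 3 2 1",
    ("32", "312"): "P 3 1 2",
    ("422", ""): "P 4 2 2",
    ("622", ""): "P 6 2 2",
    ("23", ""): "P 2 3",
    ("432", ""): "P 4 3 2",
}

POINT_GROUP_NAMES = ("1", "2", "3", "4", "6", "222", "32", "422", "622", "23", "432")

_CRYSTAL_SYSTEM = {
    "1": "triclinic", "2": "monoclinic", "3": "trigonal", "4": "tetragonal",
    "6": "hexagonal", "222": "orthorhombic", "32": "trigonal",
    "422": "tetragonal", "622": "hexagonal", "23": "cubic", "432": "cubic",
}

# Ranking of crystal systems from low to high symmetry, used for tie-breaking
# in select_strategy_symmetry.
_SYSTEM_RANK = {
    "triclinic": 0, "monoclinic": 1, "orthorhombic": 2, "tetragonal": 3,
    "trigonal": 4, "hexagonal": 5, "cubic": 6,
}

_ALLOWED_CENTRING = {
    "triclinic": {"P"},
    "monoclinic": {"P", "A", "B", "C", "I"},
    "orthorhombic": {"P", "A", "B", "C", "I", "F"},
    "tetragonal": {"P", "I"},
    "trigonal": {"P", "R"},
    "hexagonal": {"P"},
    "cubic": {"P", "I", "F"},
}


@lru_cache(maxsize=None)
def _operators(name: str, setting: str) -> tuple[np.ndarray, ...]:
    key = (name, setting)
    if key not in _PG_SPACEGROUP:
        if name not in POINT_GROUP_NAMES:
            raise ValueError(
                f"unknown point group {name!r}; supported groups are "
                + ", ".join(POINT_GROUP_NAMES)
            )
        raise ValueError(f"unknown setting {setting!r} for point group {name}")
    sg = gemmi.SpaceGroup(_PG_SPACEGROUP[key])
    mats = set()
    for op in sg.operations():
        rot = np.asarray(op.rot, dtype=np.int64) // gemmi.Op.DEN
        # gemmi rotations act on column coordinate vectors; transposing gives
        # the action on Miller index columns.
        mats.add(tuple(map(tuple, rot.T)))
    ordered = sorted(mats)
    out = tuple(np.array(m, dtype=np.int64) for m in ordered)
    for m in out:
        m.setflags(write=False)
    return out


def point_group_operators(name: str, setting: str = "") -> tuple[np.ndarray, ...]:
    """Proper rotation operators of an axial point group, acting on hkl.

    Returned in a deterministic (lexicographic) order; the identity is always
    present and the set is closed under composition.
    """
    return _operators(name, setting)


@dataclass(frozen=True)
class PointGroup:
    """One of the 11 axial point groups, with its hkl rotation operators."""

    name: str
    setting: str = ""
    operators: tuple[np.ndarray, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "operators", point_group_operators(self.name, self.setting))

    @property
    def order(self) -> int:
        return len(self.operators)

    @property
    def laue_order(self) -> int:
        # none of the axial groups contains -1, so adjoining it doubles the order
        return 2 * len(self.operators)

    @property
    def crystal_system(self) -> str:
        return _CRYSTAL_SYSTEM[self.name]

    @property
    def principal_axis_order(self) -> int:
        return {"1": 1, "2": 2, "3": 3, "4": 4, "6": 6, "222": 2, "32": 3,
                "422": 4, "622": 6, "23": 3, "432": 4}[self.name]

    def laue_operators(self) -> tuple[np.ndarray, ...]:
        """Operators of the Laue group (proper rotations plus their negatives)."""
        ops = list(self.operators) + [-op for op in self.operators]
        return tuple(ops)


def get_point_group(name: str, setting: str = "") -> PointGroup:
    return PointGroup(name, setting)


@dataclass(frozen=True)
class ArithmeticCrystalClass:
    """Point group + centring + axis setting (e.g. 321 vs 312)."""

    point_group: PointGroup
    centring: str = "P"
    setting: str = ""

    def __post_init__(self) -> None:
        system = self.point_group.crystal_system
        if self.centring not in _ALLOWED_CENTRING[system]:
            raise ValueError(
                f"centring {self.centring!r} is not compatible with the "
                f"{system} system of point group {self.point_group.name}"
            )

    @classmethod
    def from_symbols(cls, point_group: str, centring: str = "P", setting: str = "") -> "ArithmeticCrystalClass":
        return cls(PointGroup(point_group, setting), centring, setting)


@dataclass(frozen=True)
class SymmetryCandidates:
    """Ordered list of arithmetic crystal classes compatible with one indexing."""

    classes: tuple[ArithmeticCrystalClass, ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("candidate list must be non-empty")

    @classmethod
    def from_records(cls, records: Iterable[dict | str]) -> "SymmetryCandidates":
        """Build from config records: {point_group, centring, setting} or bare symbols."""
        out = []
        for rec in records:
            if isinstance(rec, str):
                out.append(ArithmeticCrystalClass.from_symbols(rec))
            else:
                out.append(ArithmeticCrystalClass.from_symbols(
                    str(rec["point_group"]),
                    rec.get("centring", "P"),
                    rec.get("setting", ""),
                ))
        return cls(tuple(out))

    def __iter__(self):
        return iter(self.classes)

    def __len__(self) -> int:
        return len(self.classes)


def expand_equivalents(hkl: Sequence[int], pg: PointGroup, friedel: bool = True) -> set[tuple[int, int, int]]:
    """Orbit of a Miller index under the point group (plus Friedel mates).

    The orbit size always divides the Laue order (group-action orbit theorem).
    """
    h = np.asarray(hkl, dtype=np.int64)
    orbit = {tuple(int(x) for x in op @ h) for op in pg.operators}
    if friedel:
        orbit |= {(-a, -b, -c) for a, b, c in orbit}
    return orbit


def select_strategy_symmetry(cands: SymmetryCandidates) -> ArithmeticCrystalClass:
    """Choose the symmetry a strategy is computed for from an ambiguity list.

    The rule is to assume the lowest symmetry above monoclinic (e.g. 3 rather
    than 6, 32 or 622 on a hexagonal lattice): among candidates of trigonal
    symmetry or above -- more precisely with at least 3 proper operators --
    pick the one with the fewest operators, ranking by crystal system and then
    list position on ties.  If every candidate is triclinic or monoclinic the
    lowest-order candidate wins.
    """
    ranked = []
    for i, c in enumerate(cands):
        pg = c.point_group
        ranked.append((pg.order, _SYSTEM_RANK[pg.crystal_system], i, c))
    above = [r for r in ranked if r[0] >= 3]
    pool = above if above else ranked
    return min(pool, key=lambda r: r[:3])[3]
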