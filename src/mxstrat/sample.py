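"""Crystal description and seeded synthetic fixtures.

A :class:`CrystalSample` carries everything the strategy pipeline needs about
the sample: unit cell, symmetry candidates, the crystal-to-lab orientation
matrix at all-zero goniostat angles, thickness, relative radiation
sensitivity and the target resolution.  Indexing itself is out of scope --
the orientation matrix is supplied directly (in production it would come from
characterization images processed externally).

The fixture generator draws random cells in realistic macromolecular ranges
respecting the crystal-system constraints, and uniformly random orientations,
all from a single seed so that fixtures are exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .symmetry import ArithmeticCrystalClass, SymmetryCandidates, select_strategy_symmetry

__all__ = ["CrystalSample", "random_crystal", "CRYSTAL_SYSTEMS"]

CRYSTAL_SYSTEMS = ("triclinic", "monoclinic", "orthorhombic", "tetragonal",
                   "trigonal", "hexagonal", "cubic")

_SYSTEM_DEFAULT_PG = {
    "triclinic": "1", "monoclinic": "2", "orthorhombic": "222",
    "tetragonal": "4", "trigonal": "3", "hexagonal": "6", "cubic": "23",
}


@dataclass(frozen=True)
class CrystalSample:
    """Sample description used throughout the strategy pipeline."""

    cell: tuple[float, float, float, float, float, float]
    symmetry: SymmetryCandidates
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    thickness_um: float = 12.0
    sensitivity: float = 1.0
    target_resolution_A: float | None = None

    def __post_init__(self):
        if any(p <= 0 for p in self.cell):
            raise ValueError("cell parameters must be positive")
        if self.thickness_um <= 0 or self.sensitivity <= 0:
            raise ValueError("thickness and sensitivity must be positive")
        u = np.asarray(self.orientation, dtype=float)
        if u.shape != (3, 3) or not np.allclose(u @ u.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be a 3x3 rotation matrix")
        object.__setattr__(self, "orientation", u)

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    def reciprocal_matrix(self) -> np.ndarray:
        """Columns are the reciprocal cell vectors a*, b*, c* (1/A, crystal frame)."""
        orth = np.array(self.gemmi_cell.orth.mat.tolist())
        return np.linalg.inv(orth).T

    def strategy_class(self) -> ArithmeticCrystalClass:
        """Arithmetic crystal class the strategy is computed for."""
        return select_strategy_symmetry(self.symmetry)

    def with_target_resolution(self, d_min: float) -> "CrystalSample":
        return replace(self, target_resolution_A=d_min)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cell": list(self.cell),
            "symmetry": [
                {"point_group": c.point_group.name, "centring": c.centring,
                 "setting": c.setting}
                for c in self.symmetry
            ],
            "orientation": self.orientation.tolist(),
            "thickness_um": self.thickness_um,
            "sensitivity": self.sensitivity,
            "target_resolution_A": self.target_resolution_A,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CrystalSample":
        return cls(
            cell=tuple(data["cell"]),
            symmetry=SymmetryCandidates.from_records(data["symmetry"]),
            orientation=np.asarray(data.get("orientation", np.eye(3)), dtype=float),
            thickness_um=data.get("thickness_um", 12.0),
            sensitivity=data.get("sensitivity", 1.0),
            target_resolution_A=data.get("target_resolution_A"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CrystalSample":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _random_cell(system: str, rng: np.random.Generator) -> tuple[float, ...]:
    edge = lambda: float(rng.uniform(40.0, 90.0))
    if system == "triclinic":
        ang = lambda: float(rng.uniform(80.0, 100.0))
        return (edge(), edge(), edge(), ang(), ang(), ang())
    if system == "monoclinic":
        return (edge(), edge(), edge(), 90.0, float(rng.uniform(95.0, 115.0)), 90.0)
    if system == "orthorhombic":
        return (edge(), edge(), edge(), 90.0, 90.0, 90.0)
    if system == "tetragonal":
        a = edge()
        return (a, a, edge(), 90.0, 90.0, 90.0)
    if system in ("trigonal", "hexagonal"):
        a = edge()
        return (a, a, edge(), 90.0, 90.0, 120.0)
    if system == "cubic":
        a = edge()
        return (a, a, a, 90.0, 90.0, 90.0)
    raise ValueError(f"unknown crystal system {system!r}; choose from {CRYSTAL_SYSTEMS}")


def random_crystal(
    system: str = "triclinic",
    seed: int | np.random.Generator = 0,
    point_group: str | None = None,
    target_resolution_A: float | None = 2.0,
    thickness_um: float = 12.0,
    sensitivity: float = 1.0,
    cell_edge_range: tuple[float, float] | None = None,
) -> CrystalSample:
    """Seeded synthetic crystal: random cell for the system, uniform orientation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if system not in CRYSTAL_SYSTEMS:
        raise ValueError(f"unknown crystal system {system!r}; choose from {CRYSTAL_SYSTEMS}")
    cell = _random_cell(system, rng)
    if cell_edge_range is not None:
        lo, hi = cell_edge_range
        scale = rng.uniform(lo, hi) / max(cell[:3])
        cell = tuple(p * scale for p in cell[:3]) + cell[3:]
    pg = point_group or _SYSTEM_DEFAULT_PG[system]
    u = Rotation.random(rng=rng).as_matrix()
    return CrystalSample(
        cell=cell,
        symmetry=SymmetryCandidates.from_records([pg]),
        orientation=u,
        thickness_um=thickness_um,
        sensitivity=sensitivity,
        target_resolution_A=target_resolution_A,
    )
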