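"""Native data-collection strategy generation.

Strategies are built from sweeps: contiguous omega rotations at a fixed
goniostat (kappa, phi) setting.  The guiding ideas are

* the first sweep is a full 360 deg turn at the lowest reachable chi (best
  scaling anchor, least shadowing);
* later sweeps are 360 deg when shadow-free at their chi, otherwise 192 deg
  (slightly over a half turn, so the ends scale against each other), with
  every width an integer number of 4.8 deg processing batches;
* the sweep orientations and their symmetry images should tile the sphere of
  reflections as evenly as possible.  Vertices of semiregular polyhedra whose
  rotation group contains the crystal point group provide such tilings: a
  rhombicuboctahedron vertex for point group 23 (triangle triplets for 222
  and 4, the inter-triangle square for 3), a truncated cuboctahedron vertex
  for 432, truncated octahedron vertices for 32.  Point groups 1 and 2 use a
  four-orientation spread limited by the goniostat range, and the
  high-multiplicity groups 6, 422 and 622 a two-orientation compromise.

The crystal mounting fixes which rotation-axis orientations are reachable: a
goniostat tilting the axis by at most chi_max away from the mounted phi
direction reaches the fraction 1 - cos(chi_max) of all (unsigned) axis
directions, about 33% at chi_max = 48 deg.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (
    DetectorModel,
    GoniostatModel,
    chi_max_shadow_free,
    kappa_phi_for_axis,
    shadow_free_omega_range,
    two_theta_for_resolution,
    two_theta_max,
)
from .symmetry import PointGroup

__all__ = [
    "Sweep",
    "StrategyPlan",
    "characterization_strategy",
    "target_orientations",
    "fit_to_mounting",
    "assign_lengths",
    "basic_strategy",
    "advanced_strategy",
    "predicted_multiplicity",
    "accessible_fraction",
    "DEFAULT_BATCH_DEG",
]

DEFAULT_BATCH_DEG = 4.8

_SQ2 = np.sqrt(2.0)


@dataclass(frozen=True)
class Sweep:
    """One rotation sweep: goniostat setting, omega interval, beam settings."""

    axis_direction_crystal: tuple[float, float, float] = (1.0, 0.0, 0.0)
    kappa_deg: float = 0.0
    phi_deg: float = 0.0
    chi_deg: float = 0.0
    omega_start_deg: float = 0.0
    width_deg: float = 360.0
    image_width_deg: float = 0.1
    exposure_per_image_s: float = 0.01
    transmission: float = 1.0
    goniostat: GoniostatModel = field(default_factory=GoniostatModel)

    def __post_init__(self):
        if self.width_deg <= 0:
            raise ValueError("sweep width must be positive")
        if self.chi_deg > self.goniostat.chi_max_mech_deg + 1e-6:
            raise ValueError(
                f"chi = {self.chi_deg:.1f} deg exceeds the mechanical limit "
                f"{self.goniostat.chi_max_mech_deg:.1f} deg"
            )

    def setting_matrix(self, orientation: np.ndarray) -> np.ndarray:
        """Crystal-to-lab matrix at sweep omega = 0 (goniostat applied to U)."""
        from .geometry import GoniostatPose
        pose = GoniostatPose(kappa_deg=self.kappa_deg, phi_deg=self.phi_deg,
                             goniostat=self.goniostat)
        return pose.setting_rotation().as_matrix() @ np.asarray(orientation, dtype=float)

    @property
    def n_images(self) -> int:
        return int(round(self.width_deg / self.image_width_deg))

    def to_dict(self) -> dict:
        return {
            "axis_direction_crystal": list(self.axis_direction_crystal),
            "kappa_deg": self.kappa_deg, "phi_deg": self.phi_deg,
            "chi_deg": self.chi_deg, "omega_start_deg": self.omega_start_deg,
            "width_deg": self.width_deg, "image_width_deg": self.image_width_deg,
            "exposure_per_image_s": self.exposure_per_image_s,
            "transmission": self.transmission,
        }


@dataclass
class StrategyPlan:
    """Ordered sweeps plus headline numbers for the plan."""

    sweeps: list[Sweep]
    kind: str = "basic"  # basic | advanced | phasing | characterization
    point_group: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def total_length_deg(self) -> float:
        return float(sum(s.width_deg for s in self.sweeps))

    @property
    def recentring_count(self) -> int:
        settings = {(round(s.kappa_deg, 3), round(s.phi_deg, 3)) for s in self.sweeps}
        return max(len(settings) - 1, 0)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "point_group": self.point_group,
            "total_length_deg": self.total_length_deg,
            "recentring_count": self.recentring_count,
            "sweeps": [s.to_dict() for s in self.sweeps],
            "notes": self.notes,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def characterization_strategy(
    n_wedges: int = 5,
    images_per_wedge: int = 12,
    image_width_deg: float = 0.1,
    omega_span_deg: float = 180.0,
) -> StrategyPlan:
    """Small wedges spread over an omega range for robust pre-experiment indexing.

    Wedge starts are placed at equal spacing across the span, endpoints
    included (defaults: 5 wedges of 12 x 0.1 deg images at 0, 45, 90, 135 and
    180 deg).
    """
    starts = np.linspace(0.0, omega_span_deg, n_wedges) if n_wedges > 1 else [0.0]
    width = images_per_wedge * image_width_deg
    sweeps = [
        Sweep(omega_start_deg=float(s), width_deg=width, image_width_deg=image_width_deg)
        for s in starts
    ]
    return StrategyPlan(sweeps, kind="characterization")


# -- polyhedron-based target orientations ---------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _align_z_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +z to ``direction`` (shortest arc)."""
    d = _unit(direction)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if d[2] > 0 else Rotation.from_euler("x", 180, degrees=True).as_matrix()
    angle = np.arctan2(s, float(z @ d))
    return Rotation.from_rotvec(v / s * angle).as_matrix()


# Rotation taking the cube diagonal (1,1,1) to +z, used for the trigonal
# groups whose 3-fold axis is the crystal c axis.
_R_111_TO_Z = _align_z_to(np.array([1.0, 1.0, 1.0])).T


def _polar(polar_deg: float, azim_deg: float) -> np.ndarray:
    p, a = np.radians(polar_deg), np.radians(azim_deg)
    return np.array([np.sin(p) * np.cos(a), np.sin(p) * np.sin(a), np.cos(p)])


def target_orientations(point_group: str | PointGroup) -> tuple[list[np.ndarray], str]:
    """Preferred sweep rotation-axis directions (crystal frame) for a point group.

    Returns (unit vectors, polyhedron/scheme name).  The vectors are expressed
    in the conventional symmetry frame: principal axis along c (+z) for the
    axial groups (along b for point group 2), cube axes along a, b, c for 222
    and the cubic groups.
    """
    name = point_group.name if isinstance(point_group, PointGroup) else str(point_group)

    rco_vertex = _unit([1.0, 1.0, 1.0 + _SQ2])
    rco_triangle = [_unit([1, 1, 1 + _SQ2]), _unit([1, 1 + _SQ2, 1]), _unit([1 + _SQ2, 1, 1])]
    rco_square = [_unit([1, 1, 1 + _SQ2]), _unit([-1, 1, 1 + _SQ2]),
                  _unit([-1, -1, 1 + _SQ2]), _unit([1, -1, 1 + _SQ2])]
    tco_vertex = _unit([1.0, 1.0 + _SQ2, 1.0 + 2.0 * _SQ2])
    trunc_oct = [_unit([0, 1, 2]), _unit([2, 0, 1])]

    if name == "1":
        # goniostat-range-limited spread: a cap centre plus a 40 deg tripod
        vecs = [_polar(0, 0), _polar(40, 0), _polar(40, 120), _polar(40, 240)]
        return vecs, "cap-spread"
    if name == "2":
        # same spread, arranged around the unique b axis
        base = [_polar(55, 0), _polar(55, 90), _polar(55, 180), _polar(55, 270)]
        swap = Rotation.from_euler("x", -90, degrees=True).as_matrix()  # z -> y
        return [swap @ v for v in base], "cap-spread"
    if name == "3":
        # three-sweep variant (default): triangle around the 3-fold axis
        tri = [_R_111_TO_Z @ v for v in rco_triangle]
        return tri, "rhombicuboctahedron-triangle"
    if name == "3x4":
        return [_R_111_TO_Z @ v for v in rco_square], "rhombicuboctahedron-square"
    if name in ("222", "4"):
        return list(rco_triangle), "rhombicuboctahedron-triangle"
    if name == "23":
        return [rco_vertex], "rhombicuboctahedron-vertex"
    if name == "23x2":
        return [tco_vertex, _unit([1.0 + 2.0 * _SQ2, 1.0, 1.0 + _SQ2])], "truncated-cuboctahedron"
    if name == "432":
        return [tco_vertex], "truncated-cuboctahedron-vertex"
    if name == "32":
        return [_R_111_TO_Z @ v for v in trunc_oct], "truncated-octahedron"
    if name in ("6", "422", "622"):
        n = {"6": 6, "422": 4, "622": 6}[name]
        # two orientations splitting the azimuthal symmetry wedge
        return [_polar(50.0, 0.0), _polar(70.0, 180.0 / n)], "two-orientation"
    raise ValueError(f"no advanced-strategy targets for point group {name!r}")


_TABLE_SWEEP_COUNT = {"1": 4, "2": 4, "3": 3, "222": 3, "4": 3, "32": 2,
                      "6": 2, "422": 2, "622": 2, "23": 1, "432": 1}


# -- mounting fit ----------------------------------------------------------

def _axis_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between unsigned axis directions, folded into [0, 90] deg."""
    c = abs(float(np.clip(np.dot(u, v), -1.0, 1.0)))
    return float(np.degrees(np.arccos(c)))


@dataclass
class MountingFit:
    sweeps: list[Sweep]
    max_chi_deg: float
    fallback: bool
    spin_deg: float = 0.0


def fit_to_mounting(
    targets: Sequence[np.ndarray],
    orientation: np.ndarray,
    gonio: GoniostatModel,
    spin_axis: np.ndarray | None = None,
    spin_step_deg: float = 2.0,
) -> MountingFit:
    """Realize target axis orientations on the goniostat, minimizing max chi.

    The target set may be rigidly spun about ``spin_axis`` (a symmetry axis of
    the target scheme, crystal frame) without changing the tiling it
    generates; the spin angle minimizing the maximum required chi is found by
    grid search.  Targets that still exceed the mechanical chi limit are
    replaced by the nearest accessible direction on the chi_max cone (the
    documented fallback), with a warning.  Pairwise angles within the set are
    preserved exactly whenever no fallback substitution occurs.
    """
    u = np.asarray(orientation, dtype=float)
    mount = u.T @ np.array([1.0, 0.0, 0.0])  # mounted phi/omega axis, crystal frame

    def required_chis(spun):
        return [_axis_angle(t, mount) for t in spun]

    best = (np.inf, 0.0, list(map(_unit, targets)))
    if spin_axis is not None and len(targets) > 0:
        axis = _unit(spin_axis)
        for gamma in np.arange(0.0, 360.0, spin_step_deg):
            rot = Rotation.from_rotvec(axis * np.radians(gamma)).as_matrix()
            spun = [_unit(rot @ t) for t in targets]
            worst = max(required_chis(spun))
            if worst < best[0]:
                best = (worst, float(gamma), spun)
    else:
        spun = list(map(_unit, targets))
        best = (max(required_chis(spun)) if spun else 0.0, 0.0, spun)

    worst, spin, spun = best
    chi_limit = gonio.chi_max_mech_deg
    sweeps: list[Sweep] = []
    fallback = False
    for t in spun:
        chi_req = _axis_angle(t, mount)
        if chi_req > chi_limit + 1e-9:
            fallback = True
            # slerp the target towards the mount axis until it sits on the
            # accessible cone boundary
            m = mount if float(np.dot(t, mount)) >= 0 else -mount
            ang = np.radians(_axis_angle(t, m))
            lam = np.radians(chi_limit) / ang
            t = _unit(np.sin((1 - lam) * ang) / np.sin(ang) * m
                      + np.sin(lam * ang) / np.sin(ang) * t)
            chi_req = chi_limit
        kappa, phi, chi = kappa_phi_for_axis(t, u, gonio)
        sweeps.append(Sweep(axis_direction_crystal=tuple(t), kappa_deg=kappa,
                            phi_deg=phi, chi_deg=chi, goniostat=gonio))
    if fallback:
        warnings.warn(
            "some target orientations exceed the chi limit; nearest accessible "
            "directions substituted", stacklevel=2,
        )
    max_chi = max((s.chi_deg for s in sweeps), default=0.0)
    return MountingFit(sweeps=sweeps, max_chi_deg=max_chi, fallback=fallback,
                       spin_deg=spin)


def assign_lengths(
    sweeps: Sequence[Sweep],
    detector: DetectorModel,
    distance_mm: float,
    gonio: GoniostatModel | None = None,
    batch_deg: float = DEFAULT_BATCH_DEG,
) -> list[Sweep]:
    """Order sweeps by chi and assign widths and omega starts.

    The lowest-chi sweep comes first at 360 deg; later sweeps get 360 deg
    when a full turn at their chi is shadow-free for this detector setting,
    otherwise 192 deg started inside the widest shadow-free omega window.
    360 and 192 are both integer multiples of the 4.8 deg batch.
    """
    g = gonio or (sweeps[0].goniostat if sweeps else GoniostatModel())
    tth = two_theta_max(detector.narrowest_mm, distance_mm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi_free = chi_max_shadow_free(tth, g.cone_half_angle_deg)
    ordered = sorted(sweeps, key=lambda s: s.chi_deg)
    out = []
    for i, sw in enumerate(ordered):
        if i == 0 or sw.chi_deg <= chi_free + 1e-9:
            width = 360.0
            start = 0.0
        else:
            width = 40 * batch_deg  # 192 deg by default
            w_start, w_width = shadow_free_omega_range(
                [sw.kappa_deg], detector, distance_mm, g)
            start = w_start if w_width >= width else w_start
            if w_width < width:
                warnings.warn(
                    f"sweep at chi = {sw.chi_deg:.1f} deg: shadow-free window "
                    f"({w_width:.0f} deg) narrower than the sweep", stacklevel=2,
                )
        out.append(replace(sw, omega_start_deg=float(start), width_deg=float(width)))
    return out


# -- strategies ------------------------------------------------------------

def _symmetry_axes(pg: PointGroup) -> list[np.ndarray]:
    """Unit rotation-axis directions (crystal orthonormal frame) of the group.

    Derived from the hkl operators; adequate for the orthogonal-axis frames
    used here (the trigonal/hexagonal in-plane twofold axes are located via
    eigenvectors of the Cartesian operators is out of scope -- the principal
    axis dominates the reorientation rule).
    """
    axes = []
    if pg.name == "2":
        axes.append(np.array([0.0, 1.0, 0.0]))
    elif pg.name in ("3", "4", "6", "32", "422", "622"):
        axes.append(np.array([0.0, 0.0, 1.0]))
        if pg.name in ("32", "422", "622"):
            axes.append(np.array([1.0, 0.0, 0.0]))
            axes.append(np.array([0.0, 1.0, 0.0]))
    elif pg.name in ("222", "23", "432"):
        axes.extend([np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
                     np.array([0.0, 0.0, 1.0])])
        if pg.name in ("23", "432"):
            axes.append(_unit([1.0, 1.0, 1.0]))
    return axes


def basic_strategy(
    crystal,
    gonio: GoniostatModel | None = None,
    theta_max_deg: float | None = None,
    margin_deg: float = 2.0,
) -> StrategyPlan:
    """Single 360 deg sweep at the lowest chi that keeps cusps self-compensating.

    If the mounted rotation axis lies within theta_max of a unique symmetry
    axis, the cusp around the rotation axis would coincide with its own
    symmetry image and lose reflections irrecoverably, so the crystal is
    reoriented by the minimal chi that moves the axis theta_max (+ margin)
    away.  P1 has no compensating symmetry at all and needs two sweeps.
    """
    g = gonio or GoniostatModel()
    pg = crystal.strategy_class().point_group
    u = crystal.orientation
    mount = u.T @ np.array([1.0, 0.0, 0.0])
    if theta_max_deg is None:
        d = crystal.target_resolution_A
        theta_max_deg = two_theta_for_resolution(d) / 2.0 if d else 15.0

    notes = []
    if pg.name == "1":
        tilt = min(2.0 * theta_max_deg + margin_deg, g.chi_max_mech_deg)
        second = _tilt_away(mount, mount, tilt)
        sweeps = []
        for t in (mount, second):
            kappa, phi, chi = kappa_phi_for_axis(t, u, g)
            sweeps.append(Sweep(axis_direction_crystal=tuple(t), kappa_deg=kappa,
                                phi_deg=phi, chi_deg=chi, width_deg=360.0,
                                goniostat=g))
        notes.append("P1: two sweeps required to measure both cusps")
        return StrategyPlan(sweeps, kind="basic", point_group="1", notes=notes)

    axis_target = mount
    offending = [
        (a, _axis_angle(mount, a)) for a in _symmetry_axes(pg)
        if _axis_angle(mount, a) < theta_max_deg
    ]
    if offending:
        axis, gap = min(offending, key=lambda p: p[1])
        tilt = theta_max_deg + margin_deg - gap
        axis_target = _tilt_away(mount, axis, tilt)
        notes.append(
            f"rotation axis within theta_max of a symmetry axis "
            f"({gap:.1f} deg); reoriented by {tilt:.1f} deg"
        )
    kappa, phi, chi = kappa_phi_for_axis(axis_target, u, g)
    sweep = Sweep(axis_direction_crystal=tuple(_unit(axis_target)), kappa_deg=kappa,
                  phi_deg=phi, chi_deg=chi, width_deg=360.0, goniostat=g)
    return StrategyPlan([sweep], kind="basic", point_group=pg.name, notes=notes)


def _tilt_away(v: np.ndarray, away_from: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Rotate v by tilt_deg away from a direction (any perpendicular if aligned)."""
    a = _unit(away_from)
    if float(np.dot(v, a)) < 0:
        a = -a
    perp = v - float(np.dot(v, a)) * a
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(a, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(a, [0.0, 1.0, 0.0])
    perp = _unit(perp)
    rotvec = _unit(np.cross(a, perp)) * np.radians(tilt_deg)
    return Rotation.from_rotvec(rotvec).as_matrix() @ _unit(v)


def advanced_strategy(
    crystal,
    detector: DetectorModel,
    distance_mm: float,
    gonio: GoniostatModel | None = None,
    three_sweep_trigonal: bool = True,
    first_sweep_chi0: bool = False,
) -> StrategyPlan:
    """Multi-sweep native strategy from polyhedron target orientations.

    ``first_sweep_chi0`` trades orientation ideality for one fewer recentring
    by forcing the first sweep onto the mounted axis (chi = 0).
    """
    g = gonio or GoniostatModel()
    pg = crystal.strategy_class().point_group
    name = pg.name if (pg.name != "3" or three_sweep_trigonal) else "3x4"
    targets, scheme = target_orientations(name)
    spin_axis = {"2": np.array([0.0, 1.0, 0.0]), "1": None}.get(
        pg.name, np.array([0.0, 0.0, 1.0]))
    if pg.name in ("222", "23", "432"):
        spin_axis = None  # cube-axis alignment leaves no continuous freedom
    fit = fit_to_mounting(targets, crystal.orientation, g, spin_axis=spin_axis)
    sweeps = fit.sweeps
    if first_sweep_chi0 and sweeps:
        mount = crystal.orientation.T @ np.array([1.0, 0.0, 0.0])
        lowest = min(range(len(sweeps)), key=lambda i: sweeps[i].chi_deg)
        sweeps[lowest] = Sweep(axis_direction_crystal=tuple(mount), kappa_deg=0.0,
                               phi_deg=0.0, chi_deg=0.0, goniostat=g)
    plan_sweeps = assign_lengths(sweeps, detector, distance_mm, g)
    notes = [f"targets: {scheme}", f"max chi {fit.max_chi_deg:.1f} deg"]
    if fit.fallback:
        notes.append("fallback orientations used (preferred set unreachable)")
    return StrategyPlan(plan_sweeps, kind="advanced", point_group=pg.name, notes=notes)


def predicted_multiplicity(plan: StrategyPlan, point_group: str | PointGroup) -> float:
    """Maximum multiplicity implied by the strategy length.

    2 x Laue order x (effective length / 360), with 192 deg sweeps counted as
    the 180 deg they were prolonged from.
    """
    pg = point_group if isinstance(point_group, PointGroup) else PointGroup(point_group)
    eff = sum(180.0 if abs(s.width_deg - 192.0) < 1e-6 else s.width_deg
              for s in plan.sweeps)
    return 2.0 * pg.laue_order * eff / 360.0


def accessible_fraction(
    chi_max_deg: float = 48.0,
    n_samples: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo fraction of unsigned axis orientations within chi_max of a mount.

    Converges to the analytic value 1 - cos(chi_max): the two polar caps of
    half-angle chi_max cover that fraction of the sphere.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = rng.normal(size=(int(n_samples), 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    cosang = np.abs(v[:, 0])  # mount along x; unsigned axes fold the sign
    return float(np.mean(cosang >= np.cos(np.radians(chi_max_deg))))
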