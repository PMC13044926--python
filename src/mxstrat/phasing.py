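"""Building blocks for anomalous-phasing experiments.

Anomalous phasing lives or dies by the clean subtraction of Friedel/Bijvoet
mates, so the planner's concerns are: aligning an evenfold symmetry axis with
the rotation axis so that the mates h,k,l and h,k,-l land on the very same
image; minimum sweep lengths for full anomalous completeness (after Dauter's
classic analysis); filling the uncompensated cusp that an aligned sweep
leaves; interleaving wedges at omega and omega + 180 (and across wavelengths
for MAD) so compared reflections share irradiation history; and splitting a
half-turn sweep into two out-of-sequence parts that are each complete.

The planner deliberately exposes building blocks rather than one canonical
plan per point group: which blocks combine best depends on the mounted
orientation and the beamline's recentring cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import GoniostatModel, kappa_phi_for_axis
from .strategy import Sweep, _axis_angle, _unit
from .symmetry import PointGroup

__all__ = [
    "PhasingPlan",
    "AcquisitionSegment",
    "min_anomalous_sweep",
    "cusp_fill",
    "interleave_schedule",
    "split_sweep_for_completeness",
]

_SINGLE_AXIS_GROUPS = {"2": 2, "3": 3, "4": 4, "6": 6}
_MULTI_AXIS_GROUPS = {"222": 2, "32": 2, "422": 4, "622": 6, "23": 2, "432": 4}


@dataclass(frozen=True)
class AcquisitionSegment:
    """One contiguous block of images within an interleaved schedule."""

    omega_start_deg: float
    width_deg: float
    offset_deg: float  # 0 or 180: which half of the interleave pair
    wavelength: str | float | None = None


@dataclass
class PhasingPlan:
    """Alignment choice, sweeps, interleave schedule and cusp-filling sweeps."""

    alignment: Literal["aligned-evenfold", "aligned", "orthogonal-to-axis", "unaligned"]
    sweeps: list[Sweep] = field(default_factory=list)
    fill_sweeps: list[Sweep] = field(default_factory=list)
    segments: list[AcquisitionSegment] = field(default_factory=list)
    aligned_axis_order: int | None = None

    def __post_init__(self):
        if self.alignment == "aligned-evenfold":
            if self.aligned_axis_order is None or self.aligned_axis_order % 2:
                raise ValueError("aligned-evenfold requires an even axis order")


def min_anomalous_sweep(
    point_group: str | PointGroup,
    alignment: Literal["aligned", "orthogonal"],
    two_theta_max_deg: float,
    axis_order: int | None = None,
    dauter_monoclinic: bool = False,
) -> float:
    """Minimum sweep length (deg) for ~100% anomalous completeness.

    Summary of the Dauter minimum-range rules: P1 needs 180 + 2theta_max; a
    single-axis group needs 360/n aligned on its n-fold axis, or 90 +
    theta_max orthogonal to it; any other group needs 360/2n aligned on an
    n-fold axis (n even) or 90 orthogonal to a symmetry axis.  For the
    monoclinic orthogonal case Dauter's published value is 180 + 2theta_max;
    that value disagrees with the single-axis rule above (which this package
    follows) and is only returned when ``dauter_monoclinic`` is set.
    """
    pg = point_group if isinstance(point_group, PointGroup) else PointGroup(point_group)
    if two_theta_max_deg <= 0:
        raise ValueError("2 theta max must be positive")
    if pg.name == "1":
        return 180.0 + two_theta_max_deg

    if pg.name in _SINGLE_AXIS_GROUPS:
        n = _SINGLE_AXIS_GROUPS[pg.name]
        if alignment == "aligned":
            return 360.0 / n
        if pg.name == "2" and dauter_monoclinic:
            return 180.0 + two_theta_max_deg
        return 90.0 + two_theta_max_deg / 2.0

    if pg.name in _MULTI_AXIS_GROUPS:
        if alignment == "aligned":
            n = axis_order if axis_order is not None else pg.principal_axis_order
            if n % 2:
                even = sorted({o for o in (2, pg.principal_axis_order) if o % 2 == 0})
                raise ValueError(
                    f"aligned minimum-sweep rule needs an even axis order; "
                    f"point group {pg.name} offers {even or 'none'}"
                )
            return 360.0 / (2 * n)
        return 90.0
    raise ValueError(f"no minimum-sweep rule for point group {pg.name!r}")


def cusp_fill(
    main_sweep: Sweep,
    two_theta_max_deg: float,
    mode: Literal["basic", "extended", "pair"] = "basic",
    gonio: GoniostatModel | None = None,
    orientation: np.ndarray | None = None,
) -> list[Sweep]:
    """Auxiliary sweeps measuring the reflections lost in the main sweep's cusp.

    The fill orientation is taken as far from the main rotation axis as the
    goniostat allows (the cusp sits around that axis); when the mounting
    information is omitted, an orthogonal axis is assumed reachable.  Widths:
    ``basic`` one sweep of 180 + 2theta_max; ``extended`` 180 + 4theta_max;
    ``pair`` two sweeps of 2theta_max each, started 180 deg apart.
    """
    g = gonio or main_sweep.goniostat
    main_axis = _unit(main_sweep.axis_direction_crystal)
    if orientation is not None:
        mount = np.asarray(orientation, dtype=float).T @ np.array([1.0, 0.0, 0.0])
        # farthest accessible direction from the main axis: across the cap
        away = main_axis - 2.0 * float(np.dot(main_axis, _unit(mount))) * _unit(mount)
        target = _rotate_towards(_unit(mount), _unit(away) if np.linalg.norm(away) > 1e-9 else None,
                                 g.chi_max_mech_deg)
        if _axis_angle(target, main_axis) < 5.0:
            warnings.warn("no well-separated fill orientation accessible; "
                          "best-effort orientation used", stacklevel=2)
        kappa, phi, chi = kappa_phi_for_axis(target, orientation, g)
    else:
        target = _perpendicular(main_axis)
        kappa, phi, chi = 0.0, 0.0, 0.0
    base = Sweep(axis_direction_crystal=tuple(target), kappa_deg=kappa, phi_deg=phi,
                 chi_deg=chi, goniostat=g,
                 image_width_deg=main_sweep.image_width_deg,
                 exposure_per_image_s=main_sweep.exposure_per_image_s,
                 transmission=main_sweep.transmission)
    if mode == "basic":
        return [replace(base, omega_start_deg=0.0, width_deg=180.0 + two_theta_max_deg)]
    if mode == "extended":
        return [replace(base, omega_start_deg=0.0, width_deg=180.0 + 2.0 * two_theta_max_deg)]
    if mode == "pair":
        return [
            replace(base, omega_start_deg=0.0, width_deg=two_theta_max_deg),
            replace(base, omega_start_deg=180.0, width_deg=two_theta_max_deg),
        ]
    raise ValueError("mode must be 'basic', 'extended' or 'pair'")


def _perpendicular(v: np.ndarray) -> np.ndarray:
    p = np.cross(v, [0.0, 0.0, 1.0])
    if np.linalg.norm(p) < 1e-9:
        p = np.cross(v, [0.0, 1.0, 0.0])
    return _unit(p)


def _rotate_towards(start: np.ndarray, towards: np.ndarray | None, angle_deg: float) -> np.ndarray:
    if towards is None:
        towards = _perpendicular(start)
    axis = np.cross(start, towards)
    if np.linalg.norm(axis) < 1e-9:
        axis = _perpendicular(start)
    rot = Rotation.from_rotvec(_unit(axis) * np.radians(angle_deg))
    return _unit(rot.apply(start))


def interleave_schedule(
    sweep: Sweep,
    wedge_deg: float,
    wavelengths: Sequence[str | float] | None = None,
) -> list[AcquisitionSegment]:
    """Alternating wedges at omega and omega + 180 (crossed with wavelengths).

    The wedge width must divide the sweep width; each wavelength covers the
    sweep (and its 180 deg counterpart) exactly once, wedge by wedge, so that
    the Bijvoet mates compared are measured close in time from the same
    irradiated volume.
    """
    n = sweep.width_deg / wedge_deg
    if abs(n - round(n)) > 1e-9 or wedge_deg <= 0:
        raise ValueError(
            f"wedge width {wedge_deg} deg does not divide the sweep width "
            f"{sweep.width_deg} deg"
        )
    n = int(round(n))
    wls: list = list(wavelengths) if wavelengths else [None]
    segments = []
    for i in range(n):
        start = sweep.omega_start_deg + i * wedge_deg
        for wl in wls:
            for offset in (0.0, 180.0):
                segments.append(AcquisitionSegment(
                    omega_start_deg=start + offset, width_deg=wedge_deg,
                    offset_deg=offset, wavelength=wl))
    return segments


def split_sweep_for_completeness(
    sweep: Sweep,
    anchor_omega_deg: float | None = None,
) -> list[Sweep]:
    """Split a half-turn-class sweep into two parts acquired out of sequence.

    The split point is placed at the symmetry-anchor omega (e.g. where a
    symmetry axis crosses the equator of the Ewald sphere) so that each part
    individually reaches full completeness; the part starting at the anchor
    is acquired first.  Without an anchor the sweep splits at its midpoint.
    Returns the original sweep unchanged (with a warning) when the anchor
    lies outside the sweep.
    """
    start, width = sweep.omega_start_deg, sweep.width_deg
    if anchor_omega_deg is None:
        cut = start + width / 2.0
    else:
        rel = (anchor_omega_deg - start) % 360.0
        if rel >= width or rel == 0.0:
            if (anchor_omega_deg - start) % 360.0 == 0.0:
                cut = start + width / 2.0
            else:
                warnings.warn("anchor omega lies outside the sweep; not split",
                              stacklevel=2)
                return [sweep]
        else:
            cut = start + rel
    first = replace(sweep, omega_start_deg=cut, width_deg=start + width - cut)
    second = replace(sweep, omega_start_deg=start, width_deg=cut - start)
    return [first, second]
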