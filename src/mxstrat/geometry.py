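"""Detector and goniostat geometry.

Lab frame convention, used throughout the package:

* beam along **+z**, pointing from the crystal towards the detector;
* omega (main rotation) axis along **+x**, horizontal, perpendicular to the beam;
* detector plane perpendicular to the beam at distance ``D`` downstream.

The goniostat is a mini-kappa-style three-axis instrument: omega carries the
kappa axis (inclined by alpha to omega), which carries the phi axis holding
the sample mount.  Rotating kappa tilts the phi axis away from omega by

    cos(chi) = cos^2(alpha) + sin^2(alpha) cos(kappa),

so chi ranges from 0 at kappa = 0 to 2 alpha at kappa = 180 deg (48 deg for a
standard mini-kappa with alpha = 24 deg).

The dominant obstruction between crystal and detector is the phi-axis
mounting, modelled as an infinite cone of half-angle ``A`` (19.84 deg for a
mini-kappa) around the direction -phi_hat, apexed at the crystal.  A
diffracted ray is shadowed when it makes an angle smaller than ``A`` with
that direction.  For a centred detector this cone model has a closed-form
consequence: a full 360 deg omega sweep is shadow-free exactly when

    (90 - chi) - 2 theta_max >= A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DetectorModel",
    "GoniostatModel",
    "GoniostatPose",
    "two_theta_max",
    "resolution_limit",
    "two_theta_for_resolution",
    "chi_max_shadow_free",
    "chi_of_kappa",
    "kappa_for_chi",
    "kappa_phi_for_axis",
    "is_ray_shadowed",
    "shadow_fraction",
    "shadow_free_omega_range",
]

BEAM_AXIS = np.array([0.0, 0.0, 1.0])
OMEGA_AXIS = np.array([1.0, 0.0, 0.0])

_D2R = np.pi / 180.0


@dataclass(frozen=True)
class DetectorModel:
    """Flat pixel-array detector: active area, module/gap layout, distance limit.

    ``module_px``/``gap_px`` describe the tiling of the face into modules
    separated by inactive gap strips, as (nx, ny) pixel counts; ``None`` means
    a gap-free face.  The beam centre defaults to the face centre; coordinates
    on the face are measured in mm relative to the beam centre.
    """

    name: str
    width_mm: float
    height_mm: float
    pixel_mm: float = 0.172
    module_px: tuple[int, int] | None = None
    gap_px: tuple[int, int] | None = None
    min_distance_mm: float = 137.0
    beam_centre_mm: tuple[float, float] | None = None  # offset from face centre

    def __post_init__(self):
        if self.width_mm <= 0 or self.height_mm <= 0 or self.min_distance_mm <= 0:
            raise ValueError("detector dimensions and minimum distance must be positive")
        if self.module_px is not None:
            npx = self.n_pixels
            for dim, n_mod, gap, total in zip(
                (0, 1), self._n_modules(), self.gap_px, npx
            ):
                tiled = n_mod * self.module_px[dim] + (n_mod - 1) * gap
                if abs(tiled - total) > 1:  # 1 px slack for rounding width/pitch
                    raise ValueError(
                        f"module layout does not tile the detector face (axis {dim}: "
                        f"{tiled} px tiled vs {total} px total)"
                    )

    @property
    def n_pixels(self) -> tuple[int, int]:
        return (int(round(self.width_mm / self.pixel_mm)),
                int(round(self.height_mm / self.pixel_mm)))

    def _n_modules(self) -> tuple[int, int]:
        assert self.module_px is not None and self.gap_px is not None
        out = []
        for dim in (0, 1):
            period = self.module_px[dim] + self.gap_px[dim]
            out.append(max(1, int(round((self.n_pixels[dim] + self.gap_px[dim]) / period))))
        return tuple(out)

    @property
    def narrowest_mm(self) -> float:
        return min(self.width_mm, self.height_mm)

    def beam_centre_offset(self) -> np.ndarray:
        if self.beam_centre_mm is None:
            return np.zeros(2)
        return np.asarray(self.beam_centre_mm, dtype=float)

    def active_mask(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """True where a point (mm, relative to the beam centre) is on an active pixel."""
        off = self.beam_centre_offset()
        px = (np.asarray(x_mm) + off[0] + self.width_mm / 2.0) / self.pixel_mm
        py = (np.asarray(y_mm) + off[1] + self.height_mm / 2.0) / self.pixel_mm
        npx, npy = self.n_pixels
        on = (px >= 0) & (px < npx) & (py >= 0) & (py < npy)
        if self.module_px is None:
            return on
        act = on.copy()
        for p, dim in ((px, 0), (py, 1)):
            period = self.module_px[dim] + self.gap_px[dim]
            act &= np.mod(p, period) < self.module_px[dim]
        return act


@dataclass(frozen=True)
class GoniostatModel:
    """Multi-axis goniostat: kappa geometry, shadow cone, mechanical chi limit."""

    kind: str = "mini-kappa"
    cone_half_angle_deg: float = 19.84
    kappa_axis_angle_deg: float = 24.0
    chi_max_mech_deg: float = 48.0

    def __post_init__(self):
        if not 0.0 < self.cone_half_angle_deg < 90.0:
            raise ValueError("shadow cone half-angle must lie in (0, 90) deg")
        if not 0.0 < self.kappa_axis_angle_deg <= 90.0:
            raise ValueError("kappa-axis angle must lie in (0, 90] deg")
        if self.chi_max_mech_deg > 2.0 * self.kappa_axis_angle_deg + 1e-9:
            raise ValueError("mechanical chi limit cannot exceed 2 * kappa-axis angle")

    @property
    def kappa_axis(self) -> np.ndarray:
        a = self.kappa_axis_angle_deg * _D2R
        return np.array([np.cos(a), np.sin(a), 0.0])


@dataclass(frozen=True)
class GoniostatPose:
    """Goniostat axis settings plus the derived phi-axis direction in the lab."""

    omega_deg: float = 0.0
    kappa_deg: float = 0.0
    phi_deg: float = 0.0
    goniostat: GoniostatModel = field(default_factory=GoniostatModel)

    @property
    def chi_deg(self) -> float:
        return chi_of_kappa(self.kappa_deg, self.goniostat.kappa_axis_angle_deg)

    def kappa_rotation(self) -> Rotation:
        return Rotation.from_rotvec(self.goniostat.kappa_axis * self.kappa_deg * _D2R)

    def setting_rotation(self) -> Rotation:
        """Crystal-to-lab rotation contributed by the goniostat at this pose.

        Composition (outermost first): omega about +x, kappa about the kappa
        axis, phi about the phi rest direction (+x).
        """
        r_omega = Rotation.from_rotvec(OMEGA_AXIS * self.omega_deg * _D2R)
        r_phi = Rotation.from_rotvec(OMEGA_AXIS * self.phi_deg * _D2R)
        return r_omega * self.kappa_rotation() * r_phi

    @property
    def phi_axis_direction(self) -> np.ndarray:
        """Unit vector of the phi axis in the lab frame at this pose."""
        r_omega = Rotation.from_rotvec(OMEGA_AXIS * self.omega_deg * _D2R)
        return (r_omega * self.kappa_rotation()).apply(OMEGA_AXIS)

    @property
    def mount_direction(self) -> np.ndarray:
        """Direction from the crystal into the phi-axis mounting (shadow cone axis)."""
        return -self.phi_axis_direction


def two_theta_max(width_mm: float, distance_mm: float) -> float:
    """Largest diffraction angle (deg) landing on a centred detector.

    ``width_mm`` is the narrowest detector dimension; the limiting reflection
    exits at arctan(half-width / distance).
    """
    if width_mm < 0 or distance_mm <= 0:
        raise ValueError("detector width and distance must be positive")
    return float(np.degrees(np.arctan2(width_mm / 2.0, distance_mm)))


def resolution_limit(two_theta_deg: float, wavelength_A: float = 1.0) -> float:
    """Bragg resolution d = lambda / (2 sin theta) for a scattering angle 2 theta."""
    if not 0.0 < two_theta_deg <= 180.0:
        raise ValueError("2 theta must lie in (0, 180] deg")
    if wavelength_A <= 0:
        raise ValueError("wavelength must be positive")
    return float(wavelength_A / (2.0 * np.sin(np.radians(two_theta_deg) / 2.0)))


def two_theta_for_resolution(d_A: float, wavelength_A: float = 1.0) -> float:
    """Scattering angle 2 theta (deg) at which resolution d diffracts."""
    s = wavelength_A / (2.0 * d_A)
    if not 0.0 < s <= 1.0:
        raise ValueError("resolution out of range for this wavelength")
    return float(np.degrees(2.0 * np.arcsin(s)))


def chi_max_shadow_free(two_theta_max_deg: float, cone_half_angle_deg: float) -> float:
    """Highest chi permitting a shadow-free 360 deg sweep: 90 - A - 2theta_max.

    Negative values (detector too close / too wide) are clamped to 0 with a
    warning; the mechanical chi limit is applied by callers.
    """
    chi = 90.0 - cone_half_angle_deg - two_theta_max_deg
    if chi < 0.0:
        warnings.warn(
            "no chi allows a shadow-free 360 deg sweep at this detector setting",
            stacklevel=2,
        )
        return 0.0
    return chi


def chi_of_kappa(kappa_deg: float, alpha_deg: float) -> float:
    """Tilt chi of the phi axis away from omega for a kappa setting.

    cos chi = cos^2 alpha + sin^2 alpha cos kappa, evaluated in the
    numerically stable half-angle form sin(chi/2) = sin alpha |sin(kappa/2)|.
    """
    a = np.radians(alpha_deg)
    s = np.sin(a) * np.abs(np.sin(np.radians(kappa_deg) / 2.0))
    return float(np.degrees(2.0 * np.arcsin(np.clip(s, -1.0, 1.0))))


def kappa_for_chi(chi_deg: float, alpha_deg: float) -> float:
    """Kappa setting producing a requested chi tilt (inverse of chi_of_kappa)."""
    a = np.radians(alpha_deg)
    if chi_deg < 0 or chi_deg > 2 * alpha_deg + 1e-9:
        raise ValueError(f"chi = {chi_deg:.2f} deg unreachable (max {2*alpha_deg:.2f} deg)")
    num = np.cos(np.radians(chi_deg)) - np.cos(a) ** 2
    return float(np.degrees(np.arccos(np.clip(num / np.sin(a) ** 2, -1.0, 1.0))))


def kappa_phi_for_axis(
    axis_crystal: Sequence[float],
    orientation: np.ndarray,
    gonio: GoniostatModel,
) -> tuple[float, float, float]:
    """Goniostat (kappa, phi) that puts a crystal direction along the rotation axis.

    ``axis_crystal`` is the desired sweep rotation-axis direction expressed in
    the crystal frame (unsigned: the antiparallel direction is equivalent);
    ``orientation`` is the crystal-to-lab setting matrix at all-zero goniostat
    angles.  Returns (kappa_deg, phi_deg, chi_deg).  Raises when the required
    chi exceeds what the kappa axis can reach.

    Derivation: the achieved axis in the crystal frame is
    U^T Rphi(x, phi)^T Rkappa^T x_hat, whose polar angle about the mounted
    phi-axis direction U^T x_hat is chi(kappa) and whose azimuth is set by phi.
    """
    t = np.asarray(axis_crystal, dtype=float)
    t = t / np.linalg.norm(t)
    t_lab = np.asarray(orientation, dtype=float) @ t
    if t_lab[0] < 0:  # rotation axes are unsigned; fold into the +x hemisphere
        t_lab = -t_lab
    chi_req = float(np.degrees(np.arccos(np.clip(t_lab[0], -1.0, 1.0))))
    kappa = kappa_for_chi(chi_req, gonio.kappa_axis_angle_deg)
    pose = GoniostatPose(kappa_deg=kappa, goniostat=gonio)
    w = pose.kappa_rotation().inv().apply(OMEGA_AXIS)  # Rkappa^T x_hat
    az_w = np.arctan2(w[2], w[1])
    az_t = np.arctan2(t_lab[2], t_lab[1])
    phi = float(np.degrees(az_w - az_t)) % 360.0
    return kappa, phi, chi_req


def is_ray_shadowed(ray: Sequence[float], pose: GoniostatPose,
                    gonio: GoniostatModel | None = None) -> bool:
    """Whether a crystal-to-detector ray falls inside the phi-mount shadow cone."""
    g = gonio if gonio is not None else pose.goniostat
    r = np.asarray(ray, dtype=float)
    cosang = float(np.dot(r, pose.mount_direction))
    return cosang > np.cos(np.radians(g.cone_half_angle_deg))


def _detector_rays(det: DetectorModel, distance_mm: float, grid: int) -> np.ndarray:
    off = det.beam_centre_offset()
    xs = np.linspace(-det.width_mm / 2.0, det.width_mm / 2.0, grid) - off[0]
    ys = np.linspace(-det.height_mm / 2.0, det.height_mm / 2.0, grid) - off[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    rays = np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, distance_mm)], axis=1)
    return rays / np.linalg.norm(rays, axis=1, keepdims=True)


def shadow_fraction(pose: GoniostatPose, det: DetectorModel, distance_mm: float,
                    grid: int = 256) -> float:
    """Fraction of the detector face occluded by the phi-mount cone at this pose.

    Evaluated on a ``grid x grid`` sample of the face; exactly 0 whenever the
    closed-form criterion (90 - chi) - 2theta_corner >= A holds.
    """
    rays = _detector_rays(det, distance_mm, grid)
    cos_a = np.cos(np.radians(pose.goniostat.cone_half_angle_deg))
    shadowed = rays @ pose.mount_direction > cos_a
    return float(np.count_nonzero(shadowed)) / rays.shape[0]


def per_kappa_shadow_free_widths(
    kappa_set: Sequence[float],
    det: DetectorModel,
    distance_mm: float,
    gonio: GoniostatModel | None = None,
    omega_step_deg: float = 1.0,
    grid: int = 96,
) -> dict[float, float]:
    """Shadow-free omega window width (deg) separately for each kappa setting.

    Because the azimuth of the phi-mount drifts with kappa, the shadow-free
    window keeps roughly the same width across a kappa range while its
    position in omega moves; this per-kappa width is the quantity a strategy
    needs when choosing the omega start of a sweep at one kappa.
    """
    return {
        float(k): shadow_free_omega_range([k], det, distance_mm, gonio,
                                          omega_step_deg, grid)[1]
        for k in np.atleast_1d(np.asarray(kappa_set, dtype=float))
    }


def shadow_free_omega_range(
    kappa_set: Sequence[float],
    det: DetectorModel,
    distance_mm: float,
    gonio: GoniostatModel | None = None,
    omega_step_deg: float = 1.0,
    grid: int = 96,
) -> tuple[float, float]:
    """Widest omega interval with zero detector shadow for every kappa in the set.

    Returns ``(omega_start_deg, width_deg)`` with the interval taken on the
    omega circle (wrap-around allowed); width 0 means no shadow-free omega
    exists, width 360 means no pose in the set ever shadows the detector.
    """
    kappas = np.atleast_1d(np.asarray(kappa_set, dtype=float))
    if kappas.size == 0:
        raise ValueError("kappa set must be non-empty")
    g = gonio if gonio is not None else GoniostatModel()
    rays = _detector_rays(det, distance_mm, grid)
    cos_a = np.cos(np.radians(g.cone_half_angle_deg))
    omegas = np.arange(0.0, 360.0, omega_step_deg)
    free = np.ones(omegas.size, dtype=bool)
    for kappa in kappas:
        # mount direction vs omega, vectorized: rotate the kappa-tilted phi axis
        base = GoniostatPose(kappa_deg=kappa, goniostat=g).phi_axis_direction
        rot = Rotation.from_rotvec(np.outer(omegas * _D2R, OMEGA_AXIS))
        mounts = -rot.apply(base)  # (n_omega, 3)
        free &= (rays @ mounts.T).max(axis=0) <= cos_a
    if not free.any():
        return 0.0, 0.0
    if free.all():
        return 0.0, 360.0
    # longest circular run of shadow-free samples
    doubled = np.concatenate([free, free])
    best_len = run = 0
    best_start = 0
    for i, ok in enumerate(doubled):
        if ok:
            run += 1
            if run > best_len and i < omegas.size + run:
                best_len, best_start = run, i - run + 1
        else:
            run = 0
    best_len = min(best_len, omegas.size)
    return float((best_start % omegas.size) * omega_step_deg), float(best_len * omega_step_deg)
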