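"""Ray-tracing simulator for rotation-method diffraction experiments.

All reciprocal-space vectors are normalized to wavelength 1 ("lambda
normalization"), so the Ewald sphere has unit radius and is centred at -z
(the beam travels along +z).  A reflection with lambda-normalized vector r0
in the sweep setting crosses the sphere at rotation angles omega solving

    r_z(omega) + |r0|^2 / 2 = 0          (rotation about the lab x axis),

which is a phase-shifted cosine in omega: every reciprocal point crosses 0 or
2 times per full turn.  Writing theta for the Bragg angle (sin theta =
|r0|/2) and X for the angle between r0 and the rotation axis, crossings exist
iff theta <= X <= 180 - theta; the excluded "trumpet" around the axis is the
blind region (cusp).  The crossing speed through the sphere gives the Lorentz
intensity enhancement

    L = 1 / (2 sin theta sqrt(cos^2 theta - cos^2 X)),

which reduces to 1/sin(2 theta) on the equator (X = 90 deg) and diverges at
the cusp boundary.

Crossings are projected onto the detector face; a reflection whose footprint
(modelled as a small disc) loses more than 25% of its area to inter-module
gaps is flagged ``in_gap``, and rays inside the phi-mount shadow cone are
flagged ``shadowed``.  Merging the retained observations under the Laue group
(optionally with Friedel pairs) yields completeness, multiplicity and S/N
enhancement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import DetectorModel, GoniostatModel, GoniostatPose
from .sample import CrystalSample
from .strategy import Sweep
from .symmetry import PointGroup

__all__ = [
    "Observation",
    "MergedStats",
    "generate_hkl",
    "ewald_crossings",
    "is_blind",
    "lorentz_factor",
    "detector_hit",
    "simulate_sweeps",
    "merge_stats",
]

OBSERVATION_COLUMNS = [
    "sweep", "h", "k", "l", "omega_deg", "theta_deg", "axis_angle_deg", "xi",
    "lorentz", "x_mm", "y_mm", "on_detector", "in_gap", "shadowed",
]


@dataclass(frozen=True)
class Observation:
    """One predicted Ewald-sphere crossing (row view of the observation table)."""

    hkl: tuple[int, int, int]
    omega_deg: float
    theta_deg: float
    axis_angle_deg: float
    xi: float
    lorentz: float
    x_mm: float | None = None
    y_mm: float | None = None
    on_detector: bool = True
    in_gap: bool = False
    shadowed: bool = False


def generate_hkl(crystal: CrystalSample, d_min: float) -> np.ndarray:
    """All Miller indices (excluding 000) with resolution d >= d_min."""
    a, b, c = crystal.cell[:3]
    hmax = int(np.ceil(a / d_min)) + 1
    kmax = int(np.ceil(b / d_min)) + 1
    lmax = int(np.ceil(c / d_min)) + 1
    h, k, l = np.mgrid[-hmax:hmax + 1, -kmax:kmax + 1, -lmax:lmax + 1]
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    bmat = crystal.reciprocal_matrix()
    d_star = np.linalg.norm(hkl @ bmat.T, axis=1)
    keep = (d_star > 0) & (d_star <= 1.0 / d_min + 1e-12)
    return hkl[keep]


def _lambda_normalized(crystal: CrystalSample, setting: np.ndarray,
                       hkl: np.ndarray, wavelength: float) -> np.ndarray:
    """Lambda-normalized reciprocal vectors in the lab frame at sweep omega = 0."""
    bmat = crystal.reciprocal_matrix()
    return wavelength * (hkl @ (setting @ bmat).T)


def _crossing_solutions(r0: np.ndarray):
    """Vectorized crossing angles for lambda-normalized vectors r0 (N, 3).

    Returns (omega1, omega2, blind) in degrees, omega in [0, 360).  The
    diffraction condition y0 sin w + z0 cos w + rho^2/2 = 0 has amplitude
    rho sin X; reflections with rho^2/2 > amplitude never cross (blind).
    """
    y0, z0 = r0[:, 1], r0[:, 2]
    rho2 = np.einsum("ij,ij->i", r0, r0)
    amp = np.hypot(y0, z0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(amp > 0, -rho2 / (2.0 * amp), -2.0)
    blind = q < -1.0
    a = np.degrees(np.arccos(np.clip(q, -1.0, 1.0)))
    delta = np.degrees(np.arctan2(y0, z0))
    return (delta + a) % 360.0, (delta - a) % 360.0, blind


def ewald_crossings(
    hkl: Sequence[int],
    crystal: CrystalSample,
    sweep: Sweep,
    wavelength: float = 1.0,
) -> list[float]:
    """Crossing angles (deg, within the sweep interval) for one reflection."""
    setting = sweep.setting_matrix(crystal.orientation)
    r0 = _lambda_normalized(crystal, setting, np.asarray(hkl, dtype=float)[None, :], wavelength)
    w1, w2, blind = _crossing_solutions(r0)
    if blind[0]:
        return []
    out = []
    for w in (float(w1[0]), float(w2[0])):
        rel = (w - sweep.omega_start_deg) % 360.0
        n_extra = int(sweep.width_deg // 360.0)
        hits = n_extra + (1 if rel < (sweep.width_deg - 360.0 * n_extra) else 0)
        out.extend([sweep.omega_start_deg + rel + 360.0 * i for i in range(hits)])
    return sorted(out)


def is_blind(d_star: float, wavelength: float, axis_angle_deg: float) -> bool:
    """Whether a reflection never crosses the Ewald sphere (cusp membership).

    True iff X < theta or X > 180 - theta with sin theta = d* lambda / 2.
    The boundary X = theta is classified as measurable (closed-set convention).
    """
    s = d_star * wavelength / 2.0
    if not 0.0 < s <= 1.0:
        raise ValueError("reflection outside the measurable sphere")
    theta = np.degrees(np.arcsin(s))
    return bool(axis_angle_deg < theta or axis_angle_deg > 180.0 - theta)


def lorentz_factor(d_star, wavelength, axis_angle_deg):
    """Lorentz enhancement L = 1 / (2 sin theta sqrt(cos^2 theta - cos^2 X))."""
    s = np.asarray(d_star, dtype=float) * wavelength / 2.0
    x = np.radians(np.asarray(axis_angle_deg, dtype=float))
    cos2 = np.cos(np.arcsin(s)) ** 2 - np.cos(x) ** 2
    if np.any(cos2 <= 0):
        raise ValueError("blind reflection has no Lorentz factor")
    out = 1.0 / (2.0 * s * np.sqrt(cos2))
    return float(out) if out.ndim == 0 else out


# -- detector footprint ----------------------------------------------------

def _disc_offsets(n: int = 25) -> np.ndarray:
    """Deterministic sunflower layout of n sample points on a unit disc."""
    i = np.arange(n) + 0.5
    r = np.sqrt(i / n)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)


_FOOTPRINT = _disc_offsets()


def _gap_fraction(det: DetectorModel, x_mm: np.ndarray, y_mm: np.ndarray,
                  footprint_px: float = 3.0) -> np.ndarray:
    """Fraction of each spot footprint lost to inactive area (gaps or edges)."""
    radius = footprint_px / 2.0 * det.pixel_mm
    pts_x = x_mm[:, None] + radius * _FOOTPRINT[None, :, 0]
    pts_y = y_mm[:, None] + radius * _FOOTPRINT[None, :, 1]
    active = det.active_mask(pts_x, pts_y)
    return 1.0 - active.mean(axis=1)


def detector_hit(
    ray: np.ndarray,
    det: DetectorModel,
    distance_mm: float,
    footprint_px: float = 3.0,
    min_active_fraction: float = 0.75,
) -> tuple[float, float, bool, bool]:
    """Project a diffracted ray to the detector plane.

    Returns (x_mm, y_mm, on_detector, in_gap); coordinates are relative to
    the beam centre.  A spot is ``in_gap`` when less than
    ``min_active_fraction`` of its disc footprint lies on active modules.
    """
    ray = np.asarray(ray, dtype=float)
    if ray[2] <= 0:
        return np.nan, np.nan, False, False
    x = ray[0] / ray[2] * distance_mm
    y = ray[1] / ray[2] * distance_mm
    off = det.beam_centre_offset()
    on = (abs(x + off[0]) <= det.width_mm / 2.0) and (abs(y + off[1]) <= det.height_mm / 2.0)
    if not on:
        return x, y, False, False
    lost = float(_gap_fraction(det, np.array([x]), np.array([y]), footprint_px)[0])
    return x, y, True, lost > (1.0 - min_active_fraction)


def _rotate_about_x(r0: np.ndarray, omega_deg: np.ndarray) -> np.ndarray:
    c = np.cos(np.radians(omega_deg))
    s = np.sin(np.radians(omega_deg))
    out = np.empty_like(r0)
    out[:, 0] = r0[:, 0]
    out[:, 1] = c * r0[:, 1] - s * r0[:, 2]
    out[:, 2] = s * r0[:, 1] + c * r0[:, 2]
    return out


def simulate_sweeps(
    crystal: CrystalSample,
    sweeps: Sequence[Sweep],
    detector: DetectorModel | None = None,
    distance_mm: float | None = None,
    *,
    d_min: float | None = None,
    wavelength: float = 1.0,
    gonio: GoniostatModel | None = None,
    shadow_model: bool = False,
    footprint_px: float = 3.0,
    min_active_fraction: float = 0.75,
) -> pd.DataFrame:
    """Predict all Ewald crossings for a multi-sweep plan.

    Returns the observation table (one row per crossing) with detector
    coordinates and gap/shadow flags when a detector/goniostat is supplied.
    Deterministic for fixed inputs.  Partials at sweep boundaries count as
    observed iff the crossing lies in the half-open interval [start, start +
    width).
    """
    d_min = d_min or crystal.target_resolution_A
    if d_min is None:
        raise ValueError("a resolution limit is required (crystal target or d_min)")
    if detector is not None and distance_mm is not None:
        corner = np.hypot(detector.width_mm, detector.height_mm) / 2.0
        max_two_theta = np.degrees(np.arctan2(corner, distance_mm))
        if np.degrees(2 * np.arcsin(min(wavelength / (2 * d_min), 1.0))) > max_two_theta + 1e-9:
            import warnings
            warnings.warn("resolution limit lies beyond the detector corner", stacklevel=2)
    hkl = generate_hkl(crystal, d_min)
    frames = []
    for i_sweep, sw in enumerate(sweeps):
        setting = sw.setting_matrix(crystal.orientation)
        r0 = _lambda_normalized(crystal, setting, hkl.astype(float), wavelength)
        rho = np.linalg.norm(r0, axis=1)
        ok = rho <= 2.0  # inside the measurable sphere
        w1, w2, blind = _crossing_solutions(r0)
        usable = ok & ~blind
        rows = []
        n_full = int(sw.width_deg // 360.0)
        frac = sw.width_deg - 360.0 * n_full
        for w in (w1, w2):
            rel = (w - sw.omega_start_deg) % 360.0
            base = np.where(usable, n_full + (rel < frac).astype(int), 0)
            for rep in range(int(base.max()) if base.size else 0):
                sel = base > rep
                rows.append((np.nonzero(sel)[0], (sw.omega_start_deg + rel[sel] + 360.0 * rep) % 360.0,
                             rel[sel] + 360.0 * rep))
        if not rows:
            continue
        idx = np.concatenate([r[0] for r in rows])
        omega = np.concatenate([r[1] for r in rows])
        r0s = r0[idx]
        rhos = rho[idx]
        theta = np.degrees(np.arcsin(np.clip(rhos / 2.0, 0, 1)))
        cosX = np.clip(r0s[:, 0] / rhos, -1.0, 1.0)
        axis_angle = np.degrees(np.arccos(cosX))
        xi = r0s[:, 0]
        sin_t = rhos / 2.0
        cos2 = np.cos(np.radians(theta)) ** 2 - cosX**2
        lorentz = 1.0 / (2.0 * sin_t * np.sqrt(np.maximum(cos2, 1e-300)))

        df = pd.DataFrame({
            "sweep": i_sweep,
            "h": hkl[idx, 0], "k": hkl[idx, 1], "l": hkl[idx, 2],
            "omega_deg": omega,
            "theta_deg": theta,
            "axis_angle_deg": axis_angle,
            "xi": xi,
            "lorentz": lorentz,
        })

        if detector is not None and distance_mm is not None:
            r_c = _rotate_about_x(r0s, omega)
            d_ray = r_c + np.array([0.0, 0.0, 1.0])
            with np.errstate(divide="ignore", invalid="ignore"):
                x_mm = np.where(d_ray[:, 2] > 0, d_ray[:, 0] / d_ray[:, 2] * distance_mm, np.nan)
                y_mm = np.where(d_ray[:, 2] > 0, d_ray[:, 1] / d_ray[:, 2] * distance_mm, np.nan)
            off = detector.beam_centre_offset()
            on = (np.abs(x_mm + off[0]) <= detector.width_mm / 2.0) \
                & (np.abs(y_mm + off[1]) <= detector.height_mm / 2.0) \
                & (d_ray[:, 2] > 0)
            in_gap = np.zeros(len(df), dtype=bool)
            if detector.module_px is not None and on.any():
                lost = _gap_fraction(detector, x_mm[on], y_mm[on], footprint_px)
                in_gap[on] = lost > (1.0 - min_active_fraction)
            df["x_mm"], df["y_mm"], df["on_detector"], df["in_gap"] = x_mm, y_mm, on, in_gap
        else:
            df["x_mm"] = np.nan
            df["y_mm"] = np.nan
            df["on_detector"] = True
            df["in_gap"] = False

        if shadow_model:
            g = gonio or GoniostatModel()
            cos_a = np.cos(np.radians(g.cone_half_angle_deg))
            r_c = _rotate_about_x(r0s, omega)
            d_ray = r_c + np.array([0.0, 0.0, 1.0])
            norm = np.linalg.norm(d_ray, axis=1, keepdims=True)
            d_unit = d_ray / np.where(norm > 0, norm, 1.0)
            mounts = np.empty_like(d_unit)
            base = GoniostatPose(kappa_deg=sw.kappa_deg, phi_deg=sw.phi_deg,
                                 goniostat=g).phi_axis_direction
            c = np.cos(np.radians(omega))
            s = np.sin(np.radians(omega))
            mounts[:, 0] = -base[0]
            mounts[:, 1] = -(c * base[1] - s * base[2])
            mounts[:, 2] = -(s * base[1] + c * base[2])
            df["shadowed"] = np.einsum("ij,ij->i", d_unit, mounts) > cos_a
        else:
            df["shadowed"] = False
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    return pd.concat(frames, ignore_index=True)[OBSERVATION_COLUMNS]


# -- merging ---------------------------------------------------------------

def _orbit_representatives(hkl: np.ndarray, ops: Sequence[np.ndarray]) -> np.ndarray:
    """Lexicographically largest orbit image of each hkl under the operator set."""
    if hkl.size == 0:
        return hkl.reshape(0, 3)
    images = np.stack([hkl @ op.T for op in ops], axis=0)  # (n_ops, N, 3)
    m = int(np.abs(images).max()) + 1
    keys = (images[..., 0] * (2 * m + 1) + images[..., 1]) * (2 * m + 1) + images[..., 2]
    best = np.argmax(keys, axis=0)
    return images[best, np.arange(hkl.shape[0])]


@dataclass
class MergedStats:
    """Merged statistics of a simulated multi-sweep experiment.

    ``table`` has one row per observed unique reflection: multiplicity,
    summed Lorentz enhancement (the S/N enhancement factor), resolution and a
    ``cusp_free`` flag (no orbit member blind in any sweep).  Completeness
    values are percentages of the corresponding full unique set at d_min.
    """

    table: pd.DataFrame
    n_unique_possible: int
    n_unique_measurable: int
    completeness_pct: float
    completeness_outside_blind_pct: float
    anomalous_completeness_pct: float
    anomalous_completeness_outside_blind_pct: float
    n_observations: int

    @property
    def mean_multiplicity(self) -> float:
        return float(self.table["multiplicity"].mean()) if len(self.table) else 0.0

    @property
    def max_multiplicity_cusp_free(self) -> int:
        sub = self.table[self.table["cusp_free"]]
        return int(sub["multiplicity"].max()) if len(sub) else 0

    def enhancement_bins(self, n_bins: int = 10) -> pd.DataFrame:
        """Equi-populated S/N enhancement bins with their median enhancement."""
        if not len(self.table):
            return pd.DataFrame(columns=["bin", "n", "median_enhancement"])
        enh = self.table["enhancement"].sort_values().to_numpy()
        splits = np.array_split(enh, min(n_bins, len(enh)))
        return pd.DataFrame({
            "bin": np.arange(len(splits)),
            "n": [len(s) for s in splits],
            "median_enhancement": [float(np.median(s)) for s in splits],
        })


def merge_stats(
    observations: pd.DataFrame,
    point_group: PointGroup,
    friedel: bool = True,
    *,
    crystal: CrystalSample,
    sweeps: Sequence[Sweep],
    d_min: float,
    wavelength: float = 1.0,
    discard_gaps: bool = True,
    discard_shadowed: bool = True,
) -> MergedStats:
    """Merge an observation table under the Laue group (or proper group).

    With ``friedel=True`` merging uses the Laue group (non-anomalous
    statistics); with ``friedel=False`` Friedel mates stay separate
    (anomalous basis).  Both completeness figures are always reported.
    Observations lost to gaps/shadows/off-detector are discarded before
    counting multiplicity.
    """
    ops = list(point_group.operators)
    laue_ops = ops + [-op for op in ops]

    # full unique sets and per-unique blindness over the whole sphere at d_min
    sphere = generate_hkl(crystal, d_min)
    bmat = crystal.reciprocal_matrix()
    d_star = np.linalg.norm(sphere @ bmat.T, axis=1)
    sin_theta = np.clip(d_star * wavelength / 2.0, 0, 1)
    theta = np.degrees(np.arcsin(sin_theta))
    member_measurable = np.zeros(sphere.shape[0], dtype=bool)
    for sw in sweeps:
        setting = sw.setting_matrix(crystal.orientation)
        r0 = _lambda_normalized(crystal, setting, sphere.astype(float), wavelength)
        cosX = np.clip(r0[:, 0] / np.maximum(d_star * wavelength, 1e-300), -1.0, 1.0)
        x_ang = np.degrees(np.arccos(cosX))
        member_measurable |= (x_ang >= theta) & (x_ang <= 180.0 - theta)

    merge_ops = laue_ops if friedel else ops
    reps = _orbit_representatives(sphere, merge_ops)
    rep_df = pd.DataFrame({"rh": reps[:, 0], "rk": reps[:, 1], "rl": reps[:, 2],
                           "meas": member_measurable})
    grouped = rep_df.groupby(["rh", "rk", "rl"], sort=False)["meas"].agg(["any", "all"])
    n_possible = len(grouped)
    n_measurable = int(grouped["any"].sum())

    reps_anom = _orbit_representatives(sphere, ops)
    anom_df = pd.DataFrame({"rh": reps_anom[:, 0], "rk": reps_anom[:, 1],
                            "rl": reps_anom[:, 2], "meas": member_measurable})
    anom_grouped = anom_df.groupby(["rh", "rk", "rl"], sort=False)["meas"].any()
    n_possible_anom = len(anom_grouped)
    n_measurable_anom = int(anom_grouped.sum())

    obs = observations
    if len(obs):
        keep = obs["on_detector"].to_numpy(dtype=bool)
        if discard_gaps:
            keep &= ~obs["in_gap"].to_numpy(dtype=bool)
        if discard_shadowed:
            keep &= ~obs["shadowed"].to_numpy(dtype=bool)
        obs = obs[keep]

    if not len(obs):
        empty = pd.DataFrame(columns=["h", "k", "l", "multiplicity", "enhancement",
                                      "d_A", "cusp_free"])
        return MergedStats(empty, n_possible, n_measurable, 0.0, 0.0, 0.0, 0.0, 0)

    ohkl = obs[["h", "k", "l"]].to_numpy(dtype=np.int64)
    oreps = _orbit_representatives(ohkl, merge_ops)
    odf = pd.DataFrame({"rh": oreps[:, 0], "rk": oreps[:, 1], "rl": oreps[:, 2],
                        "lorentz": obs["lorentz"].to_numpy()})
    agg = odf.groupby(["rh", "rk", "rl"], sort=False)["lorentz"].agg(["size", "sum"])
    agg.columns = ["multiplicity", "enhancement"]

    cusp_free = grouped["all"].reindex(agg.index).fillna(False)
    table = agg.reset_index().rename(columns={"rh": "h", "rk": "k", "rl": "l"})
    rep_dstar = np.linalg.norm(table[["h", "k", "l"]].to_numpy() @ bmat.T, axis=1)
    table["d_A"] = 1.0 / rep_dstar
    table["cusp_free"] = cusp_free.to_numpy(dtype=bool)

    n_obs_unique = len(agg)
    oreps_anom = _orbit_representatives(ohkl, ops)
    n_obs_unique_anom = len(
        pd.DataFrame(oreps_anom, columns=["rh", "rk", "rl"]).drop_duplicates()
    )

    return MergedStats(
        table=table,
        n_unique_possible=n_possible,
        n_unique_measurable=n_measurable,
        completeness_pct=100.0 * n_obs_unique / n_possible if n_possible else 0.0,
        completeness_outside_blind_pct=(
            100.0 * n_obs_unique / n_measurable if n_measurable else 0.0),
        anomalous_completeness_pct=(
            100.0 * n_obs_unique_anom / n_possible_anom if n_possible_anom else 0.0),
        anomalous_completeness_outside_blind_pct=(
            100.0 * n_obs_unique_anom / n_measurable_anom if n_measurable_anom else 0.0),
        n_observations=int(len(obs)),
    )
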