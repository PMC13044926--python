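"""End-to-end strategy pipeline: symmetry -> geometry -> dose -> strategy -> simulation.

`run_pipeline` executes the full compute path for one sample and returns a
JSON-serializable report with every intermediate quantity: the symmetry the
strategy is computed for, the detector distance and angular limits at the
target resolution, the dose budget and recommended transmission, the sweep
plan, and the simulated merged statistics.  The emitted plan file is the
boundary of this package -- acquisition, centring and beamline messaging
happen elsewhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dose as dose_mod
from .dose import BeamModel, DoseParameters
from .geometry import (
    GoniostatModel,
    chi_max_shadow_free,
    two_theta_for_resolution,
    two_theta_max,
)
from .instruments import load_detector, load_goniostat
from .sample import CrystalSample
from .simulate import merge_stats, simulate_sweeps
from .strategy import StrategyPlan, advanced_strategy, basic_strategy, predicted_multiplicity

logger = logging.getLogger("mxstrat")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run (file paths or bundled names)."""

    crystal: str | Path | CrystalSample
    detector: str = "pilatus6m"
    goniostat: str = "mini-kappa"
    beam: BeamModel = field(default_factory=BeamModel)
    dose_params: DoseParameters = field(default_factory=DoseParameters)
    total_exposure_s: float = 120.0
    distance_mm: float | None = None
    output_dir: str | Path | None = None
    seed: int = 0
    simulate_d_min: float | None = None  # coarser limit for the check simulation


def _distance_for_resolution(det, d_min: float, wavelength: float = 1.0) -> float:
    """Detector distance putting the target resolution at the edge (clamped)."""
    tth = np.radians(two_theta_for_resolution(d_min, wavelength))
    if tth >= np.pi / 2:
        return det.min_distance_mm
    dist = det.narrowest_mm / 2.0 / np.tan(tth)
    return max(dist, det.min_distance_mm)


def run_pipeline(config: RunConfig, mode: str = "basic") -> dict:
    """Execute the strategy compute path; returns the report dict.

    ``mode`` is "basic" or "advanced".  The crystal's target resolution is
    mandatory: it drives the detector distance, the dose budget and the
    reorientation rule, and cannot be defaulted per-sample.
    """
    crystal = (config.crystal if isinstance(config.crystal, CrystalSample)
               else CrystalSample.load(config.crystal))
    if crystal.target_resolution_A is None:
        raise ValueError(
            "target resolution is mandatory: it is the one per-sample parameter "
            "that cannot come from configuration (it sets distance, dose budget "
            "and strategy limits)"
        )
    det = load_detector(config.detector)
    gonio = load_goniostat(config.goniostat)
    d_min = crystal.target_resolution_A

    distance = config.distance_mm or _distance_for_resolution(det, d_min)
    logger.info("detector distance %.1f mm (default from target resolution)", distance)
    tth = two_theta_max(det.narrowest_mm, distance)
    chi_free = chi_max_shadow_free(tth, gonio.cone_half_angle_deg)

    budget = dose_mod.dose_budget(d_min, config.dose_params)
    transmission = dose_mod.recommend_transmission(
        budget, config.total_exposure_s, config.beam,
        thickness_um=crystal.thickness_um, sensitivity=crystal.sensitivity,
        params=config.dose_params,
    )
    f_eff = dose_mod.effective_flux_density(config.beam, crystal.thickness_um)

    acc = crystal.strategy_class()
    if mode == "basic":
        plan = basic_strategy(crystal, gonio)
    elif mode == "advanced":
        plan = advanced_strategy(crystal, det, distance, gonio)
    else:
        raise ValueError("mode must be 'basic' or 'advanced'")

    sim_d_min = config.simulate_d_min or max(d_min, 2.5)
    obs = simulate_sweeps(crystal, plan.sweeps, det, distance, d_min=sim_d_min)
    stats = merge_stats(obs, acc.point_group, friedel=True, crystal=crystal,
                        sweeps=plan.sweeps, d_min=sim_d_min)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "mode": mode,
        "symmetry": {
            "point_group": acc.point_group.name,
            "centring": acc.centring,
            "laue_order": acc.point_group.laue_order,
        },
        "geometry": {
            "detector": det.name,
            "distance_mm": float(distance),
            "two_theta_max_deg": float(tth),
            "chi_max_shadow_free_deg": float(chi_free),
        },
        "dose": {
            "budget_MGy": float(budget),
            "transmission": float(transmission),
            "effective_flux_density": float(f_eff),
        },
        "plan": plan.to_dict(),
        "predicted_multiplicity": float(predicted_multiplicity(plan, acc.point_group)),
        "simulation": {
            "d_min_A": float(sim_d_min),
            "n_observations": stats.n_observations,
            "completeness_pct": stats.completeness_pct,
            "completeness_outside_blind_pct": stats.completeness_outside_blind_pct,
            "anomalous_completeness_pct": stats.anomalous_completeness_pct,
            "mean_multiplicity": stats.mean_multiplicity,
            "max_multiplicity_cusp_free": stats.max_multiplicity_cusp_free,
        },
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        plan.save(out / "plan.json")
    return report
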