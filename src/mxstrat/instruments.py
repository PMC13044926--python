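"""Bundled instrument library and config-file loading.

Detector module layouts come from vendor data sheets (Dectris), not from any
strategy consideration: PILATUS3 6M tiles 5 x 12 modules of 487 x 195 pixels
(0.172 mm pitch) with 7-pixel horizontal and 17-pixel vertical gaps; EIGER2
16M/9M tile 1028 x 512-pixel modules (0.075 mm pitch) with 12/38-pixel gaps.
PILATUS4 layouts are left gapless here (module data not tracked); their
overall dimensions still reproduce the geometry table.  Custom instruments
load from small YAML/JSON files with the same field names as the dataclasses.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .geometry import DetectorModel, GoniostatModel

__all__ = ["DETECTORS", "GONIOSTATS", "get_detector", "get_goniostat",
           "load_detector", "load_goniostat"]

DETECTORS: dict[str, DetectorModel] = {
    "eiger16m": DetectorModel(
        name="EIGER 16M", width_mm=311.1, height_mm=327.15, pixel_mm=0.075,
        module_px=(1028, 512), gap_px=(12, 38), min_distance_mm=137.0,
    ),
    "eiger9m": DetectorModel(
        name="EIGER 9M", width_mm=233.1, height_mm=244.65, pixel_mm=0.075,
        module_px=(1028, 512), gap_px=(12, 38), min_distance_mm=137.0,
    ),
    "pilatus4-4m": DetectorModel(
        name="PILATUS4 4M", width_mm=311.1, height_mm=327.1, pixel_mm=0.15,
        module_px=None, gap_px=None, min_distance_mm=137.0,
    ),
    "pilatus4-2m": DetectorModel(
        name="PILATUS4 2M", width_mm=233.1, height_mm=244.9, pixel_mm=0.15,
        module_px=None, gap_px=None, min_distance_mm=137.0,
    ),
    "pilatus6m": DetectorModel(
        name="PILATUS3 6M", width_mm=423.636, height_mm=434.644, pixel_mm=0.172,
        module_px=(487, 195), gap_px=(7, 17), min_distance_mm=137.0,
    ),
}

#: Order used for geometry summary tables.
TABLE_ORDER = ("eiger16m", "eiger9m", "pilatus4-4m", "pilatus4-2m", "pilatus6m")

GONIOSTATS: dict[str, GoniostatModel] = {
    "mini-kappa": GoniostatModel(
        kind="mini-kappa", cone_half_angle_deg=19.84,
        kappa_axis_angle_deg=24.0, chi_max_mech_deg=48.0,
    ),
    # Smargon: different construction, but the main phi-mount shadow is a cone
    # of similar aperture; chi capped near 45 deg for collision avoidance.
    "smargon": GoniostatModel(
        kind="smargon", cone_half_angle_deg=19.84,
        kappa_axis_angle_deg=24.0, chi_max_mech_deg=45.0,
    ),
}


def get_detector(name: str) -> DetectorModel:
    key = name.lower().replace(" ", "").replace("_", "-")
    aliases = {"pilatus3-6m": "pilatus6m", "pilatus36m": "pilatus6m",
               "eiger2-16m": "eiger16m", "eiger2-9m": "eiger9m",
               "pilatus44m": "pilatus4-4m", "pilatus42m": "pilatus4-2m"}
    key = aliases.get(key, key)
    if key not in DETECTORS:
        raise KeyError(f"unknown detector {name!r}; bundled: {sorted(DETECTORS)}")
    return DETECTORS[key]


def get_goniostat(name: str) -> GoniostatModel:
    key = name.lower().replace("_", "-")
    if key not in GONIOSTATS:
        raise KeyError(f"unknown goniostat {name!r}; bundled: {sorted(GONIOSTATS)}")
    return GONIOSTATS[key]


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_detector(path: str | Path) -> DetectorModel:
    """Load a detector from a YAML/JSON file, or fall back to the bundled library."""
    p = Path(path)
    if not p.exists():
        return get_detector(str(path))
    data = _load_mapping(p)
    for key in ("module_px", "gap_px", "beam_centre_mm"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    return DetectorModel(**data)


def load_goniostat(path: str | Path) -> GoniostatModel:
    p = Path(path)
    if not p.exists():
        return get_goniostat(str(path))
    return GoniostatModel(**_load_mapping(p))
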