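"""Run-configuration schema and validation.

A run configuration is a single YAML (or dict) document with three
blocks::

    geometry:
      code: A                # A | B
      n_zno: 215             # code A
      sio2_diameter: 80.0    # nm
      zno_np_diameter: 5.0   # nm
      shell_thickness: null  # code B; null -> equal-volume thickness
      holder_diameter_um: 8.5
      holder_height_um: 1.0
      n_nanosystems: 50000   # code B
      world_radius: null     # code A air world, nm
      seed: 0
    beam:
      energies: [3.3, 6.6, 10.0]   # keV
      n_histories: 30000
      tilt: 26.0                   # degrees
      air_column: false
      disc_radius: null            # nm; null -> circumscribe the target
    run:
      seed: 0
      mode: forced                 # analog | forced
      relaxation: local            # local | auger
      bin_width: 1.0               # nm
      electron_step: 1.0
      electron_cutoff: 0.25
      photon_cutoff: 0.25

Schema violations raise :class:`ConfigError` carrying the path of the
offending key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Dict, List, Tuple

import yaml

from .geometry import AssemblyConfig
from .transport import BeamConfig, RunConfig

__all__ = ["ConfigError", "load_config", "validate_config",
           "build_configs"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    def __init__(self, path: str, message: str):
        self.key_path = path
        super().__init__(f"{path}: {message}")


_GEOMETRY_KEYS = {
    "code": str, "n_zno": int, "sio2_diameter": (int, float),
    "zno_np_diameter": (int, float), "shell_thickness": (int, float,
                                                         type(None)),
    "holder_diameter_um": (int, float), "holder_height_um": (int, float),
    "n_nanosystems": int, "world_radius": (int, float, type(None)),
    "seed": int,
}
_BEAM_KEYS = {
    "energies": list, "n_histories": int, "tilt": (int, float),
    "air_column": bool, "disc_radius": (int, float, type(None)),
    "source_distance": (int, float),
}
_RUN_KEYS = {
    "seed": int, "mode": str, "relaxation": str,
    "bin_width": (int, float), "electron_step": (int, float),
    "electron_cutoff": (int, float), "photon_cutoff": (int, float),
    "max_secondaries": int, "detour_factor": (int, float),
    "rayleigh_counts_as_first": bool, "scoring_anchor": str,
    "record_events": bool,
}


def _check_block(cfg: Dict, name: str, keys: Dict, required: bool = True
                 ) -> Dict:
    block = cfg.get(name)
    if block is None:
        if required:
            raise ConfigError(name, "missing required block")
        return {}
    if not isinstance(block, dict):
        raise ConfigError(name, "must be a mapping")
    for k, v in block.items():
        if k not in keys:
            raise ConfigError(f"{name}.{k}", "unknown key")
        if not isinstance(v, keys[k]):
            raise ConfigError(f"{name}.{k}",
                              f"expected {keys[k]}, got {type(v).__name__}")
    return block


def validate_config(cfg: Dict) -> Dict:
    """Validate a configuration dict; returns it unchanged on success."""
    if not isinstance(cfg, dict):
        raise ConfigError("<root>", "configuration must be a mapping")
    geom = _check_block(cfg, "geometry", _GEOMETRY_KEYS)
    beam = _check_block(cfg, "beam", _BEAM_KEYS)
    _check_block(cfg, "run", _RUN_KEYS, required=False)
    code = geom.get("code", "A")
    if code not in ("A", "B"):
        raise ConfigError("geometry.code", "must be 'A' or 'B'")
    if "energies" not in beam:
        raise ConfigError("beam.energies", "missing required key")
    for i, e in enumerate(beam["energies"]):
        if not isinstance(e, (int, float)) or e <= 0:
            raise ConfigError(f"beam.energies[{i}]",
                              "must be a positive number (keV)")
    if "n_histories" not in beam or beam["n_histories"] < 1:
        raise ConfigError("beam.n_histories", "must be a positive integer")
    return cfg


def load_config(path) -> Dict:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def build_configs(cfg: Dict) -> Tuple[AssemblyConfig, List[BeamConfig],
                                      RunConfig]:
    """Turn a validated config dict into typed configuration objects
    (one BeamConfig per requested energy)."""
    geom = dict(cfg["geometry"])
    beam = dict(cfg["beam"])
    run = dict(cfg.get("run", {}))
    assembly = AssemblyConfig(**{k: v for k, v in geom.items()})
    energies = beam.pop("energies")
    beams = [BeamConfig(energy=e, **beam) for e in energies]
    run_cfg = RunConfig(**run)
    return assembly, beams, run_cfg
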