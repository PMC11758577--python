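"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here deterministically:
toy cross-section tables (via :func:`nanoscint.atomic_data.make_toy_tables`),
the benchmark grid of transport configurations at the study conditions,
and synthetic RL spectra drawn from a known Gaussian component truth with
counting-like noise.

The default synthetic spectrum emulates a porphyrin-functionalized
SiO2/ZnO sample: six positive emission bands (ZnO defect ~2.22 eV,
excitonic ~3.09 eV, porphyrin red bands 1.55-2 eV region plus a broad
green-blue band) and four negative Q-band absorption components at
2.01 / 2.2 / 2.34 / 2.5 eV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .rl_spectra import (
    GaussianComponent,
    Q_BAND_CENTERS_EV,
    Spectrum,
    model_eval,
)

__all__ = [
    "SyntheticSpectrumSpec",
    "default_truth_components",
    "make_spectrum",
    "make_benchmark_suite",
    "write_fixture_set",
]


def default_truth_components(variant: str = "functionalized"
                             ) -> List[GaussianComponent]:
    """Ground-truth component sets used by the synthetic spectra.

    Areas and widths are schematic but realistic for ZnO/porphyrin RL:
    the defect band dominates, the excitonic band is weak and narrow, the
    Q-band dips are narrow and shallow.
    """
    pos = [
        GaussianComponent(1.55, 0.060, 25.0, "positive"),
        GaussianComponent(1.70, 0.075, 55.0, "positive"),
        GaussianComponent(1.85, 0.095, 30.0, "positive"),
        GaussianComponent(2.22, 0.250, 85.0, "positive"),
        GaussianComponent(2.70, 0.200, 24.0, "positive"),
        GaussianComponent(3.09, 0.080, 28.0, "positive"),
    ]
    neg = [
        GaussianComponent(c, 0.055, a, "negative",
                          center_bounds=(c - 0.05, c + 0.05))
        for c, a in zip(Q_BAND_CENTERS_EV, (-5.0, -7.0, -5.5, -4.5))
    ]
    if variant == "bare":
        return pos
    if variant == "functionalized":
        return pos + neg
    if variant == "dye-only":
        return pos[:3]
    raise ValueError("variant must be bare, functionalized or dye-only")


@dataclass
class SyntheticSpectrumSpec:
    """Specification of one synthetic spectrum."""

    components: List[GaussianComponent] = field(
        default_factory=lambda: default_truth_components("functionalized"))
    grid_lo: float = 1.2          # eV
    grid_hi: float = 4.5
    n_points: int = 800           # CCD-like sampling (~4 meV/pixel)
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    noise_scale: float = 0.3      # poisson: sigma = scale*sqrt(bg+|model|)
    gaussian_sigma: float = 1.0
    background: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError("unknown noise model")
        for c in self.components:
            if not (self.grid_lo <= c.center - 4 * c.sigma
                    and c.center + 4 * c.sigma <= self.grid_hi):
                raise ValueError(
                    f"grid [{self.grid_lo}, {self.grid_hi}] eV does not "
                    f"cover component {c.center} eV +- 4 sigma")


def make_spectrum(spec: SyntheticSpectrumSpec
                  ) -> Tuple[Spectrum, List[GaussianComponent]]:
    """Draw one synthetic spectrum; returns (spectrum, truth components).

    Deterministic under ``spec.seed``; the truth record is returned (and
    persisted by :func:`write_fixture_set`) alongside the noisy data.
    """
    rng = np.random.default_rng(spec.seed)
    e = np.linspace(spec.grid_lo, spec.grid_hi, spec.n_points)
    clean = model_eval(spec.components, e)
    if spec.noise_model == "none":
        return Spectrum(e, clean), list(spec.components)
    if spec.noise_model == "poisson":
        sigma = spec.noise_scale * np.sqrt(spec.background + np.abs(clean))
    else:
        sigma = np.full_like(clean, spec.gaussian_sigma)
    noisy = clean + rng.normal(0.0, sigma)
    return Spectrum(e, noisy, uncertainty=sigma), list(spec.components)


def make_benchmark_suite(n_histories: int = 30_000,
                         code_b_nanosystems: int = 2_000,
                         base_seed: int = 1000) -> List[Dict]:
    """The study's simulation grid as validated run configurations.

    Twelve code A configurations (n_zno in {0, 10, 100, 215} x beam
    energies {3.3, 6.6, 10} keV) plus one code B configuration with a
    reduced nanosystem count (the partition observables are intensive, so
    the holder population can be scaled down; the full 5e4 population is
    one config key away).
    """
    from .config import validate_config

    suite = []
    k = 0
    for n_zno in (0, 10, 100, 215):
        for energy in (3.3, 6.6, 10.0):
            cfg = {
                "geometry": {"code": "A", "n_zno": n_zno, "seed": base_seed},
                "beam": {"energies": [energy], "n_histories": n_histories,
                         "tilt": 26.0, "air_column": False},
                "run": {"seed": base_seed + k, "mode": "forced",
                        "relaxation": "local", "bin_width": 1.0},
            }
            validate_config(cfg)
            suite.append(cfg)
            k += 1
    cfg_b = {
        "geometry": {"code": "B", "n_nanosystems": code_b_nanosystems,
                     "seed": base_seed},
        "beam": {"energies": [3.3, 6.6, 10.0], "n_histories": n_histories,
                 "tilt": 26.0, "air_column": False},
        "run": {"seed": base_seed + k, "mode": "forced",
                "relaxation": "local", "bin_width": 5.0},
    }
    validate_config(cfg_b)
    suite.append(cfg_b)
    return suite


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_set(directory, n_spectra: int = 3, seed: int = 0) -> Path:
    """Write a small set of synthetic spectra + truth records + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "files": {}}
    for i in range(n_spectra):
        spec = SyntheticSpectrumSpec(seed=seed + i)
        spectrum, truth = make_spectrum(spec)
        spath = directory / f"spectrum_{i:02d}.txt"
        spectrum.to_file(spath)
        tpath = directory / f"spectrum_{i:02d}_truth.json"
        with open(tpath, "w") as fh:
            json.dump([{
                "center": c.center, "sigma": c.sigma, "area": c.area,
                "sign_constraint": c.sign_constraint,
            } for c in truth], fh, indent=2)
        manifest["files"][spath.name] = _sha256(spath)
        manifest["files"][tpath.name] = _sha256(tpath)
    mpath = directory / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return mpath
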