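"""Generator of the shipped element tables (H, C, N, O, Si, Ar, Zn).

The package ships plain-CSV photon cross-section and electron
stopping-power tables covering 0.25-15 keV, produced by the compact
parameterization below.  The parameterization is anchored on published
atomic constants (K-edge energies, K-alpha line energies, K fluorescence
yields, K-edge jump ratios and 10 keV photoelectric reference values) and
uses:

* photoelectric channel — per-element power law ``pe(E) = pe10 (10/E)^n``
  above the K edge, divided by the edge jump ratio below it, with the
  exponent fitted per element; below the mean L-binding energy the law is
  flattened (the L/M fine structure is deliberately smoothed: only the K
  edge is resolved discontinuously, which is the edge the 10 keV physics of
  ZnO turns on);
* incoherent channel — Klein-Nishina total cross section per electron times
  Z/A, damped at low energy by a simple binding factor ``E/(E + 0.18 Z)``;
* coherent channel — smooth ``Z^2.9`` power law in energy (the coherent
  channel only redirects photons, so its absolute scale is uncritical);
* electron stopping — the Joy-Luo (low-beam-energy SEM) modification of the
  Bethe formula, valid down to a few hundred eV, with standard mean
  excitation energies.

Run ``python -m nanoscint.shipped_tables`` to regenerate the CSVs under
``nanoscint/data/``.  The tables are "compatible with", not identical to,
any specific evaluated data library; partition observables computed from
them carry tolerances for this reason (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np

from .atomic_data import ENERGY_MIN_KEV, ElementRecord, save_element_table

E_MAX_KEV = 15.0
_TWO_PI_RE2_BARN = 0.4989  # 2 pi r_e^2
_SIGMA_PER_BARN = 0.602214  # N_A * 1e-24 / (A in g/mol) -> cm^2/g per (b/atom/A)


@dataclass(frozen=True)
class ElementParams:
    z: int
    mass: float            # g/mol
    k_edge: float          # keV
    l_edge_mean: float     # keV, mean of L subshell binding energies
    kalpha: float          # keV
    omega_k: float         # K fluorescence yield
    pe10: float            # photoelectric mu/rho at 10 keV, cm^2/g (above K)
    pe_exp: float          # local power-law exponent
    k_jump: float          # K-edge jump ratio
    i_excitation_ev: float  # mean excitation energy, eV


# Anchors: K edges / K-alpha energies / fluorescence yields and jump ratios
# from standard x-ray data tables; pe10 values are 10 keV photoelectric
# mass attenuation anchors; I from the Berger-Seltzer compilation.
ELEMENT_PARAMS: Dict[str, ElementParams] = {
    "H": ElementParams(1, 1.008, 0.0136, 0.0, 0.0, 0.0, 3.0e-3, 3.30, 1.0, 19.2),
    "C": ElementParams(6, 12.011, 0.2842, 0.010, 0.277, 0.0028, 1.91, 3.09, 11.0, 78.0),
    "N": ElementParams(7, 14.007, 0.4099, 0.015, 0.3924, 0.0052, 3.31, 3.02, 11.0, 82.0),
    "O": ElementParams(8, 15.999, 0.5432, 0.020, 0.5249, 0.0083, 5.45, 2.92, 10.5, 95.0),
    "Si": ElementParams(14, 28.085, 1.839, 0.116, 1.740, 0.050, 32.3, 2.73, 10.3, 173.0),
    "Ar": ElementParams(18, 39.948, 3.2029, 0.275, 2.9577, 0.118, 61.7, 2.74, 9.5, 188.0),
    "Zn": ElementParams(30, 65.38, 9.659, 1.085, 8.639, 0.479, 237.0, 2.66, 7.8, 330.0),
}


def _photoelectric(p: ElementParams, e: np.ndarray, above: np.ndarray) -> np.ndarray:
    """Piecewise power-law photoelectric mu/rho; `above` marks rows that use
    the above-K-edge branch (needed at the duplicated edge node)."""
    pe_above = p.pe10 * (10.0 / e) ** p.pe_exp
    pe = np.where(above, pe_above, pe_above / p.k_jump)
    if p.l_edge_mean > ENERGY_MIN_KEV:
        # flatten the unresolved L/M continuum: below l_edge_mean continue
        # with exponent 1 from the value at l_edge_mean
        pe_at_l = p.pe10 * (10.0 / p.l_edge_mean) ** p.pe_exp / p.k_jump
        low = e < p.l_edge_mean
        pe = np.where(low, pe_at_l * (p.l_edge_mean / e), pe)
    return pe


def _klein_nishina_barn(e_kev: np.ndarray) -> np.ndarray:
    k = np.asarray(e_kev, dtype=float) / 511.0
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k)
                             - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return _TWO_PI_RE2_BARN * (t1 + t2 - t3)


def _incoherent(p: ElementParams, e: np.ndarray) -> np.ndarray:
    binding = e / (e + 0.18 * p.z)
    return _SIGMA_PER_BARN * p.z / p.mass * _klein_nishina_barn(e) * binding


def _coherent(p: ElementParams, e: np.ndarray) -> np.ndarray:
    ec = np.maximum(e, 1.0)  # flat below 1 keV
    return 1.6e-3 * p.z**2.9 / p.mass * (10.0 / ec) ** 1.9


def _stopping_mev_cm2_g(p: ElementParams, e_kev: np.ndarray) -> np.ndarray:
    """Joy-Luo electron total mass stopping power, MeV cm^2/g."""
    j = p.i_excitation_ev * 1e-3  # keV
    return (78.5 * p.z / (p.mass * e_kev)
            * np.log(1.166 * (e_kev + 0.85 * j) / j))


def build_element(symbol: str, n_photon: int = 70,
                  n_electron: int = 48) -> ElementRecord:
    p = ELEMENT_PARAMS[symbol]
    grid = np.geomspace(ENERGY_MIN_KEV, E_MAX_KEV, n_photon)
    grid = grid[np.abs(grid - p.k_edge) > 1e-9]
    if ENERGY_MIN_KEV < p.k_edge < E_MAX_KEV:
        grid = np.sort(np.concatenate([grid, [p.k_edge, p.k_edge]]))
    above = grid >= p.k_edge
    if ENERGY_MIN_KEV < p.k_edge < E_MAX_KEV:
        i = int(np.searchsorted(grid, p.k_edge, side="left"))
        above[i] = False  # first duplicate keeps the below-edge value
    photon = np.column_stack([
        grid,
        _photoelectric(p, grid, above),
        _incoherent(p, grid),
        _coherent(p, grid),
    ])
    e_grid = np.geomspace(ENERGY_MIN_KEV, E_MAX_KEV, n_electron)
    electron = np.column_stack([e_grid, _stopping_mev_cm2_g(p, e_grid)])
    return ElementRecord(
        atomic_number=p.z, symbol=symbol, atomic_mass=p.mass,
        k_edge=p.k_edge, l_edge_mean=p.l_edge_mean, kalpha_energy=p.kalpha,
        fluorescence_yield_k=p.omega_k,
        photon_table=photon, electron_table=electron,
    )


def generate_shipped_tables(directory=None) -> List[Path]:
    """Write all shipped element CSVs; returns the photon-table paths."""
    if directory is None:
        directory = Path(__file__).parent / "data"
    paths = []
    for symbol in ELEMENT_PARAMS:
        rec = build_element(symbol)
        paths.append(save_element_table(rec, directory)[0])
    return paths


if __name__ == "__main__":  # pragma: no cover
    for path in generate_shipped_tables():
        print(path)
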