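"""Element-wise photon cross sections and electron stopping powers.

This module owns the low-level radiological data the transport engine runs
on: per-element photon mass attenuation coefficients (photoelectric,
incoherent, coherent) on an energy grid that resolves the K absorption edge
as a genuine discontinuity, per-element electron total mass stopping powers,
and the mixture rules that turn them into per-material coefficients.

Conventions
-----------
* Photon energies in keV, mass coefficients in cm^2/g, linear coefficients
  in nm^-1 (the transport scale), stopping powers in keV/nm after density
  conversion.
* Interpolation is log-log linear, exact at grid nodes.  There is no
  extrapolation: energies outside the tabulated span raise
  :class:`EnergyOutOfRangeError`, because silently extrapolated cross
  sections would corrupt energy-partition observables.
* The photoelectric column carries a *duplicated* grid energy at the K edge
  (one row holding the below-edge value, one the above-edge value), so that
  interpolation never bridges the edge.  Grids are otherwise strictly
  increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ElementRecord",
    "Material",
    "TableFormatError",
    "EnergyOutOfRangeError",
    "load_element_table",
    "save_element_table",
    "mass_attenuation",
    "linear_attenuation",
    "electron_stopping",
    "csda_range",
    "make_toy_tables",
    "default_library",
    "MATERIALS",
    "CHANNELS",
]

CHANNELS = ("photoelectric", "incoherent", "coherent", "total")

#: Tracking floor of the transport engine; electron tables start here.
ENERGY_MIN_KEV = 0.25


class TableFormatError(ValueError):
    """A table file violates the documented CSV dialect or an invariant."""


class EnergyOutOfRangeError(ValueError):
    """Requested energy lies outside the tabulated grid (no extrapolation)."""


@dataclass
class ElementRecord:
    """Photon and electron data for one element.

    ``photon_table`` columns: energy_keV, photoelectric, incoherent,
    coherent (all cm^2/g).  ``electron_table`` columns: energy_keV, total
    mass stopping power (MeV cm^2/g).
    """

    atomic_number: int
    symbol: str
    atomic_mass: float
    k_edge: float
    l_edge_mean: float
    kalpha_energy: float
    fluorescence_yield_k: float
    photon_table: np.ndarray
    electron_table: np.ndarray

    def __post_init__(self) -> None:
        self.photon_table = np.asarray(self.photon_table, dtype=float)
        self.electron_table = np.asarray(self.electron_table, dtype=float)
        _validate_record(self)

    # -- derived quantities -------------------------------------------------

    @property
    def energy_span(self) -> Tuple[float, float]:
        e = self.photon_table[:, 0]
        return float(e[0]), float(e[-1])

    @property
    def k_edge_in_span(self) -> bool:
        lo, hi = self.energy_span
        return lo < self.k_edge < hi

    @property
    def k_jump_ratio(self) -> float:
        """Above/below photoelectric ratio at the K edge (1.0 if no edge)."""
        if not self.k_edge_in_span:
            return 1.0
        e = self.photon_table[:, 0]
        i = int(np.searchsorted(e, self.k_edge, side="left"))
        return float(self.photon_table[i + 1, 1] / self.photon_table[i, 1])

    def interpolate(self, energy_kev, channel: str):
        """Log-log interpolate one channel; scalar or array energy."""
        if channel == "total":
            return sum(self.interpolate(energy_kev, c) for c in CHANNELS[:3])
        col = {"photoelectric": 1, "incoherent": 2, "coherent": 3}[channel]
        return _loglog_interp(
            self.photon_table[:, 0], self.photon_table[:, col], energy_kev
        )

    def stopping_power(self, energy_kev):
        """Total mass stopping power in MeV cm^2/g (log-log interpolated)."""
        return _loglog_interp(
            self.electron_table[:, 0], self.electron_table[:, 1], energy_kev
        )


@dataclass
class Material:
    """A homogeneous medium: density and mass-fraction composition."""

    name: str
    density: float  # g/cm^3
    composition: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")
        total = sum(self.composition.values())
        if self.composition and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1"
            )


# ---------------------------------------------------------------------------
# interpolation with a duplicated K-edge node


def _loglog_interp(grid: np.ndarray, values: np.ndarray, energy):
    energy_arr = np.asarray(energy, dtype=float)
    scalar = energy_arr.ndim == 0
    e = np.atleast_1d(energy_arr)
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise EnergyOutOfRangeError(
            f"energy outside table span [{grid[0]:g}, {grid[-1]:g}] keV"
        )
    # side='right' makes an energy exactly at the duplicated edge resolve to
    # the above-edge row, and never selects the zero-width duplicate interval
    idx = np.searchsorted(grid, e, side="right")
    idx = np.clip(idx, 1, len(grid) - 1)
    lo, hi = grid[idx - 1], grid[idx]
    vlo, vhi = values[idx - 1], values[idx]
    with np.errstate(divide="ignore"):
        t = np.where(hi > lo, np.log(e / lo) / np.log(hi / lo), 0.0)
    out = np.exp(np.log(vlo) * (1.0 - t) + np.log(vhi) * t)
    # exact at nodes (guards against fp noise in the log round trip)
    exact = e == lo
    out = np.where(exact, vlo, out)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# validation


def _validate_record(rec: ElementRecord) -> None:
    pt = rec.photon_table
    if pt.ndim != 2 or pt.shape[1] != 4:
        raise TableFormatError("photon table must have 4 columns")
    if pt.shape[0] < 2:
        raise TableFormatError("photon grid too short for interpolation")
    e = pt[:, 0]
    de = np.diff(e)
    if np.any(de < 0):
        row = int(np.argmax(de < 0)) + 2  # 1-based data row of the offender
        raise TableFormatError(
            f"non-monotone photon energy grid at data row {row}")
    dup = np.flatnonzero(de == 0)
    lo, hi = e[0], e[-1]
    if lo < rec.k_edge < hi:
        ok = len(dup) == 1 and math.isclose(e[dup[0]], rec.k_edge, rel_tol=1e-6)
        if not ok:
            raise TableFormatError(
                f"K edge {rec.k_edge} keV inside grid must appear as one "
                f"duplicated energy (found {len(dup)} duplicates)"
            )
        below, above = pt[dup[0], 1], pt[dup[0] + 1, 1]
        if not above > below:
            raise TableFormatError("photoelectric K-edge jump must be > 1")
    elif len(dup) > 0:
        row = int(dup[0]) + 2
        raise TableFormatError(f"duplicated grid energy at row {row} (no edge)")
    if np.any(pt[:, 1:] <= 0):
        raise TableFormatError("all photon coefficients must be > 0")
    et = rec.electron_table
    if et.ndim != 2 or et.shape[1] != 2 or et.shape[0] < 2:
        raise TableFormatError("electron table must be (n>=2, 2)")
    if np.any(np.diff(et[:, 0]) <= 0):
        raise TableFormatError("electron energy grid must be strictly increasing")
    if np.any(et[:, 1] <= 0):
        raise TableFormatError("stopping power must be > 0")
    if not 0.0 <= rec.fluorescence_yield_k <= 1.0:
        raise TableFormatError("fluorescence_yield_k must lie in [0, 1]")
    if rec.kalpha_energy >= rec.k_edge:
        raise TableFormatError("kalpha_energy must be below k_edge")


# ---------------------------------------------------------------------------
# file I/O — documented CSV dialect

_HEADER_KEYS = ("element", "Z", "mass", "k_edge_keV", "l_edge_keV",
                "kalpha_keV", "omega_k")


def save_element_table(rec: ElementRecord, directory) -> Tuple[Path, Path]:
    """Write ``<symbol>.csv`` (photon) and ``<symbol>_electron.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    photon = directory / f"{rec.symbol}.csv"
    electron = directory / f"{rec.symbol}_electron.csv"
    header = (
        f"# element={rec.symbol} Z={rec.atomic_number} mass={rec.atomic_mass:g}"
        f" k_edge_keV={rec.k_edge:g} l_edge_keV={rec.l_edge_mean:g}"
        f" kalpha_keV={rec.kalpha_energy:g} omega_k={rec.fluorescence_yield_k:g}"
    )
    with open(photon, "w") as fh:
        fh.write(header + "\n")
        fh.write("energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g\n")
        for row in rec.photon_table:
            fh.write(",".join(f"{v:.6g}" for v in row) + "\n")
    with open(electron, "w") as fh:
        fh.write("energy_keV,stopping_MeVcm2g\n")
        for row in rec.electron_table:
            fh.write(",".join(f"{v:.6g}" for v in row) + "\n")
    return photon, electron


def load_element_table(source) -> ElementRecord:
    """Load an :class:`ElementRecord` from its photon CSV file.

    The companion ``<symbol>_electron.csv`` is read from the same directory.
    Malformed headers, non-monotone grids and missing edge duplication are
    rejected with the offending row number where applicable.
    """
    source = Path(source)
    with open(source) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# "):
        raise TableFormatError(f"{source}: missing '# element=...' header (row 1)")
    meta: Dict[str, str] = {}
    for tok in lines[0][2:].split():
        if "=" not in tok:
            raise TableFormatError(f"{source}: malformed header token {tok!r}")
        k, v = tok.split("=", 1)
        meta[k] = v
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise TableFormatError(f"{source}: header missing {missing}")
    if lines[1].strip() != "energy_keV,pe_cm2g,incoh_cm2g,coh_cm2g":
        raise TableFormatError(f"{source}: bad column header (row 2)")
    rows = []
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise TableFormatError(f"{source}: expected 4 fields at row {i}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise TableFormatError(f"{source}: non-numeric value at row {i}") from exc
    symbol = meta["element"]
    epath = source.with_name(f"{symbol}_electron.csv")
    if not epath.exists():
        raise TableFormatError(f"missing electron table {epath}")
    erows = np.loadtxt(epath, delimiter=",", skiprows=1, ndmin=2)
    return ElementRecord(
        atomic_number=int(meta["Z"]),
        symbol=symbol,
        atomic_mass=float(meta["mass"]),
        k_edge=float(meta["k_edge_keV"]),
        l_edge_mean=float(meta["l_edge_keV"]),
        kalpha_energy=float(meta["kalpha_keV"]),
        fluorescence_yield_k=float(meta["omega_k"]),
        photon_table=np.asarray(rows),
        electron_table=erows,
    )


# ---------------------------------------------------------------------------
# material-level coefficients

Library = Dict[str, ElementRecord]


def _resolve_library(library: Library | None) -> Library:
    return default_library() if library is None else library


def mass_attenuation(material: Material, energy_kev, channel: str,
                     library: Library | None = None):
    """Mixture-rule mass attenuation coefficient, cm^2/g.

    Mass-fraction weighted sum of per-element log-log interpolated values;
    ``total`` is the sum of the three physical channels.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    lib = _resolve_library(library)
    if channel == "total":
        return sum(
            mass_attenuation(material, energy_kev, c, lib) for c in CHANNELS[:3]
        )
    out = 0.0
    for symbol, frac in material.composition.items():
        out = out + frac * lib[symbol].interpolate(energy_kev, channel)
    return out


CM_TO_NM = 1e-7  # cm^-1 -> nm^-1


def linear_attenuation(material: Material, energy_kev, channel: str,
                       library: Library | None = None):
    """Linear attenuation coefficient in nm^-1 (mass coefficient x density)."""
    return mass_attenuation(material, energy_kev, channel, library) \
        * material.density * CM_TO_NM


def electron_stopping(material: Material, energy_kev,
                      library: Library | None = None):
    """Total electron stopping power in keV/nm.

    Valid from the 0.25 keV tracking cutoff up to the grid maximum; the
    transport engine deposits locally below the cutoff instead of calling
    this.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < ENERGY_MIN_KEV):
        raise EnergyOutOfRangeError(
            f"electron energy below {ENERGY_MIN_KEV} keV tracking cutoff"
        )
    lib = _resolve_library(library)
    s_mass = 0.0  # MeV cm^2/g
    for symbol, frac in material.composition.items():
        s_mass = s_mass + frac * lib[symbol].stopping_power(energy_kev)
    # MeV cm^2/g * g/cm^3 = MeV/cm; -> keV/nm: *1e3 keV/MeV * 1e-7 cm/nm
    return s_mass * material.density * 1e3 * CM_TO_NM


def csda_range(material: Material, energy_kev: float,
               library: Library | None = None, n_steps: int = 400) -> float:
    """Continuous-slowing-down path length (nm) from ``energy_kev`` down to
    the 0.25 keV cutoff, by log-grid trapezoid quadrature of 1/S."""
    if energy_kev <= ENERGY_MIN_KEV:
        return 0.0
    grid = np.geomspace(ENERGY_MIN_KEV, energy_kev, n_steps)
    inv_s = 1.0 / electron_stopping(material, grid, library)
    return float(np.trapezoid(inv_s, grid))


# ---------------------------------------------------------------------------
# toy analytic tables — deterministic stand-ins used by the test-suite


def make_toy_tables(elements: Iterable[Tuple[int, float, float]],
                    grid: Sequence[float], directory) -> List[Path]:
    """Emit analytic element tables: photoelectric C(Z) E^-3 with a
    multiplicative K-edge jump, smooth positive scatter channels, Joy-Luo
    style stopping power.  Deterministic given inputs.

    ``elements`` is an iterable of (Z, k_edge_keV, jump_ratio).
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid[0] > ENERGY_MIN_KEV or grid[-1] < 15.0:
        raise ValueError("toy grid must span 0.25-15 keV")
    paths = []
    for z, k_edge, jump in elements:
        if jump <= 1.0:
            raise ValueError(f"jump_ratio must exceed 1, got {jump}")
        symbol = f"X{z}"
        c = z**4 / 1e3
        g = grid[(grid != k_edge)]
        if grid[0] < k_edge < grid[-1]:
            g = np.sort(np.concatenate([g, [k_edge, k_edge]]))
        pe = c / g**3
        above = g >= k_edge
        # duplicated node: first occurrence keeps the below-edge value
        if grid[0] < k_edge < grid[-1]:
            i = int(np.searchsorted(g, k_edge, side="left"))
            above[i] = False
        pe = np.where(above, pe * jump, pe)
        incoh = 0.18 * (1.0 + g / 30.0)
        coh = 0.04 * (10.0 / g) ** 1.5
        photon = np.column_stack([g, pe, incoh, coh])
        a_mass = 2.0 * z
        j_kev = 0.0115 * z
        es = np.geomspace(ENERGY_MIN_KEV, grid[-1], 40)
        stopping = (78.5 * z / (a_mass * es)
                    * np.log(1.166 * (es + 0.85 * j_kev) / j_kev))  # MeV cm2/g
        rec = ElementRecord(
            atomic_number=z, symbol=symbol, atomic_mass=a_mass,
            k_edge=k_edge, l_edge_mean=k_edge / 8.0,
            kalpha_energy=0.85 * k_edge, fluorescence_yield_k=0.3,
            photon_table=photon,
            electron_table=np.column_stack([es, stopping]),
        )
        paths.append(save_element_table(rec, directory)[0])
    return paths


# ---------------------------------------------------------------------------
# shipped data

_DEFAULT_LIBRARY: Library | None = None


def default_library() -> Library:
    """The shipped element library (H, C, N, O, Si, Ar, Zn), cached."""
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        data_dir = Path(__file__).parent / "data"
        lib: Library = {}
        for path in sorted(data_dir.glob("*.csv")):
            if path.stem.endswith("_electron"):
                continue
            rec = load_element_table(path)
            lib[rec.symbol] = rec
        if not lib:
            raise FileNotFoundError(
                f"no shipped element tables under {data_dir}; regenerate with "
                "'python -m nanoscint.shipped_tables'"
            )
        _DEFAULT_LIBRARY = lib
    return _DEFAULT_LIBRARY


#: Materials of the study.  Densities: ZnO 5.61, SiO2 2.65, TCPP 1.3 g/cm^3;
#: air is standard dry air (the composition is an implementation constant).
MATERIALS: Dict[str, Material] = {
    "SiO2": Material("SiO2", 2.65, {"Si": 0.46744, "O": 0.53256}),
    "ZnO": Material("ZnO", 5.61, {"Zn": 0.80338, "O": 0.19662}),
    "air": Material("air", 1.205e-3, {"N": 0.755, "O": 0.232, "Ar": 0.013}),
    # TCPP C48H30N4O8, molar mass ~790.8 g/mol
    "TCPP": Material("TCPP", 1.3, {"C": 0.72906, "H": 0.03824,
                                   "N": 0.07085, "O": 0.16185}),
}
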