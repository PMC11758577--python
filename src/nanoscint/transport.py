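"""Monte Carlo transport of keV photons and their secondaries.

The physics model:

* photon channels: photoelectric absorption, incoherent (Compton)
  scattering on free electrons at rest (Klein-Nishina), coherent
  (Rayleigh) scattering with the Thomson angular law;
* photoelectric events resolve the K shell when the photon is above the
  element's K edge (probability ``1 - 1/jump_ratio``); the K vacancy
  relaxes either radiatively (K-alpha photon, probability ``omega_K``,
  tracked like any photon) or non-radiatively.  Non-radiative relaxation
  either deposits the vacancy energy at the interaction point
  (``relaxation="local"``, the default, matching the reference Geant4
  Livermore configuration in which Auger emission is not activated) or
  emits a single KLL-like Auger electron of energy
  ``k_edge - 2 l_edge_mean`` (``relaxation="auger"``);
* electrons follow a condensed-history walk with 1 nm steps in solids,
  a 0.25 keV tracking cutoff and Gaussian angular diffusion tuned to a
  displacement/path detour factor of 0.6 over a full range;
* ``mode="forced"`` applies forced-first-interaction variance reduction:
  the primary's first interaction is sampled conditionally on occurring in
  a solid along its ray, and the history carries the unconditional
  probability of that event as its statistical weight.

Randomness: a master seed spawns one splitmix64-derived substream per
history, so runs are reproducible independently of batching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .atomic_data import (
    ENERGY_MIN_KEV,
    Library,
    MATERIALS,
    Material,
    default_library,
    electron_stopping,
    linear_attenuation,
    mass_attenuation,
)
from .geometry import GeometryModel, locate
from .scoring import DepositionEvent

__all__ = [
    "BeamConfig",
    "RunConfig",
    "ParticleState",
    "HistoryResult",
    "TransportRun",
    "Simulator",
    "run_simulation",
    "run_history",
    "forced_first_interaction",
    "sample_channel",
    "sample_compton_cos",
    "sample_thomson_cos",
    "compton_event",
    "rayleigh_event",
    "photoelectric_event",
    "transport_electron",
]

_AIR_COLUMN_CM = 15.0


@dataclass
class BeamConfig:
    """Monochromatic parallel beam aimed at the assembly."""

    energy: float = 10.0          # keV
    n_histories: int = 10_000
    source_distance: float = 15.0  # cm of air upstream when air_column on
    tilt: float = 26.0            # degrees from the world z axis
    air_column: bool = False
    disc_radius: Optional[float] = None  # nm; None -> circumscribe target

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.energy <= 0:
            raise ValueError("energy must be > 0")


@dataclass
class RunConfig:
    seed: int = 0
    mode: str = "forced"          # "analog" | "forced"
    electron_step: float = 1.0    # nm
    electron_cutoff: float = ENERGY_MIN_KEV  # keV
    photon_cutoff: float = ENERGY_MIN_KEV    # keV
    max_secondaries: int = 48
    relaxation: str = "local"     # "local" | "auger"
    detour_factor: float = 0.6
    rayleigh_counts_as_first: bool = True
    scoring_anchor: str = "auto"  # "first" | "deposit" | "auto"
    bin_width: float = 1.0        # nm, radial histograms
    record_events: bool = False
    event_cap: int = 2_000_000

    def __post_init__(self) -> None:
        if self.mode not in ("analog", "forced"):
            raise ValueError("mode must be 'analog' or 'forced'")
        if self.relaxation not in ("local", "auger"):
            raise ValueError("relaxation must be 'local' or 'auger'")
        if self.electron_step <= 0:
            raise ValueError("electron_step must be > 0")
        if self.electron_cutoff < ENERGY_MIN_KEV or \
                self.photon_cutoff < ENERGY_MIN_KEV:
            raise ValueError("cutoffs cannot undercut the table minimum")
        if not 0.0 < self.detour_factor < 1.0:
            raise ValueError("detour_factor must be in (0, 1)")


@dataclass
class ParticleState:
    kind: str                    # "photon" | "electron"
    position: np.ndarray
    direction: np.ndarray
    energy: float
    statistical_weight: float = 1.0
    generation: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = float(self.direction @ self.direction)
        if abs(n - 1.0) > 2e-9:
            raise ValueError("direction must be a unit vector")
        if not 0.0 < self.statistical_weight <= 1.0:
            raise ValueError("weight must be in (0, 1]")


@dataclass
class HistoryResult:
    first_interaction: Optional[Tuple[str, object, np.ndarray, str]]
    depositions: List[DepositionEvent]
    escaped_energy: float
    weight: float
    flagged: bool = False


def _detour_constant(f: float) -> float:
    """Solve (1-exp(-t))/t = f for t; per-step angular variance is
    2 t step / residual_range."""
    t = 1.0
    for _ in range(100):
        g = (1.0 - math.exp(-t)) / t - f
        dg = (math.exp(-t) * (1.0 + t) - 1.0) / (t * t)
        t_new = t - g / dg
        if abs(t_new - t) < 1e-12:
            t = t_new
            break
        t = max(t_new, 1e-9)
    return 2.0 * t


# ---------------------------------------------------------------------------
# compilation of geometry and media into kernel arrays


class _CompiledGeometry:
    def __init__(self, model: GeometryModel, media: List[str]):
        entries = []  # (center, r_outer, r_inner, med_outer, med_inner)
        med_idx = {name: i for i, name in enumerate(media)}
        shells: Dict[Tuple[float, float, float], list] = {}
        for b in model.bodies:
            key = tuple(b.center)
            if b.shape == "sphere":
                entries.append((b.center, b.radii[0], 0.0,
                                med_idx[b.medium], -1, b.body_id))
            elif b.shape == "spherical_shell":
                shells.setdefault(key, []).append(b)
            else:
                raise ValueError("cylinder solid bodies are not supported "
                                 "by the transport kernels")
        # merge each shell with its concentric core sphere
        merged = []
        for (center, r_out, r_in, mo, mi, bid) in entries:
            key = tuple(center)
            if key in shells:
                sh = shells.pop(key)[0]
                merged.append((center, sh.radii[1], sh.radii[0],
                               med_idx[sh.medium], mo, sh.body_id))
            else:
                merged.append((center, r_out, r_in, mo, mi, bid))
        for key, shs in shells.items():  # shell without core
            sh = shs[0]
            merged.append((sh.center, sh.radii[1], sh.radii[0],
                           med_idx[sh.medium], med_idx[model.world.medium],
                           sh.body_id))
        n = len(merged)
        self.centers = np.zeros((max(n, 1), 3))
        self.r_outer = np.zeros(max(n, 1))
        self.r_inner = np.zeros(max(n, 1))
        self.med_outer = np.full(max(n, 1), -1, dtype=np.int64)
        self.med_inner = np.full(max(n, 1), -1, dtype=np.int64)
        self.body_ids = np.full(max(n, 1), -1, dtype=np.int64)
        for i, (c, ro, ri, mo, mi, bid) in enumerate(merged):
            self.centers[i] = c
            self.r_outer[i] = ro
            self.r_inner[i] = ri
            self.med_outer[i] = mo
            self.med_inner[i] = mi
            self.body_ids[i] = bid
        self.n_bodies = n

        # world
        w = model.world
        if w.shape == "sphere":
            self.wkind, self.wr, self.wh = 0, float(w.radii[0]), 0.0
        elif w.shape == "cylinder":
            self.wkind, self.wr, self.wh = 1, float(w.radii[0]), \
                float(w.radii[1])
        else:
            raise ValueError("world must be a sphere or a cylinder")

        # uniform cell grid over the padded body bounding box
        if n > 0:
            rmax = float(self.r_outer[:n].max())
            cell = max(2.2 * rmax, 1.0)
            lo = self.centers[:n] - self.r_outer[:n, None]
            hi = self.centers[:n] + self.r_outer[:n, None]
            g0 = lo.min(axis=0) - cell
            g1 = hi.max(axis=0) + cell
            dims = np.maximum(np.ceil((g1 - g0) / cell).astype(int), 1)
            self.cell = cell
            self.g0 = g0
            self.ngx, self.ngy, self.ngz = (int(dims[0]), int(dims[1]),
                                            int(dims[2]))
            ncells = self.ngx * self.ngy * self.ngz
            buckets: Dict[int, List[int]] = {}
            for i in range(n):
                blo = np.floor((self.centers[i] - self.r_outer[i] - g0)
                               / cell).astype(int)
                bhi = np.floor((self.centers[i] + self.r_outer[i] - g0)
                               / cell).astype(int)
                for ix in range(max(blo[0], 0), min(bhi[0], self.ngx - 1) + 1):
                    for iy in range(max(blo[1], 0),
                                    min(bhi[1], self.ngy - 1) + 1):
                        for iz in range(max(blo[2], 0),
                                        min(bhi[2], self.ngz - 1) + 1):
                            ci = (ix * self.ngy + iy) * self.ngz + iz
                            buckets.setdefault(ci, []).append(i)
            counts = np.zeros(ncells + 1, dtype=np.int64)
            for ci, items in buckets.items():
                counts[ci + 1] = len(items)
            self.cell_start = np.cumsum(counts)
            self.cell_items = np.zeros(int(self.cell_start[-1]),
                                       dtype=np.int64)
            for ci, items in buckets.items():
                s = self.cell_start[ci]
                self.cell_items[s:s + len(items)] = items
        else:
            self.cell = 1.0
            self.g0 = np.zeros(3)
            self.ngx = self.ngy = self.ngz = 1
            self.cell_start = np.zeros(2, dtype=np.int64)
            self.cell_items = np.zeros(0, dtype=np.int64)


class _CompiledMedia:
    """Per-medium linear-attenuation, stopping and element tables on
    kernel-friendly padded arrays."""

    def __init__(self, media: List[Material], library: Library,
                 n_grid: int = 300):
        self.names = [m.name for m in media]
        self.materials = media
        grids = []
        for mat in media:
            lo = max((library[s].energy_span[0]
                      for s in mat.composition), default=ENERGY_MIN_KEV)
            hi = min((library[s].energy_span[1]
                      for s in mat.composition), default=15.0)
            g = np.geomspace(lo, hi, n_grid)
            edges = []
            for s in mat.composition:
                rec = library[s]
                if rec.k_edge_in_span and lo < rec.k_edge < hi:
                    edges.append(rec.k_edge)
            g = g[~np.isin(g, edges)]
            for ek in edges:
                g = np.concatenate([g, [ek, ek]])
            grids.append(np.sort(g))
        lmax = max(len(g) for g in grids)
        nm = len(media)
        self.mu_grid = np.zeros((nm, lmax))
        self.mu_pe_log = np.full((nm, lmax), -700.0)
        self.mu_inc_log = np.full((nm, lmax), -700.0)
        self.mu_coh_log = np.full((nm, lmax), -700.0)
        self.mu_len = np.zeros(nm, dtype=np.int64)
        self.n_elem = np.zeros(nm, dtype=np.int64)
        self.el_kedge = np.zeros((nm, 4))
        self.el_ledge = np.zeros((nm, 4))
        self.el_kalpha = np.zeros((nm, 4))
        self.el_omegak = np.zeros((nm, 4))
        self.el_pk = np.zeros((nm, 4))
        self.el_share = np.zeros((nm, 4, lmax))
        floor = 1e-300

        for mi, mat in enumerate(media):
            g = grids[mi]
            self.mu_len[mi] = len(g)
            self.mu_grid[mi, :len(g)] = g
            # duplicated edge nodes: evaluate just below the edge for the
            # first copy so the discontinuity is preserved
            eval_e = g.copy()
            dup = np.flatnonzero(np.diff(g) == 0)
            eval_e[dup] = g[dup] * (1.0 - 1e-9)
            pe = np.zeros(len(g))
            inc = np.zeros(len(g))
            coh = np.zeros(len(g))
            pe_el = {}
            for s, frac in mat.composition.items():
                rec = library[s]
                v = frac * rec.interpolate(eval_e, "photoelectric")
                pe_el[s] = v
                pe += v
                inc += frac * rec.interpolate(eval_e, "incoherent")
                coh += frac * rec.interpolate(eval_e, "coherent")
            conv = mat.density * 1e-7  # cm^2/g -> nm^-1
            self.mu_pe_log[mi, :len(g)] = np.log(np.maximum(pe * conv, floor))
            self.mu_inc_log[mi, :len(g)] = np.log(np.maximum(inc * conv,
                                                             floor))
            self.mu_coh_log[mi, :len(g)] = np.log(np.maximum(coh * conv,
                                                             floor))
            self.n_elem[mi] = len(mat.composition)
            for j, (s, frac) in enumerate(mat.composition.items()):
                rec = library[s]
                self.el_kedge[mi, j] = rec.k_edge
                self.el_ledge[mi, j] = rec.l_edge_mean
                self.el_kalpha[mi, j] = rec.kalpha_energy
                self.el_omegak[mi, j] = rec.fluorescence_yield_k
                jump = rec.k_jump_ratio
                self.el_pk[mi, j] = 1.0 - 1.0 / jump if jump > 1.0 else 0.0
                with np.errstate(invalid="ignore", divide="ignore"):
                    share = np.where(pe > 0, pe_el[s] / np.maximum(pe, floor),
                                     1.0 / len(mat.composition))
                self.el_share[mi, j, :len(g)] = share

            # electron tables
        ke = 120
        self.st_grid = np.zeros((nm, ke))
        self.st_log = np.full((nm, ke), -700.0)
        self.rg_log = np.full((nm, ke), -700.0)
        self.st_len = np.full(nm, ke, dtype=np.int64)
        for mi, mat in enumerate(media):
            eg = np.geomspace(ENERGY_MIN_KEV, 15.0, ke)
            if mat.composition and mat.density > 0:
                s = electron_stopping(mat, eg, library)  # keV/nm
            else:
                s = np.full(ke, 1e-12)
            s = np.maximum(s, 1e-12)
            inv = 1.0 / s
            rng = np.concatenate([[0.0], np.cumsum(
                0.5 * (inv[1:] + inv[:-1]) * np.diff(eg))])
            self.st_grid[mi] = eg
            self.st_log[mi] = np.log(s)
            self.rg_log[mi] = np.log(np.maximum(rng, 1e-3))


@dataclass
class TransportRun:
    """Aggregated result of a transport run.

    Per-history arrays: ``weight``, ``first_med`` (medium index, negative
    codes for no interaction), ``first_body``, ``edep`` (n_histories x
    n_media, weighted keV), ``escaped`` (weighted keV), ``flag``.
    Conditioned radial histograms are filled during the run.
    """

    model: GeometryModel
    beam: BeamConfig
    run: RunConfig
    media: List[str]
    weight: np.ndarray
    first_med: np.ndarray
    first_body: np.ndarray
    edep: np.ndarray
    escaped: np.ndarray
    flag: np.ndarray
    bin_width: float
    hist_first_sio2: np.ndarray
    hist_first_zno: np.ndarray
    events: Optional[List[DepositionEvent]] = None

    @property
    def n_histories(self) -> int:
        return len(self.weight)

    def medium_index(self, name: str) -> int:
        return self.media.index(name)

    @property
    def valid(self) -> np.ndarray:
        """Histories not excluded by the secondary budget."""
        return self.flag == 0

    def energy_closure_error(self) -> float:
        """Max relative violation of weight*E = deposits + escaped."""
        lhs = self.weight * self.beam.energy
        rhs = self.edep.sum(axis=1) + self.escaped
        err = np.abs(lhs - rhs) / max(self.beam.energy, 1e-300)
        return float(err[self.valid].max()) if self.valid.any() else 0.0


class Simulator:
    """Compiles a geometry + material set once and runs histories."""

    def __init__(self, model: GeometryModel,
                 materials: Optional[Dict[str, Material]] = None,
                 library: Optional[Library] = None):
        self.model = model
        self.library = library if library is not None else default_library()
        mats = dict(MATERIALS)
        if materials:
            mats.update(materials)
        names = []
        for b in model.bodies:
            if b.medium not in names:
                names.append(b.medium)
        if model.world.medium not in names:
            names.append(model.world.medium)
        self.media = names
        self.air_idx = names.index(model.world.medium)
        self.geom = _CompiledGeometry(model, names)
        self.tables = _CompiledMedia([mats[n] for n in names], self.library)

    def _beam_frame(self, beam: BeamConfig):
        th = math.radians(beam.tilt)
        d = np.array([math.sin(th), 0.0, -math.cos(th)])
        d /= np.linalg.norm(d)
        helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        g = self.geom
        if beam.disc_radius is not None:
            rb = beam.disc_radius
        else:
            if g.n_bodies > 0:
                rb = float(np.max(np.linalg.norm(g.centers[:g.n_bodies],
                                                 axis=1)
                                  + g.r_outer[:g.n_bodies]))
            elif g.wkind == 0:
                rb = g.wr
            else:
                rb = math.hypot(g.wr, g.wh)
        if g.wkind == 1:
            t_back = 2.0 * math.hypot(g.wr, g.wh) + 10.0
        else:
            t_back = 2.0 * g.wr + 10.0
        return d, e1, e2, rb, t_back

    def run(self, beam: BeamConfig, run: RunConfig) -> TransportRun:
        g = self.geom
        t = self.tables
        d, e1, e2, rb, t_back = self._beam_frame(beam)
        if beam.air_column:
            mu_air_cm = mass_attenuation(MATERIALS["air"], beam.energy,
                                         "total", self.library) \
                * MATERIALS["air"].density
            column_survival = math.exp(-mu_air_cm * beam.source_distance)
        else:
            column_survival = 1.0
        n = beam.n_histories
        nm = len(self.media)
        out_weight = np.zeros(n)
        out_first_med = np.zeros(n, dtype=np.int64)
        out_first_body = np.zeros(n, dtype=np.int64)
        out_edep = np.zeros((n, nm))
        out_escaped = np.zeros(n)
        out_flag = np.zeros(n, dtype=np.int64)
        if g.wkind == 0:
            extent = 2.0 * g.wr
        else:
            extent = 2.0 * math.hypot(g.wr, g.wh)
        nbins = int(math.ceil(extent / run.bin_width)) + 1
        hist_s = np.zeros(nbins)
        hist_z = np.zeros(nbins)
        idx_s = self.media.index("SiO2") if "SiO2" in self.media else -9
        idx_z = self.media.index("ZnO") if "ZnO" in self.media else -9
        anchor = run.scoring_anchor
        if anchor == "auto":
            anchor = "deposit" if g.wkind == 1 else "first"
        anchor_mode = 0 if anchor == "first" else 1
        ev_cap = run.event_cap if run.record_events else 0
        ev_hist = np.zeros(max(ev_cap, 1), dtype=np.int64)
        ev_xyz = np.zeros((max(ev_cap, 1), 3))
        ev_de = np.zeros(max(ev_cap, 1))
        ev_med = np.zeros(max(ev_cap, 1), dtype=np.int64)

        n_ev = _kernels.run_transport(
            g.centers[:max(g.n_bodies, 1)], g.r_outer, g.r_inner,
            g.med_outer, g.med_inner,
            g.cell_start, g.cell_items,
            float(g.g0[0]), float(g.g0[1]), float(g.g0[2]), float(g.cell),
            g.ngx, g.ngy, g.ngz, g.wkind, g.wr, g.wh, self.air_idx,
            t.mu_grid, t.mu_pe_log, t.mu_inc_log, t.mu_coh_log, t.mu_len,
            t.st_grid, t.st_log, t.rg_log, t.st_len,
            t.n_elem, t.el_kedge, t.el_ledge, t.el_kalpha, t.el_omegak,
            t.el_pk, t.el_share,
            beam.energy, d[0], d[1], d[2], e1[0], e1[1], e1[2],
            e2[0], e2[1], e2[2], rb, t_back, column_survival,
            n, run.seed, 1 if run.mode == "forced" else 0,
            1 if run.relaxation == "local" else 0,
            run.electron_step, run.electron_cutoff, run.photon_cutoff,
            _detour_constant(run.detour_factor), run.max_secondaries,
            1 if run.rayleigh_counts_as_first else 0,
            nm, anchor_mode, run.bin_width, idx_s, idx_z, hist_s, hist_z,
            out_weight, out_first_med, out_first_body, out_edep,
            out_escaped, out_flag,
            1 if run.record_events else 0, ev_cap, ev_hist, ev_xyz, ev_de,
            ev_med,
        )
        events = None
        if run.record_events:
            events = []
            for i in range(n_ev):
                hidx = int(ev_hist[i])
                fm = int(out_first_med[hidx])
                first_name = self.media[fm] if fm >= 0 else "none"
                fb = int(out_first_body[hidx])
                if 0 <= fb < g.n_bodies:
                    fa = tuple(g.centers[fb])
                else:
                    fa = (math.nan, math.nan, math.nan)
                events.append(DepositionEvent(
                    position=tuple(ev_xyz[i]),
                    energy=float(ev_de[i]),
                    medium=self.media[int(ev_med[i])],
                    first_medium=first_name,
                    first_anchor=fa,
                    weight=float(out_weight[hidx]),
                    history=hidx,
                ))
        return TransportRun(
            model=self.model, beam=beam, run=run, media=self.media,
            weight=out_weight, first_med=out_first_med,
            first_body=out_first_body, edep=out_edep, escaped=out_escaped,
            flag=out_flag, bin_width=run.bin_width,
            hist_first_sio2=hist_s, hist_first_zno=hist_z, events=events,
        )


def run_simulation(model: GeometryModel, beam: BeamConfig, run: RunConfig,
                   materials: Optional[Dict[str, Material]] = None,
                   library: Optional[Library] = None) -> TransportRun:
    """Convenience wrapper: compile and run in one call."""
    return Simulator(model, materials, library).run(beam, run)


def _seed_from(rng) -> int:
    if rng is None:
        return 0
    if isinstance(rng, (int, np.integer)):
        return int(rng)
    return int(np.asarray(rng.integers(0, 2**31 - 1)))


def run_history(model: GeometryModel, beam: BeamConfig, run: RunConfig,
                rng=None, materials=None, library=None) -> HistoryResult:
    """Run a single history and return its full event record."""
    beam1 = replace(beam, n_histories=1)
    run1 = replace(run, seed=_seed_from(rng), record_events=True)
    sim = Simulator(model, materials, library)
    result = sim.run(beam1, run1)
    fm = int(result.first_med[0])
    if fm >= 0:
        fb = int(result.first_body[0])
        if 0 <= fb < sim.geom.n_bodies:
            body_id = int(sim.geom.body_ids[fb])
            anchor = sim.geom.centers[fb].copy()
        else:
            body_id = -2  # world air
            anchor = np.full(3, np.nan)
        first = (result.media[fm], body_id, anchor, "")
    else:
        first = None
    return HistoryResult(
        first_interaction=first,
        depositions=result.events or [],
        escaped_energy=float(result.escaped[0]),
        weight=float(result.weight[0]),
        flagged=bool(result.flag[0]),
    )


def forced_first_interaction(model: GeometryModel, beam: BeamConfig,
                             run: RunConfig, rng=None, materials=None,
                             library=None) -> HistoryResult:
    """Single history in forced-first-interaction mode."""
    return run_history(model, beam, replace(run, mode="forced"), rng,
                       materials, library)


# ---------------------------------------------------------------------------
# python-level physics surface (unit-testable against independent oracles;
# the numba kernels implement the same algorithms)


def sample_channel(material: Material, energy: float, rng,
                   library: Library | None = None) -> str:
    """Sample the interaction channel proportionally to the partial linear
    attenuation coefficients."""
    mus = np.array([
        linear_attenuation(material, energy, c, library)
        for c in ("photoelectric", "incoherent", "coherent")
    ])
    total = mus.sum()
    if total <= 0:
        raise ValueError("all channels vanish at this energy")
    r = rng.random() * total
    if r < mus[0]:
        return "photoelectric"
    if r < mus[0] + mus[1]:
        return "incoherent"
    return "coherent"


def sample_compton_cos(energy_kev: float, rng, size: Optional[int] = None):
    """Klein-Nishina scattering-angle cosines via Kahn's algorithm."""
    k = energy_kev / 511.0
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        r1, r2, r3 = rng.random((3, m))
        branch1 = r1 <= (1.0 + 2.0 * k) / (9.0 + 2.0 * k)
        x = np.where(branch1, 1.0 + 2.0 * k * r2,
                     (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2))
        ct = 1.0 - (x - 1.0) / k
        acc1 = branch1 & (r3 <= 4.0 * (1.0 / x - 1.0 / x**2))
        acc2 = (~branch1) & (r3 <= 0.5 * (ct**2 + 1.0 / x))
        good = ct[acc1 | acc2]
        take = min(len(good), n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return float(out[0]) if size is None else out


def sample_thomson_cos(rng, size: Optional[int] = None):
    """Cosines from the Thomson angular law p(ct) = 3/8 (1 + ct^2)."""
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        ct = rng.uniform(-1.0, 1.0, m)
        acc = rng.random(m) <= 0.5 * (1.0 + ct**2)
        good = ct[acc]
        take = min(len(good), n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return float(out[0]) if size is None else out


def _rotate_np(d: np.ndarray, ct: float, phi: float) -> np.ndarray:
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    if abs(d[2]) < 0.99:
        u = np.array([-d[1], d[0], 0.0])
    else:
        u = np.array([0.0, -d[2], d[1]])
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    out = st * (math.cos(phi) * u + math.sin(phi) * v) + ct * d
    return out / np.linalg.norm(out)


def compton_event(state: ParticleState, material: Material, rng
                  ) -> Tuple[ParticleState, ParticleState]:
    """Incoherent scatter on a free electron at rest: returns the scattered
    photon and the recoil electron.  Energy is conserved exactly."""
    e = state.energy
    k = e / 511.0
    ct = sample_compton_cos(e, rng)
    e_sc = e / (1.0 + k * (1.0 - ct))
    phi = rng.random() * 2.0 * math.pi
    new_dir = _rotate_np(state.direction, ct, phi)
    tan_half = math.tan(0.5 * math.acos(min(1.0, max(-1.0, ct))))
    if tan_half > 1e-12:
        th_e = math.atan(1.0 / ((1.0 + k) * tan_half))
    else:
        th_e = 0.5 * math.pi
    el_dir = _rotate_np(state.direction, math.cos(th_e), phi + math.pi)
    photon = ParticleState("photon", state.position, new_dir, e_sc,
                           state.statistical_weight, state.generation)
    electron = ParticleState("electron", state.position, el_dir, e - e_sc,
                             state.statistical_weight, state.generation + 1)
    return photon, electron


def rayleigh_event(state: ParticleState, rng) -> ParticleState:
    """Coherent scatter: Thomson angular law, energy unchanged."""
    ct = sample_thomson_cos(rng)
    phi = rng.random() * 2.0 * math.pi
    return ParticleState("photon", state.position,
                         _rotate_np(state.direction, ct, phi),
                         state.energy, state.statistical_weight,
                         state.generation)


def photoelectric_event(state: ParticleState, material: Material, rng,
                        library: Library | None = None,
                        relaxation: str = "local"
                        ) -> Tuple[List[ParticleState], float]:
    """Photoelectric absorption: returns (secondaries, locally deposited
    energy).  Secondaries + local deposit sum exactly to the photon
    energy."""
    lib = default_library() if library is None else library
    e = state.energy
    shares = {}
    for s, frac in material.composition.items():
        shares[s] = frac * lib[s].interpolate(e, "photoelectric")
    total = sum(shares.values())
    r = rng.random() * total
    cum = 0.0
    sym = next(iter(shares))
    for s, v in shares.items():
        cum += v
        if r <= cum:
            sym = s
            break
    rec = lib[sym]
    secondaries: List[ParticleState] = []
    local = 0.0

    def iso():
        ctv = rng.uniform(-1.0, 1.0)
        phv = rng.random() * 2.0 * math.pi
        stv = math.sqrt(1.0 - ctv * ctv)
        return np.array([stv * math.cos(phv), stv * math.sin(phv), ctv])

    jump = rec.k_jump_ratio
    pk = 1.0 - 1.0 / jump if jump > 1.0 else 0.0
    if e >= rec.k_edge and rng.random() < pk:
        e_pe = e - rec.k_edge
        if e_pe > 0:
            secondaries.append(ParticleState(
                "electron", state.position, iso(), e_pe,
                state.statistical_weight, state.generation + 1))
        if rng.random() < rec.fluorescence_yield_k:
            secondaries.append(ParticleState(
                "photon", state.position, iso(), rec.kalpha_energy,
                state.statistical_weight, state.generation + 1))
            local += rec.k_edge - rec.kalpha_energy
        elif relaxation == "local":
            local += rec.k_edge
        else:
            e_aug = rec.k_edge - 2.0 * rec.l_edge_mean
            if e_aug > 0:
                secondaries.append(ParticleState(
                    "electron", state.position, iso(), e_aug,
                    state.statistical_weight, state.generation + 1))
                local += 2.0 * rec.l_edge_mean
            else:
                local += rec.k_edge
    else:
        b = min(rec.l_edge_mean, e)
        local += b
        if e - b > 0:
            secondaries.append(ParticleState(
                "electron", state.position, iso(), e - b,
                state.statistical_weight, state.generation + 1))
    return secondaries, local


def transport_electron(state: ParticleState, model: GeometryModel,
                       run: RunConfig, rng,
                       materials: Optional[Dict[str, Material]] = None,
                       library: Library | None = None
                       ) -> List[DepositionEvent]:
    """Reference condensed-history electron walk on a GeometryModel.

    Fixed-step version used for unit tests and path-length oracles; the
    numba kernel implements the same scheme with adaptive air steps.
    """
    from .atomic_data import csda_range

    lib = default_library() if library is None else library
    mats = dict(MATERIALS)
    if materials:
        mats.update(materials)
    pos = state.position.copy()
    d = state.direction.copy()
    e = state.energy
    w = state.statistical_weight
    c_det = _detour_constant(run.detour_factor)
    deposits: List[DepositionEvent] = []
    while True:
        medium, body = locate(model, pos)
        if not model.world.contains(pos):
            break
        mat = mats[medium]
        if e <= run.electron_cutoff:
            deposits.append(DepositionEvent(tuple(pos), e, medium, "none",
                                            (0, 0, 0), w))
            e = 0.0
            break
        step = run.electron_step
        if mat.density > 0 and mat.composition:
            s = float(electron_stopping(mat, max(e, ENERGY_MIN_KEV), lib))
        else:
            s = 1e-12
        de = min(s * step, e)
        mid = pos + 0.5 * step * d
        mid_medium, _ = locate(model, mid)
        if not model.world.contains(mid):
            break
        deposits.append(DepositionEvent(tuple(mid), de, mid_medium, "none",
                                        (0, 0, 0), w))
        e -= de
        if e <= 0:
            break
        pos = pos + step * d
        if mat.density > 0 and mat.composition:
            rng_nm = max(csda_range(mat, e, lib), 1e-3)
        else:
            rng_nm = 1e12
        sigma = math.sqrt(c_det * step / rng_nm)
        theta = min(abs(rng.normal(0.0, sigma)), math.pi)
        phi = rng.random() * 2.0 * math.pi
        d = _rotate_np(d, math.cos(theta), phi)
    return deposits
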