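"""Observables: per-medium energy partition, first-interaction-conditioned
radial deposition profiles, and interaction counts.

All aggregations are weighted: every deposit carries the statistical
weight of its history (1 in analog mode, the interaction probability in
forced-first-interaction mode).  Partition fractions are normalised over
the scored media (SiO2, ZnO, air); energy leaving the world counts as
escaped, not as air dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DepositionEvent",
    "PartitionTable",
    "RadialProfile",
    "EmptySelectionError",
    "partition_by_medium",
    "partition_from_run",
    "radial_profile",
    "radial_profile_from_run",
    "count_interactions",
]

SCORED_MEDIA = ("SiO2", "ZnO", "air")


class EmptySelectionError(ValueError):
    """Conditioning removed every event."""


@dataclass(frozen=True)
class DepositionEvent:
    """One energy deposit: where, how much (unweighted keV), in which
    medium, tagged with the history's first-interaction anchor."""

    position: Tuple[float, float, float]
    energy: float
    medium: str
    first_medium: str
    first_anchor: Tuple[float, float, float]
    weight: float
    history: int = -1


@dataclass
class PartitionTable:
    """Weighted per-medium deposited energy and percentage shares."""

    energy_kev: Dict[str, float]
    fraction_pct: Dict[str, float]
    beam_energy: float
    geometry_label: str
    condition: str
    stat_error_pct: Optional[Dict[str, float]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.energy_kev:
            rows.append({
                "medium": m,
                "edep_keV": self.energy_kev[m],
                "fraction_pct": self.fraction_pct[m],
                "stat_error_pct": (self.stat_error_pct or {}).get(m,
                                                                  np.nan),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path, sidecar: Optional[dict] = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump(sidecar, fh, indent=2, sort_keys=True)


@dataclass
class RadialProfile:
    """Weighted E_dep histogram vs distance from the scoring anchor."""

    anchor_kind: str             # "r_SiO2" | "r_ZnO" | "r"
    bin_width: float
    bin_edges: np.ndarray
    edep: np.ndarray             # keV per bin, weighted
    condition: str = ""

    @property
    def total(self) -> float:
        return float(self.edep.sum())

    def fraction_beyond(self, radius: float) -> float:
        """Fraction of the conditioned energy deposited beyond ``radius``."""
        total = self.total
        if total <= 0:
            return 0.0
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(self.edep[centers > radius].sum() / total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_lo_nm": self.bin_edges[:-1],
            "r_hi_nm": self.bin_edges[1:],
            "edep_keV": self.edep,
        })

    def to_csv(self, path, sidecar: Optional[dict] = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump(sidecar, fh, indent=2, sort_keys=True)


_CONDITIONS = ("all", "first_sio2", "first_zno")


def _condition_mask_events(events: Sequence[DepositionEvent],
                           condition: str) -> List[DepositionEvent]:
    if condition == "all":
        return list(events)
    want = {"first_sio2": "SiO2", "first_zno": "ZnO"}[condition]
    return [e for e in events if e.first_medium == want]


def partition_by_medium(events: Sequence[DepositionEvent],
                        condition: str = "all",
                        beam_energy: float = float("nan"),
                        geometry_label: str = "") -> PartitionTable:
    """Aggregate an event stream into a per-medium energy partition.

    Fractions are percentages normalised over the scored media and sum to
    100 within 1e-6.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be one of {_CONDITIONS}")
    sel = _condition_mask_events(events, condition)
    if not sel:
        raise EmptySelectionError(
            f"no events satisfy condition {condition!r}")
    energy = {m: 0.0 for m in SCORED_MEDIA}
    for e in sel:
        if e.medium in energy:
            energy[e.medium] += e.weight * e.energy
    total = sum(energy.values())
    if total <= 0:
        raise EmptySelectionError("conditioned deposits carry no energy")
    frac = {m: 100.0 * v / total for m, v in energy.items()}
    return PartitionTable(energy, frac, beam_energy, geometry_label,
                          condition)


def partition_from_run(run, condition: str = "all",
                       n_batches: int = 20) -> PartitionTable:
    """Partition computed from a :class:`TransportRun`'s per-history
    aggregates, with batch-variance statistical errors on the
    percentages."""
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be one of {_CONDITIONS}")
    media = run.media
    mask = run.valid.copy()
    if condition != "all":
        want = {"first_sio2": "SiO2", "first_zno": "ZnO"}[condition]
        if want not in media:
            raise EmptySelectionError(f"medium {want} not in run")
        mask &= run.first_med == media.index(want)
    edep = run.edep[mask]
    if edep.shape[0] == 0 or edep.sum() <= 0:
        raise EmptySelectionError(
            f"no deposited energy under condition {condition!r}")
    scored = [m for m in SCORED_MEDIA if m in media]
    cols = np.array([media.index(m) for m in scored])
    e = edep[:, cols]
    sums = e.sum(axis=0)
    total = sums.sum()
    frac = {m: 100.0 * s / total for m, s in zip(scored, sums)}
    energy = {m: float(s) for m, s in zip(scored, sums)}
    # batch variance on the fractions
    nb = min(n_batches, e.shape[0])
    errs = {}
    if nb >= 2:
        splits = np.array_split(np.arange(e.shape[0]), nb)
        bf = []
        for idx in splits:
            bs = e[idx].sum(axis=0)
            bt = bs.sum()
            bf.append(100.0 * bs / bt if bt > 0 else np.full(len(scored),
                                                             np.nan))
        bf = np.asarray(bf)
        with np.errstate(invalid="ignore"):
            se = np.nanstd(bf, axis=0, ddof=1) / np.sqrt(nb)
        errs = {m: float(s) for m, s in zip(scored, se)}
    return PartitionTable(energy, frac, run.beam.energy, run.model.label,
                          condition, errs or None)


def radial_profile(events: Sequence[DepositionEvent], anchor_kind: str,
                   bin_width: float = 1.0,
                   max_radius: Optional[float] = None) -> RadialProfile:
    """Histogram E_dep vs distance from the first-interaction anchor.

    ``anchor_kind`` must match the conditioning: ``r_SiO2`` uses events
    whose history first interacted in SiO2, ``r_ZnO`` in ZnO; ``r`` uses
    every event (its anchor is whatever the run scored against).
    """
    if anchor_kind not in ("r_SiO2", "r_ZnO", "r"):
        raise ValueError("anchor_kind must be r_SiO2, r_ZnO or r")
    if anchor_kind == "r_SiO2":
        sel = [e for e in events if e.first_medium == "SiO2"]
    elif anchor_kind == "r_ZnO":
        sel = [e for e in events if e.first_medium == "ZnO"]
    else:
        sel = list(events)
    if not sel:
        raise EmptySelectionError(
            f"no events for anchor kind {anchor_kind!r}")
    pos = np.array([e.position for e in sel])
    anc = np.array([e.first_anchor for e in sel])
    if np.isnan(anc).any():
        raise ValueError("events lack first-interaction anchors for the "
                         "requested conditioning")
    r = np.linalg.norm(pos - anc, axis=1)
    wde = np.array([e.weight * e.energy for e in sel])
    rmax = max_radius if max_radius is not None else float(r.max()) + bin_width
    nbins = max(int(np.ceil(rmax / bin_width)), 1)
    edges = np.arange(nbins + 1) * bin_width
    idx = np.minimum((r / bin_width).astype(int), nbins - 1)
    edep = np.zeros(nbins)
    np.add.at(edep, idx, wde)
    cond = {"r_SiO2": "first_sio2", "r_ZnO": "first_zno", "r": "all"}
    return RadialProfile(anchor_kind, bin_width, edges, edep,
                         cond[anchor_kind])


def radial_profile_from_run(run, anchor_kind: str) -> RadialProfile:
    """Radial profile from the histograms filled during a kernel run."""
    if anchor_kind == "r_SiO2":
        hist = run.hist_first_sio2
        cond = "first_sio2"
    elif anchor_kind in ("r_ZnO", "r"):
        hist = run.hist_first_zno if anchor_kind == "r_ZnO" else \
            run.hist_first_sio2 + run.hist_first_zno
        cond = "first_zno" if anchor_kind == "r_ZnO" else "all"
    else:
        raise ValueError("anchor_kind must be r_SiO2, r_ZnO or r")
    nbins = len(hist)
    edges = np.arange(nbins + 1) * run.bin_width
    return RadialProfile(anchor_kind, run.bin_width, edges, hist.copy(),
                         cond)


def count_interactions(run, solids: Iterable[str] = ("SiO2", "ZnO")
                       ) -> Dict[str, float]:
    """Weighted count of histories whose first interaction lies in a solid
    medium, and the per-primary interaction probability.

    In forced mode every history carries the interaction probability of
    its ray as weight, so the estimator is the mean weight; in analog mode
    it is the tagged-history frequency.
    """
    media = run.media
    solid_idx = [media.index(m) for m in solids if m in media]
    n = run.n_histories
    if run.run.mode == "forced":
        count = float(run.weight.sum())
    else:
        mask = np.isin(run.first_med, solid_idx)
        count = float(mask.sum())
    return {
        "n_histories": float(n),
        "weighted_count": count,
        "per_primary": count / n,
    }
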