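"""Core-satellite and core-shell nanogeometries with ray queries.

Two assemblies are modelled:

* **code A** — one SiO2 sphere (80 nm diameter) decorated with ``n_zno``
  ZnO nanoparticles (5 nm diameter) whose centres sit tangent on the sphere
  of radius ``R_SiO2 + r_ZnO``, placed by rejection sampling without
  overlap, all inside an air-filled world sphere;
* **code B** — many SiO2 spheres each coated by a thin equal-volume ZnO
  shell, placed uniformly and without overlap inside an air-filled
  micro-cylinder (default 8.5 um diameter x 1 um height, the downscaled
  sample holder).

Coordinates are Cartesian nanometres with the world origin at the host
sphere centre (code A) or the cylinder centre (code B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Body",
    "GeometryModel",
    "AssemblyConfig",
    "PlacementError",
    "build_code_a",
    "build_code_b",
    "locate",
    "ray_segments",
    "sphere_volume",
    "zno_total_volume",
    "equal_volume_shell_thickness",
    "export_bodies_csv",
]


class PlacementError(RuntimeError):
    """Random placement failed within the retry budget."""


@dataclass
class Body:
    """A labelled solid: sphere, spherical shell or (axis-aligned) cylinder.

    ``radii`` holds (radius,), (inner, outer) or (radius, half_height)
    depending on ``shape``.
    """

    shape: str
    center: Tuple[float, float, float]
    radii: Tuple[float, ...]
    medium: str
    body_id: int = -1

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "spherical_shell", "cylinder"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be > 0")
        if self.shape == "spherical_shell" and self.radii[1] <= self.radii[0]:
            raise ValueError("shell outer radius must exceed inner radius")

    @property
    def volume(self) -> float:
        if self.shape == "sphere":
            return 4.0 / 3.0 * math.pi * self.radii[0] ** 3
        if self.shape == "spherical_shell":
            ri, ro = self.radii
            return 4.0 / 3.0 * math.pi * (ro**3 - ri**3)
        r, h = self.radii
        return math.pi * r**2 * (2.0 * h)

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float) - np.asarray(self.center)
        if self.shape == "sphere":
            return float(p @ p) < self.radii[0] ** 2
        if self.shape == "spherical_shell":
            d2 = float(p @ p)
            return self.radii[0] ** 2 <= d2 < self.radii[1] ** 2
        r, h = self.radii
        return p[0] ** 2 + p[1] ** 2 < r**2 and abs(p[2]) < h


@dataclass
class GeometryModel:
    """World body plus an ordered list of solid bodies and their anchors."""

    world: Body
    bodies: List[Body]
    anchors: Dict[int, np.ndarray] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for i, b in enumerate(self.bodies):
            if b.body_id < 0:
                b.body_id = i
            self.anchors.setdefault(b.body_id, np.asarray(b.center, float))


@dataclass
class AssemblyConfig:
    """Parameters of the two assemblies, at the study's stated dimensions."""

    code: str = "A"
    sio2_diameter: float = 80.0      # nm
    zno_np_diameter: float = 5.0     # nm
    n_zno: int = 215                 # code A: 0 / 10 / 100 / 215
    shell_thickness: Optional[float] = None  # code B; None -> equal volume
    holder_diameter_um: float = 8.5  # code B sample holder
    holder_height_um: float = 1.0
    n_nanosystems: int = 50_000
    world_radius: Optional[float] = None  # code A air world; None -> 500 nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.code not in ("A", "B"):
            raise ValueError("code must be 'A' or 'B'")
        if self.n_zno < 0:
            raise ValueError("n_zno must be >= 0")


# ---------------------------------------------------------------------------
# closed forms


def sphere_volume(diameter: float) -> float:
    return math.pi / 6.0 * diameter**3


def zno_total_volume(n_np: int = 215, np_diameter: float = 5.0) -> float:
    """Total volume (nm^3) of ``n_np`` ZnO nanoparticles."""
    return n_np * sphere_volume(np_diameter)


def equal_volume_shell_thickness(core_diameter: float = 80.0,
                                 n_np: int = 215,
                                 np_diameter: float = 5.0) -> float:
    """Thickness (nm) of the shell whose volume equals ``n_np`` NP volumes."""
    r = core_diameter / 2.0
    v = zno_total_volume(n_np, np_diameter)
    return (r**3 + 3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0) - r


# ---------------------------------------------------------------------------
# builders

_RETRY_BUDGET = 1_000_000  # attempts per particle before giving up


def build_code_a(config: AssemblyConfig, seed: Optional[int] = None) -> GeometryModel:
    """One SiO2 sphere decorated with non-overlapping surface ZnO NPs.

    NP centres are uniform on the sphere of radius ``R_SiO2 + r_ZnO``
    (tangent, no embedding), accepted when no two centres are closer than
    one NP diameter.  Deterministic under a fixed seed.
    """
    if config.code != "A":
        raise ValueError("config.code must be 'A'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    r_host = config.sio2_diameter / 2.0
    r_np = config.zno_np_diameter / 2.0
    shell_r = r_host + r_np
    min_d2 = (2.0 * r_np) ** 2
    world_r = config.world_radius if config.world_radius else 500.0

    centers: List[np.ndarray] = []
    for i in range(config.n_zno):
        for attempt in range(_RETRY_BUDGET):
            v = rng.normal(size=3)
            v *= shell_r / np.linalg.norm(v)
            if all(float(np.sum((v - c) ** 2)) >= min_d2 for c in centers):
                centers.append(v)
                break
        else:
            raise PlacementError(
                f"failed to place NP {i + 1}/{config.n_zno} after "
                f"{_RETRY_BUDGET} attempts"
            )

    bodies = [Body("sphere", (0.0, 0.0, 0.0), (r_host,), "SiO2", 0)]
    for j, c in enumerate(centers, start=1):
        bodies.append(Body("sphere", tuple(c), (r_np,), "ZnO", j))
    world = Body("sphere", (0.0, 0.0, 0.0), (world_r,), "air")
    return GeometryModel(world=world, bodies=bodies,
                         label=f"codeA_n{config.n_zno}")


def build_code_b(config: AssemblyConfig, seed: Optional[int] = None) -> GeometryModel:
    """ZnO-shelled SiO2 spheres placed uniformly in the air cylinder.

    Non-overlap is enforced on centre distances (>= one outer diameter)
    with a uniform cell grid, and spheres are fully contained in the
    holder.  Deterministic under a fixed seed.
    """
    if config.code != "B":
        raise ValueError("config.code must be 'B'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    r_core = config.sio2_diameter / 2.0
    t = (config.shell_thickness if config.shell_thickness is not None
         else equal_volume_shell_thickness(config.sio2_diameter,
                                           config.n_zno,
                                           config.zno_np_diameter))
    r_outer = r_core + t
    hold_r = config.holder_diameter_um * 1e3 / 2.0
    hold_h = config.holder_height_um * 1e3 / 2.0  # half-height, nm
    max_r = hold_r - r_outer
    max_z = hold_h - r_outer
    if max_r <= 0 or max_z <= 0:
        raise PlacementError("holder too small for one coated sphere")
    min_d = 2.0 * r_outer
    cell = min_d
    grid: Dict[Tuple[int, int, int], List[int]] = {}
    pts = np.empty((config.n_nanosystems, 3))

    def cell_of(p):
        return (int(p[0] // cell), int(p[1] // cell), int(p[2] // cell))

    n_placed = 0
    for i in range(config.n_nanosystems):
        for attempt in range(_RETRY_BUDGET):
            x, y = rng.uniform(-max_r, max_r, size=2)
            if x * x + y * y > max_r * max_r:
                continue
            z = rng.uniform(-max_z, max_z)
            p = np.array([x, y, z])
            cx, cy, cz = cell_of(p)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        for j in grid.get((cx + dx, cy + dy, cz + dz), ()):
                            d = pts[j] - p
                            if float(d @ d) < min_d * min_d:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pts[i] = p
                grid.setdefault((cx, cy, cz), []).append(i)
                n_placed += 1
                break
        else:
            raise PlacementError(
                f"packing infeasible: placed {n_placed} of "
                f"{config.n_nanosystems} coated spheres"
            )

    bodies: List[Body] = []
    anchors: Dict[int, np.ndarray] = {}
    for i in range(config.n_nanosystems):
        c = tuple(pts[i])
        core_id, shell_id = 2 * i, 2 * i + 1
        bodies.append(Body("sphere", c, (r_core,), "SiO2", core_id))
        bodies.append(Body("spherical_shell", c, (r_core, r_outer), "ZnO",
                           shell_id))
        anchors[core_id] = pts[i]
        anchors[shell_id] = pts[i]
    world = Body("cylinder", (0.0, 0.0, 0.0), (hold_r, hold_h), "air")
    return GeometryModel(world=world, bodies=bodies, anchors=anchors,
                         label=f"codeB_n{config.n_nanosystems}")


# ---------------------------------------------------------------------------
# queries


def locate(model: GeometryModel, point) -> Tuple[str, object]:
    """Medium and body id at a point; the innermost containing body wins
    (a shell wins over its core at shell radii), points outside every body
    map to the world medium."""
    p = np.asarray(point, dtype=float)
    best = None
    for b in model.bodies:
        if b.contains(p):
            if best is None or b.volume < best.volume:
                best = b
    if best is not None:
        return best.medium, best.body_id
    return model.world.medium, "world"


def _sphere_interval(center, radius, origin, direction):
    oc = origin - center
    b = float(oc @ direction)
    c = float(oc @ oc) - radius * radius
    disc = b * b - c
    if disc <= 0.0:
        return None
    s = math.sqrt(disc)
    return (-b - s, -b + s)


def _cylinder_exit(radii, origin, direction):
    """Distance to exit of an axis-aligned cylinder from an interior point."""
    r, h = radii
    dx, dy, dz = direction
    ox, oy, oz = origin
    a = dx * dx + dy * dy
    t_side = math.inf
    if a > 0:
        b = ox * dx + oy * dy
        c = ox * ox + oy * oy - r * r
        disc = b * b - a * c
        if disc > 0:
            t_side = (-b + math.sqrt(disc)) / a
    t_cap = math.inf
    if dz > 0:
        t_cap = (h - oz) / dz
    elif dz < 0:
        t_cap = (-h - oz) / dz
    return min(t_side, t_cap)


def ray_segments(model: GeometryModel, origin, direction
                 ) -> List[Tuple[float, str]]:
    """Ordered (length, medium) segments from origin to the world exit.

    The direction must be a unit vector; an origin outside the world yields
    an empty list.  Media are evaluated at segment midpoints, and adjacent
    segments with the same medium are merged.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(float(direction @ direction) - 1.0) > 2e-9:
        raise ValueError("direction must be a unit vector")
    w = model.world
    rel = origin - np.asarray(w.center)
    if w.shape == "sphere":
        if float(rel @ rel) >= w.radii[0] ** 2:
            return []
        iv = _sphere_interval(np.asarray(w.center), w.radii[0], origin, direction)
        t_exit = iv[1]
    else:
        if not w.contains(origin):
            return []
        t_exit = _cylinder_exit(w.radii, rel, direction)
    cuts = {0.0, t_exit}
    for b in model.bodies:
        radii = (b.radii,) if b.shape == "sphere" else None
        if b.shape == "sphere":
            iv = _sphere_interval(np.asarray(b.center), b.radii[0], origin,
                                  direction)
            ivs = [iv] if iv else []
        elif b.shape == "spherical_shell":
            ivs = []
            for r in b.radii:
                iv = _sphere_interval(np.asarray(b.center), r, origin, direction)
                if iv:
                    ivs.append(iv)
        else:  # cylinder body: treat like the world formula from inside only
            ivs = []
        for iv in ivs:
            for t in iv:
                if 0.0 < t < t_exit:
                    cuts.add(t)
    ts = sorted(cuts)
    segments: List[Tuple[float, str]] = []
    for t0, t1 in zip(ts[:-1], ts[1:]):
        if t1 - t0 <= 0:
            continue
        mid = origin + direction * (0.5 * (t0 + t1))
        medium, _ = locate(model, mid)
        if segments and segments[-1][1] == medium:
            segments[-1] = (segments[-1][0] + (t1 - t0), medium)
        else:
            segments.append((t1 - t0, medium))
    return segments


def export_bodies_csv(model: GeometryModel, path) -> None:
    """Write the placed bodies as CSV (id, shape, center, radii, medium)."""
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["body_id", "shape", "cx_nm", "cy_nm", "cz_nm",
                     "r1_nm", "r2_nm", "medium"])
        for b in model.bodies:
            r2 = b.radii[1] if len(b.radii) > 1 else ""
            wr.writerow([b.body_id, b.shape, *b.center, b.radii[0], r2,
                         b.medium])
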