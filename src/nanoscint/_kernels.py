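"""Numba kernels for photon/electron Monte Carlo transport.

Everything in this module operates on flat numpy arrays prepared by
:mod:`nanoscint.transport`; no Python objects cross the boundary.  Bodies
are spheres with an optional concentric inner sphere (``r_inner > 0``
models a coated sphere: outer medium between ``r_inner`` and ``r_outer``,
inner medium inside ``r_inner``).  A uniform cell grid accelerates point
location; photon rays use a distance-to-line candidate filter over all
bodies.

Units: nm, keV.  Linear attenuation tables are in nm^-1, stopping powers
in keV/nm, residual ranges in nm.  Deposits are accumulated pre-multiplied
by the history weight, so the per-history identity
``weight * E_beam = sum(deposits) + escaped`` holds exactly up to float
round-off.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ESCAPED = -1        # medium code: outside the world
FIRST_NONE = -1     # history never interacted
FIRST_LOST_COLUMN = -3  # primary absorbed in the source-to-world air column

_SEG_CAP = 512
_STACK_CAP = 64


@njit(cache=True, inline="always")
def _sm64(x):
    """splitmix64 mix, used to derive per-history substream seeds."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0xFFFFFFFFFFFFFFFF


@njit(cache=True, inline="always")
def _bisect_right(grid, n, e):
    lo = 0
    hi = n
    while lo < hi:
        mid = (lo + hi) // 2
        if grid[mid] <= e:
            lo = mid + 1
        else:
            hi = mid
    if lo <= 0:
        lo = 1
    if lo >= n:
        lo = n - 1
    return lo


@njit(cache=True, inline="always")
def _interp_loglog(grid, vals_log, n, e):
    """Log-log interpolation on an ascending grid that may contain one
    duplicated K-edge node; an energy exactly at the edge resolves to the
    above-edge branch (side='right' semantics)."""
    i = _bisect_right(grid, n, e)
    g0 = grid[i - 1]
    g1 = grid[i]
    if e == g0 or g1 <= g0:
        return math.exp(vals_log[i - 1])
    t = math.log(e / g0) / math.log(g1 / g0)
    return math.exp(vals_log[i - 1] * (1.0 - t) + vals_log[i] * t)


@njit(cache=True, inline="always")
def _interp_lin(grid, vals, n, e):
    i = _bisect_right(grid, n, e)
    g0 = grid[i - 1]
    g1 = grid[i]
    if e == g0 or g1 <= g0:
        return vals[i - 1]
    t = math.log(e / g0) / math.log(g1 / g0)
    return vals[i - 1] * (1.0 - t) + vals[i] * t


@njit(cache=True, inline="always")
def _mu_total(mu_grid, mu_pe_log, mu_inc_log, mu_coh_log, mu_len, m, e):
    return (_interp_loglog(mu_grid[m], mu_pe_log[m], mu_len[m], e)
            + _interp_loglog(mu_grid[m], mu_inc_log[m], mu_len[m], e)
            + _interp_loglog(mu_grid[m], mu_coh_log[m], mu_len[m], e))


# ---------------------------------------------------------------------------
# geometry


@njit(cache=True, inline="always")
def _inside_world(x, y, z, wkind, wr, wh):
    if wkind == 0:
        return x * x + y * y + z * z < wr * wr
    return x * x + y * y < wr * wr and -wh < z < wh


@njit(cache=True, inline="always")
def _world_exit(x, y, z, dx, dy, dz, wkind, wr, wh):
    """Distance to the world exit from an interior point."""
    if wkind == 0:
        b = x * dx + y * dy + z * dz
        c = x * x + y * y + z * z - wr * wr
        disc = b * b - c
        if disc <= 0.0:
            return 0.0
        return -b + math.sqrt(disc)
    a = dx * dx + dy * dy
    t_side = 1e30
    if a > 0.0:
        b = x * dx + y * dy
        c = x * x + y * y - wr * wr
        disc = b * b - a * c
        if disc > 0.0:
            t_side = (-b + math.sqrt(disc)) / a
    t_cap = 1e30
    if dz > 0.0:
        t_cap = (wh - z) / dz
    elif dz < 0.0:
        t_cap = (-wh - z) / dz
    t = t_side if t_side < t_cap else t_cap
    return t if t > 0.0 else 0.0


@njit(cache=True)
def _locate(x, y, z, centers, r_outer, r_inner, med_outer, med_inner,
            cell_start, cell_items, gx0, gy0, gz0, cell, nx, ny, nz,
            wkind, wr, wh, air_idx):
    """(medium index, body index); body -2 for world air, -1 if escaped."""
    if not _inside_world(x, y, z, wkind, wr, wh):
        return ESCAPED, -1
    ix = int((x - gx0) / cell)
    iy = int((y - gy0) / cell)
    iz = int((z - gz0) / cell)
    if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
        ci = (ix * ny + iy) * nz + iz
        for k in range(cell_start[ci], cell_start[ci + 1]):
            b = cell_items[k]
            ddx = x - centers[b, 0]
            ddy = y - centers[b, 1]
            ddz = z - centers[b, 2]
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 < r_outer[b] * r_outer[b]:
                ri = r_inner[b]
                if ri > 0.0 and d2 < ri * ri:
                    return med_inner[b], b
                return med_outer[b], b
    return air_idx, -2


@njit(cache=True)
def _nearest_surface(x, y, z, centers, r_outer,
                     cell_start, cell_items, gx0, gy0, gz0, cell,
                     nx, ny, nz):
    """Distance to the nearest body surface among the 27 neighbouring
    cells; one cell size is a safe lower bound when the neighbourhood is
    empty (the grid is padded so every surface is registered in the cells
    it can reach)."""
    ix = int((x - gx0) / cell)
    iy = int((y - gy0) / cell)
    iz = int((z - gz0) / cell)
    best = 1e30
    found = False
    for ax in range(ix - 1, ix + 2):
        if ax < 0 or ax >= nx:
            continue
        for ay in range(iy - 1, iy + 2):
            if ay < 0 or ay >= ny:
                continue
            for az in range(iz - 1, iz + 2):
                if az < 0 or az >= nz:
                    continue
                ci = (ax * ny + ay) * nz + az
                for k in range(cell_start[ci], cell_start[ci + 1]):
                    b = cell_items[k]
                    ddx = x - centers[b, 0]
                    ddy = y - centers[b, 1]
                    ddz = z - centers[b, 2]
                    d = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz) \
                        - r_outer[b]
                    found = True
                    if d < best:
                        best = d
    if not found:
        return cell
    return best if best > 0.0 else 0.0


@njit(cache=True)
def _nearest_center(x, y, z, centers, n_bodies,
                    cell_start, cell_items, gx0, gy0, gz0, cell,
                    nx, ny, nz):
    """Body with the nearest centre (27-cell scan, brute-force fallback)."""
    ix = int((x - gx0) / cell)
    iy = int((y - gy0) / cell)
    iz = int((z - gz0) / cell)
    best = 1e30
    bi = -1
    for ax in range(ix - 1, ix + 2):
        if ax < 0 or ax >= nx:
            continue
        for ay in range(iy - 1, iy + 2):
            if ay < 0 or ay >= ny:
                continue
            for az in range(iz - 1, iz + 2):
                if az < 0 or az >= nz:
                    continue
                ci = (ax * ny + ay) * nz + az
                for k in range(cell_start[ci], cell_start[ci + 1]):
                    b = cell_items[k]
                    ddx = x - centers[b, 0]
                    ddy = y - centers[b, 1]
                    ddz = z - centers[b, 2]
                    d2 = ddx * ddx + ddy * ddy + ddz * ddz
                    if d2 < best:
                        best = d2
                        bi = b
    if bi >= 0:
        return bi
    for b in range(n_bodies):
        ddx = x - centers[b, 0]
        ddy = y - centers[b, 1]
        ddz = z - centers[b, 2]
        d2 = ddx * ddx + ddy * ddy + ddz * ddz
        if d2 < best:
            best = d2
            bi = b
    return bi


@njit(cache=True)
def _ray_solid_segments(px, py, pz, dx, dy, dz,
                        centers, r_outer, r_inner, med_outer, med_inner,
                        n_bodies, t_exit,
                        seg_t0, seg_t1, seg_med, seg_body):
    """Collect solid-body segments along the ray in (0, t_exit), sorted by
    entry distance.  Coated spheres contribute up to three sub-segments
    (shell / core / shell)."""
    n = 0
    for b in range(n_bodies):
        ox = centers[b, 0] - px
        oy = centers[b, 1] - py
        oz = centers[b, 2] - pz
        tc = ox * dx + oy * dy + oz * dz
        d2 = ox * ox + oy * oy + oz * oz - tc * tc
        ro = r_outer[b]
        if d2 >= ro * ro:
            continue
        half = math.sqrt(ro * ro - d2)
        t0 = tc - half
        t1 = tc + half
        if t1 <= 0.0 or t0 >= t_exit:
            continue
        ri = r_inner[b]
        if ri > 0.0 and d2 < ri * ri:
            half_i = math.sqrt(ri * ri - d2)
            ti0 = tc - half_i
            ti1 = tc + half_i
            n = _push_seg(seg_t0, seg_t1, seg_med, seg_body, n,
                          t0, ti0, med_outer[b], b, t_exit)
            n = _push_seg(seg_t0, seg_t1, seg_med, seg_body, n,
                          ti0, ti1, med_inner[b], b, t_exit)
            n = _push_seg(seg_t0, seg_t1, seg_med, seg_body, n,
                          ti1, t1, med_outer[b], b, t_exit)
        else:
            n = _push_seg(seg_t0, seg_t1, seg_med, seg_body, n,
                          t0, t1, med_outer[b], b, t_exit)
    for i in range(1, n):  # insertion sort, n is small
        k0 = seg_t0[i]
        k1 = seg_t1[i]
        km = seg_med[i]
        kb = seg_body[i]
        j = i - 1
        while j >= 0 and seg_t0[j] > k0:
            seg_t0[j + 1] = seg_t0[j]
            seg_t1[j + 1] = seg_t1[j]
            seg_med[j + 1] = seg_med[j]
            seg_body[j + 1] = seg_body[j]
            j -= 1
        seg_t0[j + 1] = k0
        seg_t1[j + 1] = k1
        seg_med[j + 1] = km
        seg_body[j + 1] = kb
    return n


@njit(cache=True, inline="always")
def _push_seg(seg_t0, seg_t1, seg_med, seg_body, n, a0, a1, m, b, t_exit):
    if a0 < 0.0:
        a0 = 0.0
    if a1 > t_exit:
        a1 = t_exit
    if a1 - a0 <= 0.0 or n >= seg_t0.shape[0]:
        return n
    seg_t0[n] = a0
    seg_t1[n] = a1
    seg_med[n] = m
    seg_body[n] = b
    return n + 1


# ---------------------------------------------------------------------------
# sampling


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, ct, phi):
    """Rotate a unit vector by polar angle arccos(ct) and azimuth phi."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(dz) < 0.99:
        ux = -dy
        uy = dx
        uz = 0.0
    else:
        ux = 0.0
        uy = -dz
        uz = dy
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un
    uy /= un
    uz /= un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    nx = st * (cp * ux + sp * vx) + ct * dx
    ny = st * (cp * uy + sp * vy) + ct * dy
    nz = st * (cp * uz + sp * vz) + ct * dz
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / nn, ny / nn, nz / nn


@njit(cache=True, inline="always")
def _iso_dir():
    ct = 2.0 * np.random.random() - 1.0
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * np.random.random()
    return st * math.cos(phi), st * math.sin(phi), ct


@njit(cache=True)
def _kahn_compton_cos(k):
    """Scattering-angle cosine from the Klein-Nishina differential cross
    section, via Kahn's composition-rejection algorithm; k = E/mc^2."""
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * k) / (9.0 + 2.0 * k):
            x = 1.0 + 2.0 * k * r2  # x = E/E'
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                return 1.0 - (x - 1.0) / k
        else:
            x = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            ct = 1.0 - (x - 1.0) / k
            if r3 <= 0.5 * (ct * ct + 1.0 / x):
                return ct


@njit(cache=True)
def _thomson_cos():
    """cos(theta) from the Thomson angular law, p(ct) ∝ 1 + ct^2."""
    while True:
        ct = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + ct * ct):
            return ct


# ---------------------------------------------------------------------------
# scoring helpers


@njit(cache=True)
def _score_hist(x, y, z, wde, first_med, anchor_mode,
                ax, ay, az, centers, n_bodies, cell_start, cell_items,
                gx0, gy0, gz0, cell, ngx, ngy, ngz, bin_width,
                hist_sio2_idx, hist_zno_idx, hist_first_s, hist_first_z):
    """Add one weighted deposit to the conditioned radial histogram.

    anchor_mode 0: r measured from the first-interaction body centre;
    anchor_mode 1: r measured from the nearest body centre (the
    nanosystem in which / next to which the energy is deposited).
    Overflow clamps into the last bin so bin sums stay exhaustive.
    """
    if first_med == hist_sio2_idx:
        hist = hist_first_s
    elif first_med == hist_zno_idx:
        hist = hist_first_z
    else:
        return
    nbins = hist.shape[0]
    if anchor_mode == 1 and n_bodies > 0:
        b = _nearest_center(x, y, z, centers, n_bodies, cell_start,
                            cell_items, gx0, gy0, gz0, cell, ngx, ngy, ngz)
        ax = centers[b, 0]
        ay = centers[b, 1]
        az = centers[b, 2]
    r = math.sqrt((x - ax) ** 2 + (y - ay) ** 2 + (z - az) ** 2)
    i = int(r / bin_width)
    if i >= nbins:
        i = nbins - 1
    hist[i] += wde


@njit(cache=True)
def _deposit(m, de, x, y, z, weight, acc,
             first_med, anchor_mode, ax, ay, az,
             centers, cell_start, cell_items, gx0, gy0, gz0, cell,
             ngx, ngy, ngz, bin_width,
             hist_sio2_idx, hist_zno_idx, hist_first_s, hist_first_z,
             record_events, ev_cap, ev_hist, ev_xyz, ev_de, ev_med,
             h, ev_n_arr):
    acc[m] += weight * de
    if record_events and ev_n_arr[0] < ev_cap:
        k = ev_n_arr[0]
        ev_hist[k] = h
        ev_xyz[k, 0] = x
        ev_xyz[k, 1] = y
        ev_xyz[k, 2] = z
        ev_de[k] = de
        ev_med[k] = m
        ev_n_arr[0] = k + 1
    _score_hist(x, y, z, weight * de, first_med, anchor_mode, ax, ay, az,
                centers, centers.shape[0], cell_start, cell_items,
                gx0, gy0, gz0, cell, ngx, ngy, ngz, bin_width,
                hist_sio2_idx, hist_zno_idx, hist_first_s, hist_first_z)


# ---------------------------------------------------------------------------
# electron condensed-history walk


@njit(cache=True)
def _electron(x, y, z, dx, dy, dz, e, weight,
              centers, r_outer, r_inner, med_outer, med_inner,
              cell_start, cell_items, gx0, gy0, gz0, cell, ngx, ngy, ngz,
              wkind, wr, wh, air_idx,
              st_grid, st_log, rg_log, st_len,
              electron_step, e_cutoff, detour_c, acc,
              first_med, anchor_mode, ax, ay, az, bin_width,
              hist_sio2_idx, hist_zno_idx, hist_first_s, hist_first_z,
              record_events, ev_cap, ev_hist, ev_xyz, ev_de, ev_med,
              h, ev_n_arr):
    """Condensed-history electron walk; returns the escaped (weighted)
    energy.

    Fixed ``electron_step`` (1 nm) steps in solid media; adaptive steps in
    air bounded by half the distance to the nearest body surface.  The
    per-step energy loss ``S(E) * step`` is deposited at the step midpoint
    in the midpoint medium; below the tracking cutoff the residual energy
    is deposited locally.  Per-step Gaussian angular diffusion with
    variance ``detour_c * step / residual_range(E)`` reproduces a
    displacement/path detour factor of ~0.6 over a full range.
    """
    while True:
        med, body = _locate(x, y, z, centers, r_outer, r_inner,
                            med_outer, med_inner, cell_start, cell_items,
                            gx0, gy0, gz0, cell, ngx, ngy, ngz,
                            wkind, wr, wh, air_idx)
        if med == ESCAPED:
            return weight * e
        if e <= e_cutoff:
            _deposit(med, e, x, y, z, weight, acc, first_med, anchor_mode,
                     ax, ay, az, centers, cell_start, cell_items,
                     gx0, gy0, gz0, cell, ngx, ngy, ngz, bin_width,
                     hist_sio2_idx, hist_zno_idx, hist_first_s,
                     hist_first_z, record_events, ev_cap, ev_hist, ev_xyz,
                     ev_de, ev_med, h, ev_n_arr)
            return 0.0
        if med == air_idx:
            d = _nearest_surface(x, y, z, centers, r_outer, cell_start,
                                 cell_items, gx0, gy0, gz0, cell,
                                 ngx, ngy, ngz)
            step = 0.5 * d
            if step < electron_step:
                step = electron_step
            if step > 400.0:
                step = 400.0
        else:
            step = electron_step
        eg = st_grid[med]
        ec = min(max(e, eg[0]), eg[st_len[med] - 1])
        s = _interp_loglog(eg, st_log[med], st_len[med], ec)
        de = s * step
        if de > e:
            de = e
        mx = x + 0.5 * step * dx
        my = y + 0.5 * step * dy
        mz = z + 0.5 * step * dz
        mmed, mbody = _locate(mx, my, mz, centers, r_outer, r_inner,
                              med_outer, med_inner, cell_start, cell_items,
                              gx0, gy0, gz0, cell, ngx, ngy, ngz,
                              wkind, wr, wh, air_idx)
        if mmed == ESCAPED:
            return weight * e
        _deposit(mmed, de, mx, my, mz, weight, acc, first_med, anchor_mode,
                 ax, ay, az, centers, cell_start, cell_items,
                 gx0, gy0, gz0, cell, ngx, ngy, ngz, bin_width,
                 hist_sio2_idx, hist_zno_idx, hist_first_s, hist_first_z,
                 record_events, ev_cap, ev_hist, ev_xyz, ev_de, ev_med,
                 h, ev_n_arr)
        e -= de
        if e <= 0.0:
            return 0.0
        x += step * dx
        y += step * dy
        z += step * dz
        ec = min(max(e, eg[0]), eg[st_len[med] - 1])
        rng_nm = _interp_loglog(eg, rg_log[med], st_len[med], ec)
        if rng_nm > 0.0:
            sigma = math.sqrt(detour_c * step / rng_nm)
            theta = np.random.normal() * sigma
            if theta > math.pi:
                theta = math.pi
            phi = 2.0 * math.pi * np.random.random()
            dx, dy, dz = _rotate(dx, dy, dz, math.cos(theta), phi)


# ---------------------------------------------------------------------------
# main run


@njit(cache=True)
def run_transport(
    # geometry
    centers, r_outer, r_inner, med_outer, med_inner,
    cell_start, cell_items, gx0, gy0, gz0, cell, ngx, ngy, ngz,
    wkind, wr, wh, air_idx,
    # media photon tables (linear attenuation, nm^-1, log values)
    mu_grid, mu_pe_log, mu_inc_log, mu_coh_log, mu_len,
    # media electron tables
    st_grid, st_log, rg_log, st_len,
    # element data per medium (padded to 3 slots)
    n_elem, el_kedge, el_ledge, el_kalpha, el_omegak, el_pk, el_share,
    # beam
    e_beam, bdx, bdy, bdz, b1x, b1y, b1z, b2x, b2y, b2z,
    disc_radius, t_back, column_survival,
    # run options
    n_histories, master_seed, forced, relax_local, electron_step,
    e_cutoff, photon_cutoff, detour_c, max_secondaries, rayleigh_tags,
    # scoring
    n_media, anchor_mode, bin_width, hist_sio2_idx, hist_zno_idx,
    hist_first_s, hist_first_z,
    out_weight, out_first_med, out_first_body, out_edep, out_escaped,
    out_flag,
    # optional event recording
    record_events, ev_cap, ev_hist, ev_xyz, ev_de, ev_med,
):
    """Run ``n_histories`` primary photons; fills the ``out_*`` arrays and
    the conditioned radial histograms; returns the number of recorded
    deposition events."""
    seg_t0 = np.empty(_SEG_CAP)
    seg_t1 = np.empty(_SEG_CAP)
    seg_med = np.empty(_SEG_CAP, dtype=np.int64)
    seg_body = np.empty(_SEG_CAP, dtype=np.int64)
    pseg = np.empty(_SEG_CAP)
    st_x = np.empty(_STACK_CAP)
    st_y = np.empty(_STACK_CAP)
    st_z = np.empty(_STACK_CAP)
    st_dx = np.empty(_STACK_CAP)
    st_dy = np.empty(_STACK_CAP)
    st_dz = np.empty(_STACK_CAP)
    st_e = np.empty(_STACK_CAP)
    acc = np.empty(n_media)
    ev_n_arr = np.zeros(1, dtype=np.int64)
    n_bodies = centers.shape[0]

    for h in range(n_histories):
        s = _sm64(np.uint64(master_seed) * np.uint64(0x100000001)
                  + np.uint64(h))
        np.random.seed(np.uint32(s & np.uint64(0x7FFFFFFF)))
        for m in range(n_media):
            acc[m] = 0.0
        escaped = 0.0
        weight = 1.0
        first_med = FIRST_NONE
        first_body = -1
        anchor_x = 0.0
        anchor_y = 0.0
        anchor_z = 0.0
        flag = 0
        n_secondaries = 0

        while True:  # single-pass block
            # ---- primary setup on the beam disc ----------------------
            while True:
                u = (2.0 * np.random.random() - 1.0) * disc_radius
                v = (2.0 * np.random.random() - 1.0) * disc_radius
                if u * u + v * v <= disc_radius * disc_radius:
                    break
            px = u * b1x + v * b2x - t_back * bdx
            py = u * b1y + v * b2y - t_back * bdy
            pz = u * b1z + v * b2z - t_back * bdz
            dx, dy, dz = bdx, bdy, bdz
            # advance to the world boundary
            t_in = -1.0
            if wkind == 0:
                b = px * dx + py * dy + pz * dz
                c = px * px + py * py + pz * pz - wr * wr
                disc = b * b - c
                if disc > 0.0:
                    t_in = -b - math.sqrt(disc)
            else:
                a = dx * dx + dy * dy
                if a > 0.0:
                    b = px * dx + py * dy
                    c = px * px + py * py - wr * wr
                    disc = b * b - a * c
                    if disc > 0.0:
                        t0 = (-b - math.sqrt(disc)) / a
                        zz = pz + t0 * dz
                        if t0 > 0.0 and -wh < zz < wh:
                            t_in = t0
                if dz != 0.0:
                    for icap in range(2):
                        capz = -wh if icap == 0 else wh
                        t0 = (capz - pz) / dz
                        if t0 > 0.0:
                            xx = px + t0 * dx
                            yy = py + t0 * dy
                            if xx * xx + yy * yy < wr * wr:
                                if t_in < 0.0 or t0 < t_in:
                                    t_in = t0
            if t_in <= 0.0:
                escaped += weight * e_beam
                break
            px += (t_in + 1e-6) * dx
            py += (t_in + 1e-6) * dy
            pz += (t_in + 1e-6) * dz

            if forced == 0 and column_survival < 1.0:
                if np.random.random() > column_survival:
                    first_med = FIRST_LOST_COLUMN
                    escaped += weight * e_beam
                    break

            t_exit = _world_exit(px, py, pz, dx, dy, dz, wkind, wr, wh)
            nseg = _ray_solid_segments(
                px, py, pz, dx, dy, dz, centers, r_outer, r_inner,
                med_outer, med_inner, n_bodies, t_exit,
                seg_t0, seg_t1, seg_med, seg_body)

            e = e_beam
            if forced == 1:
                # ---- forced first interaction ------------------------
                tau0 = 0.0
                psum = 0.0
                for i in range(nseg):
                    m = seg_med[i]
                    mu = _mu_total(mu_grid, mu_pe_log, mu_inc_log,
                                   mu_coh_log, mu_len, m, e)
                    ln = seg_t1[i] - seg_t0[i]
                    pseg[i] = math.exp(-tau0) - math.exp(-tau0 - mu * ln)
                    tau0 += mu * ln
                    psum += pseg[i]
                weight = psum * column_survival
                if nseg == 0 or weight <= 0.0:
                    weight = 0.0
                    break
                r = np.random.random() * psum
                i_sel = nseg - 1
                cum = 0.0
                for i in range(nseg):
                    cum += pseg[i]
                    if r <= cum:
                        i_sel = i
                        break
                m = seg_med[i_sel]
                mu = _mu_total(mu_grid, mu_pe_log, mu_inc_log, mu_coh_log,
                               mu_len, m, e)
                ln = seg_t1[i_sel] - seg_t0[i_sel]
                rr = np.random.random()
                t_loc = -math.log(1.0 - rr * (1.0 - math.exp(-mu * ln))) / mu
                t_int = seg_t0[i_sel] + t_loc
                px += t_int * dx
                py += t_int * dy
                pz += t_int * dz
                first_med = m
                first_body = seg_body[i_sel]
                anchor_x = centers[first_body, 0]
                anchor_y = centers[first_body, 1]
                anchor_z = centers[first_body, 2]
            else:
                # ---- analog free path to the first interaction -------
                tau_target = -math.log(1.0 - np.random.random())
                mu_air = _mu_total(mu_grid, mu_pe_log, mu_inc_log,
                                   mu_coh_log, mu_len, air_idx, e)
                t_cur = 0.0
                tau = 0.0
                t_int = -1.0
                m_first = -1
                b_first = -1
                for i in range(nseg + 1):
                    t_next = seg_t0[i] if i < nseg else t_exit
                    if t_next > t_cur:
                        dtau = mu_air * (t_next - t_cur)
                        if tau + dtau >= tau_target:
                            t_int = t_cur + (tau_target - tau) / mu_air
                            m_first = air_idx
                            b_first = -2
                            break
                        tau += dtau
                        t_cur = t_next
                    if i < nseg:
                        m = seg_med[i]
                        mu = _mu_total(mu_grid, mu_pe_log, mu_inc_log,
                                       mu_coh_log, mu_len, m, e)
                        dtau = mu * (seg_t1[i] - seg_t0[i])
                        if tau + dtau >= tau_target:
                            t_int = seg_t0[i] + (tau_target - tau) / mu
                            m_first = m
                            b_first = seg_body[i]
                            break
                        tau += dtau
                        t_cur = seg_t1[i]
                if t_int < 0.0:
                    escaped += weight * e_beam
                    break
                px += t_int * dx
                py += t_int * dy
                pz += t_int * dz
                first_med = m_first
                first_body = b_first
                if b_first >= 0:
                    anchor_x = centers[b_first, 0]
                    anchor_y = centers[b_first, 1]
                    anchor_z = centers[b_first, 2]
                else:
                    anchor_x = px
                    anchor_y = py
                    anchor_z = pz

            # ---- interaction cascade ---------------------------------
            st_x[0] = px
            st_y[0] = py
            st_z[0] = pz
            st_dx[0] = dx
            st_dy[0] = dy
            st_dz[0] = dz
            st_e[0] = e
            n_stack = 1
            entry_interacts = True   # the first popped photon interacts now
            first_tag_pending = True

            while n_stack > 0:
                n_stack -= 1
                px = st_x[n_stack]
                py = st_y[n_stack]
                pz = st_z[n_stack]
                dx = st_dx[n_stack]
                dy = st_dy[n_stack]
                dz = st_dz[n_stack]
                e = st_e[n_stack]
                must_interact = entry_interacts
                entry_interacts = False

                while True:  # photon flight/interaction loop
                    if must_interact:
                        m_int = first_med
                        b_int = first_body
                        must_interact = False
                    else:
                        med_here, _bh = _locate(
                            px, py, pz, centers, r_outer, r_inner,
                            med_outer, med_inner, cell_start, cell_items,
                            gx0, gy0, gz0, cell, ngx, ngy, ngz,
                            wkind, wr, wh, air_idx)
                        if med_here == ESCAPED:
                            escaped += weight * e
                            break
                        t_exit = _world_exit(px, py, pz, dx, dy, dz,
                                             wkind, wr, wh)
                        nseg = _ray_solid_segments(
                            px, py, pz, dx, dy, dz, centers, r_outer,
                            r_inner, med_outer, med_inner, n_bodies,
                            t_exit, seg_t0, seg_t1, seg_med, seg_body)
                        tau_target = -math.log(1.0 - np.random.random())
                        mu_air = _mu_total(mu_grid, mu_pe_log, mu_inc_log,
                                           mu_coh_log, mu_len, air_idx, e)
                        t_cur = 0.0
                        tau = 0.0
                        t_int = -1.0
                        m_int = -1
                        b_int = -1
                        for i in range(nseg + 1):
                            t_next = seg_t0[i] if i < nseg else t_exit
                            if t_next > t_cur:
                                dtau = mu_air * (t_next - t_cur)
                                if tau + dtau >= tau_target:
                                    t_int = t_cur \
                                        + (tau_target - tau) / mu_air
                                    m_int = air_idx
                                    b_int = -2
                                    break
                                tau += dtau
                                t_cur = t_next
                            if i < nseg:
                                m = seg_med[i]
                                mu = _mu_total(mu_grid, mu_pe_log,
                                               mu_inc_log, mu_coh_log,
                                               mu_len, m, e)
                                dtau = mu * (seg_t1[i] - seg_t0[i])
                                if tau + dtau >= tau_target:
                                    t_int = seg_t0[i] \
                                        + (tau_target - tau) / mu
                                    m_int = m
                                    b_int = seg_body[i]
                                    break
                                tau += dtau
                                t_cur = seg_t1[i]
                        if t_int < 0.0:
                            escaped += weight * e
                            break
                        px += t_int * dx
                        py += t_int * dy
                        pz += t_int * dz

                    # channel selection
                    m = m_int
                    mu_pe = _interp_loglog(mu_grid[m], mu_pe_log[m],
                                           mu_len[m], e)
                    mu_in = _interp_loglog(mu_grid[m], mu_inc_log[m],
                                           mu_len[m], e)
                    mu_co = _interp_loglog(mu_grid[m], mu_coh_log[m],
                                           mu_len[m], e)
                    r = np.random.random() * (mu_pe + mu_in + mu_co)
                    if r < mu_pe:
                        channel = 0
                    elif r < mu_pe + mu_in:
                        channel = 1
                    else:
                        channel = 2

                    if first_tag_pending:
                        if channel != 2 or rayleigh_tags == 1:
                            # (re)anchor the first-interaction tag here
                            first_med = m_int
                            first_body = b_int
                            if b_int >= 0:
                                anchor_x = centers[b_int, 0]
                                anchor_y = centers[b_int, 1]
                                anchor_z = centers[b_int, 2]
                            else:
                                anchor_x = px
                                anchor_y = py
                                anchor_z = pz
                            first_tag_pending = False

                    if channel == 0:
                        # -------- photoelectric ------------------------
                        ne = n_elem[m]
                        rs = np.random.random()
                        j_sel = ne - 1
                        cumshare = 0.0
                        for j in range(ne):
                            cumshare += _interp_lin(mu_grid[m],
                                                    el_share[m, j],
                                                    mu_len[m], e)
                            if rs <= cumshare:
                                j_sel = j
                                break
                        kedge = el_kedge[m, j_sel]
                        ledge = el_ledge[m, j_sel]
                        e_pe = 0.0
                        if e >= kedge and \
                                np.random.random() < el_pk[m, j_sel]:
                            e_pe = e - kedge
                            if np.random.random() < el_omegak[m, j_sel]:
                                # fluorescence: K-alpha photon + residual
                                # vacancy energy deposited locally
                                ka = el_kalpha[m, j_sel]
                                _deposit(m, kedge - ka, px, py, pz, weight,
                                         acc, first_med, anchor_mode,
                                         anchor_x, anchor_y, anchor_z,
                                         centers, cell_start, cell_items,
                                         gx0, gy0, gz0, cell, ngx, ngy,
                                         ngz, bin_width, hist_sio2_idx,
                                         hist_zno_idx, hist_first_s,
                                         hist_first_z, record_events,
                                         ev_cap, ev_hist, ev_xyz, ev_de,
                                         ev_med, h, ev_n_arr)
                                if n_stack < _STACK_CAP and \
                                        n_secondaries < max_secondaries:
                                    fdx, fdy, fdz = _iso_dir()
                                    st_x[n_stack] = px
                                    st_y[n_stack] = py
                                    st_z[n_stack] = pz
                                    st_dx[n_stack] = fdx
                                    st_dy[n_stack] = fdy
                                    st_dz[n_stack] = fdz
                                    st_e[n_stack] = ka
                                    n_stack += 1
                                    n_secondaries += 1
                                else:
                                    flag = 1
                                    escaped += weight * ka
                            elif relax_local == 1:
                                # non-radiative relaxation, local deposit
                                _deposit(m, kedge, px, py, pz, weight, acc,
                                         first_med, anchor_mode, anchor_x,
                                         anchor_y, anchor_z, centers,
                                         cell_start, cell_items, gx0, gy0,
                                         gz0, cell, ngx, ngy, ngz,
                                         bin_width, hist_sio2_idx,
                                         hist_zno_idx, hist_first_s,
                                         hist_first_z, record_events,
                                         ev_cap, ev_hist, ev_xyz, ev_de,
                                         ev_med, h, ev_n_arr)
                            else:
                                # single KLL-like Auger electron
                                e_aug = kedge - 2.0 * ledge
                                de_loc = 2.0 * ledge
                                if e_aug <= 0.0:
                                    e_aug = 0.0
                                    de_loc = kedge
                                _deposit(m, de_loc, px, py, pz, weight,
                                         acc, first_med, anchor_mode,
                                         anchor_x, anchor_y, anchor_z,
                                         centers, cell_start, cell_items,
                                         gx0, gy0, gz0, cell, ngx, ngy,
                                         ngz, bin_width, hist_sio2_idx,
                                         hist_zno_idx, hist_first_s,
                                         hist_first_z, record_events,
                                         ev_cap, ev_hist, ev_xyz, ev_de,
                                         ev_med, h, ev_n_arr)
                                if e_aug > 0.0:
                                    adx, ady, adz = _iso_dir()
                                    escaped += _electron(
                                        px, py, pz, adx, ady, adz, e_aug,
                                        weight, centers, r_outer, r_inner,
                                        med_outer, med_inner, cell_start,
                                        cell_items, gx0, gy0, gz0, cell,
                                        ngx, ngy, ngz, wkind, wr, wh,
                                        air_idx, st_grid, st_log, rg_log,
                                        st_len, electron_step, e_cutoff,
                                        detour_c, acc, first_med,
                                        anchor_mode, anchor_x, anchor_y,
                                        anchor_z, bin_width, hist_sio2_idx,
                                        hist_zno_idx, hist_first_s,
                                        hist_first_z, record_events,
                                        ev_cap, ev_hist, ev_xyz, ev_de,
                                        ev_med, h, ev_n_arr)
                        else:
                            # outer-shell ionization
                            b_en = ledge if ledge < e else e
                            e_pe = e - b_en
                            _deposit(m, b_en, px, py, pz, weight, acc,
                                     first_med, anchor_mode, anchor_x,
                                     anchor_y, anchor_z, centers,
                                     cell_start, cell_items, gx0, gy0,
                                     gz0, cell, ngx, ngy, ngz, bin_width,
                                     hist_sio2_idx, hist_zno_idx,
                                     hist_first_s, hist_first_z,
                                     record_events, ev_cap, ev_hist,
                                     ev_xyz, ev_de, ev_med, h, ev_n_arr)
                        if e_pe > 0.0:
                            pdx, pdy, pdz = _iso_dir()
                            escaped += _electron(
                                px, py, pz, pdx, pdy, pdz, e_pe, weight,
                                centers, r_outer, r_inner, med_outer,
                                med_inner, cell_start, cell_items,
                                gx0, gy0, gz0, cell, ngx, ngy, ngz,
                                wkind, wr, wh, air_idx,
                                st_grid, st_log, rg_log, st_len,
                                electron_step, e_cutoff, detour_c, acc,
                                first_med, anchor_mode, anchor_x,
                                anchor_y, anchor_z, bin_width,
                                hist_sio2_idx, hist_zno_idx, hist_first_s,
                                hist_first_z, record_events, ev_cap,
                                ev_hist, ev_xyz, ev_de, ev_med, h,
                                ev_n_arr)
                        break  # photon absorbed
                    elif channel == 1:
                        # -------- incoherent (Compton) -----------------
                        k = e / 511.0
                        ct = _kahn_compton_cos(k)
                        e_sc = e / (1.0 + k * (1.0 - ct))
                        e_el = e - e_sc
                        phi = 2.0 * math.pi * np.random.random()
                        if e_el > 0.0:
                            ctc = min(1.0, max(-1.0, ct))
                            tan_half = math.tan(0.5 * math.acos(ctc))
                            if tan_half > 1e-12:
                                th_e = math.atan(
                                    1.0 / ((1.0 + k) * tan_half))
                            else:
                                th_e = 0.5 * math.pi
                            edx, edy, edz = _rotate(dx, dy, dz,
                                                    math.cos(th_e),
                                                    phi + math.pi)
                            escaped += _electron(
                                px, py, pz, edx, edy, edz, e_el, weight,
                                centers, r_outer, r_inner, med_outer,
                                med_inner, cell_start, cell_items,
                                gx0, gy0, gz0, cell, ngx, ngy, ngz,
                                wkind, wr, wh, air_idx,
                                st_grid, st_log, rg_log, st_len,
                                electron_step, e_cutoff, detour_c, acc,
                                first_med, anchor_mode, anchor_x,
                                anchor_y, anchor_z, bin_width,
                                hist_sio2_idx, hist_zno_idx, hist_first_s,
                                hist_first_z, record_events, ev_cap,
                                ev_hist, ev_xyz, ev_de, ev_med, h,
                                ev_n_arr)
                        dx, dy, dz = _rotate(dx, dy, dz, ct, phi)
                        e = e_sc
                        if e <= photon_cutoff:
                            _deposit(m, e, px, py, pz, weight, acc,
                                     first_med, anchor_mode, anchor_x,
                                     anchor_y, anchor_z, centers,
                                     cell_start, cell_items, gx0, gy0,
                                     gz0, cell, ngx, ngy, ngz, bin_width,
                                     hist_sio2_idx, hist_zno_idx,
                                     hist_first_s, hist_first_z,
                                     record_events, ev_cap, ev_hist,
                                     ev_xyz, ev_de, ev_med, h, ev_n_arr)
                            break
                    else:
                        # -------- coherent (Rayleigh) ------------------
                        ct = _thomson_cos()
                        phi = 2.0 * math.pi * np.random.random()
                        dx, dy, dz = _rotate(dx, dy, dz, ct, phi)
                        # energy unchanged; continue flight
            break  # leave the single-pass block

        out_weight[h] = weight
        out_first_med[h] = first_med
        out_first_body[h] = first_body
        for m in range(n_media):
            out_edep[h, m] = acc[m]
        out_escaped[h] = escaped
        out_flag[h] = flag
    return ev_n_arr[0]
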