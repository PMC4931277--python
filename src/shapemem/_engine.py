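"""Fused Metropolis + particle-layer kernel (numba) for ensemble runs.

Numerically identical to the readable reference path
(:mod:`shapemem.cpm` + :mod:`shapemem.particles`) specialized to the
single-cell rounding phase: one cell (id 1) in medium (id 0) with a frozen
one-site medium frame.  Per accepted copy the local boundary mask is
repaired and stranded particles are moved to a nearest boundary site; per
mcs each particle layer takes one annulus random-walk step.  Particles are
held in per-site doubly-linked lists so the stranded-particle lookup after
a copy is O(occupants of the seven affected sites), not O(N).

The kernel draws from numba's global PRNG, seeded once per call, so runs
are reproducible given (inputs, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._mcsurface import AREA_TABLE, window_configs

__all__ = ["simulate_rounding", "STATUS_DIVIDED", "STATUS_NO_DIVISION",
           "STATUS_ANNIHILATED"]

STATUS_DIVIDED = 0
STATUS_NO_DIVISION = 1
STATUS_ANNIHILATED = 2

CELL = 1


@njit(cache=True)
def _init_caches(ids, bmask):
    """Volume (sites) and 6-face boundary mask of cell 1."""
    nx, ny, nz = ids.shape
    v = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if ids[x, y, z] != CELL:
                    bmask[x, y, z] = 0
                    continue
                v += 1
                bmask[x, y, z] = 1 if _is_boundary(ids, x, y, z) else 0
    return v


@njit(cache=True, inline="always")
def _is_boundary(ids, x, y, z):
    """Recompute boundary status of one site (cell site with an unlike face)."""
    if ids[x, y, z] != CELL:
        return False
    nx, ny, nz = ids.shape
    if x == 0 or ids[x - 1, y, z] != CELL:
        return True
    if x == nx - 1 or ids[x + 1, y, z] != CELL:
        return True
    if y == 0 or ids[x, y - 1, z] != CELL:
        return True
    if y == ny - 1 or ids[x, y + 1, z] != CELL:
        return True
    if z == 0 or ids[x, y, z - 1] != CELL:
        return True
    if z == nz - 1 or ids[x, y, z + 1] != CELL:
        return True
    return False


@njit(cache=True)
def _nearest_boundary(bmask, px, py, pz):
    """Uniform choice among the boundary sites nearest (Euclidean) to a site.

    Scans cubes of growing Chebyshev radius; Euclidean >= Chebyshev, so the
    best candidate within radius R is globally nearest once best_d2 <= R^2.
    """
    nx, ny, nz = bmask.shape
    max_r = nx
    if ny > max_r:
        max_r = ny
    if nz > max_r:
        max_r = nz
    radius = 1
    while radius <= max_r:
        best_d2 = 1 << 60
        count = 0
        x0 = max(px - radius, 0)
        x1 = min(px + radius, nx - 1)
        y0 = max(py - radius, 0)
        y1 = min(py + radius, ny - 1)
        z0 = max(pz - radius, 0)
        z1 = min(pz + radius, nz - 1)
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                for z in range(z0, z1 + 1):
                    if bmask[x, y, z] == 0:
                        continue
                    d2 = (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2
                    if d2 < best_d2:
                        best_d2 = d2
                        count = 1
                    elif d2 == best_d2:
                        count += 1
        if count > 0 and best_d2 <= radius * radius:
            pick = np.random.randint(count)
            seen = 0
            for x in range(x0, x1 + 1):
                for y in range(y0, y1 + 1):
                    for z in range(z0, z1 + 1):
                        if bmask[x, y, z] == 0:
                            continue
                        d2 = (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2
                        if d2 == best_d2:
                            if seen == pick:
                                return x, y, z
                            seen += 1
        if count > 0:
            r_need = int(np.sqrt(best_d2)) + 1
            radius = r_need if r_need > radius else radius + 1
        else:
            radius += radius  # grow fast through empty space
    return -1, -1, -1


@njit(cache=True, inline="always")
def _lin(x, y, z, ny, nz):
    return (x * ny + y) * nz + z


@njit(cache=True)
def _list_remove(k, pos, head, prv, nxt, ny, nz):
    site = _lin(pos[k, 0], pos[k, 1], pos[k, 2], ny, nz)
    p = prv[k]
    n = nxt[k]
    if p >= 0:
        nxt[p] = n
    else:
        head[site] = n
    if n >= 0:
        prv[n] = p


@njit(cache=True)
def _list_insert(k, x, y, z, pos, head, prv, nxt, ny, nz):
    pos[k, 0] = x
    pos[k, 1] = y
    pos[k, 2] = z
    site = _lin(x, y, z, ny, nz)
    h = head[site]
    nxt[k] = h
    prv[k] = -1
    if h >= 0:
        prv[h] = k
    head[site] = k


@njit(cache=True)
def _reattach_site(ids, bmask, sx, sy, sz, pos, head, prv, nxt, scratch):
    """Move every particle stranded at one site to a nearest boundary site.

    Returns False when the cell has no boundary left (annihilated).
    """
    ny = ids.shape[1]
    nz = ids.shape[2]
    if bmask[sx, sy, sz] != 0:
        return True  # still a valid attachment site
    site = _lin(sx, sy, sz, ny, nz)
    k = head[site]
    n_here = 0
    while k >= 0:
        scratch[n_here] = k
        n_here += 1
        k = nxt[k]
    for i in range(n_here):
        k = scratch[i]
        tx, ty, tz = _nearest_boundary(bmask, sx, sy, sz)
        if tx < 0:
            return False
        _list_remove(k, pos, head, prv, nxt, ny, nz)
        _list_insert(k, tx, ty, tz, pos, head, prv, nxt, ny, nz)
    return True


@njit(cache=True)
def _diffuse_layer(ids, bmask, step, pos, head, prv, nxt):
    """One annulus random-walk step for every particle of one layer.

    Candidates are boundary sites at Euclidean distance in the open
    interval (step - 0.5, step + 0.5); an empty annulus leaves the particle
    in place.  Returns the number of stuck particles this mcs.
    """
    n = pos.shape[0]
    if n == 0 or step <= 0.0:
        return 0
    nx, ny, nz = ids.shape
    lo2 = (step - 0.5) * (step - 0.5)
    hi2 = (step + 0.5) * (step + 0.5)
    radius = int(np.ceil(step + 0.5))
    stuck = 0
    for k in range(n):
        px, py, pz = pos[k, 0], pos[k, 1], pos[k, 2]
        x0 = max(px - radius, 0)
        x1 = min(px + radius, nx - 1)
        y0 = max(py - radius, 0)
        y1 = min(py + radius, ny - 1)
        z0 = max(pz - radius, 0)
        z1 = min(pz + radius, nz - 1)
        count = 0
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                for z in range(z0, z1 + 1):
                    if bmask[x, y, z] == 0:
                        continue
                    d2 = float((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2)
                    if d2 > lo2 and d2 < hi2:
                        count += 1
        if count == 0:
            stuck += 1
            continue
        pick = np.random.randint(count)
        seen = 0
        done = False
        for x in range(x0, x1 + 1):
            if done:
                break
            for y in range(y0, y1 + 1):
                if done:
                    break
                for z in range(z0, z1 + 1):
                    if bmask[x, y, z] == 0:
                        continue
                    d2 = float((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2)
                    if d2 > lo2 and d2 < hi2:
                        if seen == pick:
                            _list_remove(k, pos, head, prv, nxt, ny, nz)
                            _list_insert(k, x, y, z, pos, head, prv, nxt, ny, nz)
                            done = True
                            break
                        seen += 1
    return stuck


@njit(cache=True)
def _rounding_loop(
    ids,
    bmask,
    wcfg, area_table,
    bpos, bhead, bprv, bnxt,
    ypos, yhead, yprv, ynxt,
    step_blue, step_yellow,
    j_cm, lam_v, lam_s, temp,
    v_target, s_target, s_div,
    max_mcs, seed,
    v_hist, s_hist,
):
    np.random.seed(seed)
    nx, ny, nz = ids.shape
    n_sites = nx * ny * nz
    v = _init_caches(ids, bmask)
    s = 0.0
    for i in range(wcfg.shape[0]):
        for j in range(wcfg.shape[1]):
            for k in range(wcfg.shape[2]):
                s += area_table[wcfg[i, j, k]]
    scratch = np.empty(bpos.shape[0] + ypos.shape[0], dtype=np.int64)
    stuck = 0
    for mcs in range(max_mcs):
        for _ in range(n_sites):
            tx = np.random.randint(nx)
            ty = np.random.randint(ny)
            tz = np.random.randint(nz)
            if tx < 1 or tx > nx - 2 or ty < 1 or ty > ny - 2 or tz < 1 or tz > nz - 2:
                continue  # frozen medium frame
            d = np.random.randint(26)
            if d >= 13:
                d += 1  # skip the null offset in the 3x3x3 block
            sx = tx + d // 9 - 1
            sy = ty + (d // 3) % 3 - 1
            sz = tz + d % 3 - 1
            old = ids[tx, ty, tz]
            new = ids[sx, sy, sz]
            if old == new:
                continue
            # local energy change: interfacial + volume + surface terms
            dj = 0.0
            for face in range(6):
                if face == 0:
                    ux, uy, uz = tx - 1, ty, tz
                elif face == 1:
                    ux, uy, uz = tx + 1, ty, tz
                elif face == 2:
                    ux, uy, uz = tx, ty - 1, tz
                elif face == 3:
                    ux, uy, uz = tx, ty + 1, tz
                elif face == 4:
                    ux, uy, uz = tx, ty, tz - 1
                else:
                    ux, uy, uz = tx, ty, tz + 1
                nb = ids[ux, uy, uz]
                if nb != new:
                    dj += j_cm
                if nb != old:
                    dj -= j_cm
            # marching-cubes area change: the 8 windows containing the site
            ds = 0.0
            for i in range(2):
                for j in range(2):
                    for k in range(2):
                        w = wcfg[tx + i, ty + j, tz + k]
                        bit = (1 - i) << 2 | (1 - j) << 1 | (1 - k)
                        ds += area_table[w ^ (1 << bit)] - area_table[w]
            dv = 1 if new == CELL else -1
            dh = (
                dj
                + lam_v * ((v + dv - v_target) ** 2 - (v - v_target) ** 2)
                + lam_s * ((s + ds - s_target) ** 2 - (s - s_target) ** 2)
            )
            if dh >= 0.0 and np.random.random() >= np.exp(-dh / temp):
                continue
            # accept
            ids[tx, ty, tz] = new
            v += dv
            s += ds
            for i in range(2):
                for j in range(2):
                    for k in range(2):
                        bit = (1 - i) << 2 | (1 - j) << 1 | (1 - k)
                        wcfg[tx + i, ty + j, tz + k] ^= np.uint8(1 << bit)
            if v <= 0:
                return STATUS_ANNIHILATED, mcs, v, s, stuck
            # repair boundary mask at the 7 affected sites, then particles
            bmask[tx, ty, tz] = 1 if _is_boundary(ids, tx, ty, tz) else 0
            bmask[tx - 1, ty, tz] = 1 if _is_boundary(ids, tx - 1, ty, tz) else 0
            bmask[tx + 1, ty, tz] = 1 if _is_boundary(ids, tx + 1, ty, tz) else 0
            bmask[tx, ty - 1, tz] = 1 if _is_boundary(ids, tx, ty - 1, tz) else 0
            bmask[tx, ty + 1, tz] = 1 if _is_boundary(ids, tx, ty + 1, tz) else 0
            bmask[tx, ty, tz - 1] = 1 if _is_boundary(ids, tx, ty, tz - 1) else 0
            bmask[tx, ty, tz + 1] = 1 if _is_boundary(ids, tx, ty, tz + 1) else 0
            for a in range(7):
                if a == 0:
                    ux, uy, uz = tx, ty, tz
                elif a == 1:
                    ux, uy, uz = tx - 1, ty, tz
                elif a == 2:
                    ux, uy, uz = tx + 1, ty, tz
                elif a == 3:
                    ux, uy, uz = tx, ty - 1, tz
                elif a == 4:
                    ux, uy, uz = tx, ty + 1, tz
                elif a == 5:
                    ux, uy, uz = tx, ty, tz - 1
                else:
                    ux, uy, uz = tx, ty, tz + 1
                if not _reattach_site(ids, bmask, ux, uy, uz,
                                      bpos, bhead, bprv, bnxt, scratch):
                    return STATUS_ANNIHILATED, mcs, v, s, stuck
                if not _reattach_site(ids, bmask, ux, uy, uz,
                                      ypos, yhead, yprv, ynxt, scratch):
                    return STATUS_ANNIHILATED, mcs, v, s, stuck
        v_hist[mcs] = v
        s_hist[mcs] = s
        if s_div > 0.0 and s <= s_div:
            return STATUS_DIVIDED, mcs + 1, v, s, stuck
        stuck += _diffuse_layer(ids, bmask, step_blue, bpos, bhead, bprv, bnxt)
        stuck += _diffuse_layer(ids, bmask, step_yellow, ypos, yhead, yprv, ynxt)
    return STATUS_NO_DIVISION, max_mcs, v, s, stuck


def _build_lists(pos: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = shape
    head = np.full(nx * ny * nz, -1, dtype=np.int64)
    n = len(pos)
    prv = np.full(n, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        site = (pos[k, 0] * ny + pos[k, 1]) * nz + pos[k, 2]
        h = head[site]
        nxt[k] = h
        if h >= 0:
            prv[h] = k
        head[site] = k
    return head, prv, nxt


def simulate_rounding(
    cell_ids: np.ndarray,
    blue_positions: np.ndarray,
    yellow_positions: np.ndarray,
    step_blue: float,
    step_yellow: float,
    j_cell_medium: float,
    lambda_v: float,
    lambda_s: float,
    temperature: float,
    target_volume: float,
    target_surface: float,
    s_division: float,
    max_mcs: int,
    seed: int,
) -> dict:
    """Run mitotic rounding until division triggers or ``max_mcs`` elapses.

    Mutates nothing: works on copies and returns a dict with the evolved
    lattice, final particle positions, per-mcs volume/surface histories and
    the division status/time.
    """
    ids = np.ascontiguousarray(cell_ids, dtype=np.int32).copy()
    bmask = np.zeros_like(ids, dtype=np.uint8)
    wcfg = window_configs(ids == 1)
    bpos = np.ascontiguousarray(blue_positions, dtype=np.int64).copy().reshape(-1, 3)
    ypos = np.ascontiguousarray(yellow_positions, dtype=np.int64).copy().reshape(-1, 3)
    bhead, bprv, bnxt = _build_lists(bpos, ids.shape)
    yhead, yprv, ynxt = _build_lists(ypos, ids.shape)
    v_hist = np.zeros(max_mcs, dtype=np.int64)
    s_hist = np.zeros(max_mcs, dtype=np.float64)
    status, mcs, v, s, stuck = _rounding_loop(
        ids, bmask,
        wcfg, AREA_TABLE,
        bpos, bhead, bprv, bnxt,
        ypos, yhead, yprv, ynxt,
        float(step_blue), float(step_yellow),
        float(j_cell_medium), float(lambda_v), float(lambda_s),
        float(temperature),
        float(target_volume), float(target_surface), float(s_division),
        int(max_mcs), int(seed) & 0x7FFFFFFF,
        v_hist, s_hist,
    )
    n_done = mcs
    return {
        "status": status,
        "mcs": int(mcs),
        "cell_ids": ids,
        "blue_positions": bpos,
        "yellow_positions": ypos,
        "volume": int(v),
        "surface": float(s),
        "v_hist": v_hist[:n_done],
        "s_hist": s_hist[:n_done],
        "stuck_events": int(stuck),
    }
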