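"""Numba kernel for band-wise Monte Carlo path tracing.

One geometric path is traced per ray; the 60-band spectrum travels along
it as a weight vector that is attenuated multiplicatively at every
interaction (per-band absorptance tallied, survival split between
reflection and transmission by importance weights).  Photon conservation
is therefore exact per band up to floating-point rounding: absorbed +
floor + stems + escaped + truncated = emitted.

Acceleration is a uniform voxel grid traversed with a 3-DDA; mirror
walls and the absorbing floor are handled analytically.  The RNG is a
counter-based splitmix64-seeded xorshift64*, one independent stream per
ray, so results are bit-reproducible for a given seed regardless of
batching.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS_T = 1e-9
_EPS_OFFSET = 1e-6
_MAX_WALL_BOUNCES = 1000


@njit(cache=True)
def _seed_stream(seed, ray):
    z = np.uint64(seed) ^ (np.uint64(ray + 1) * np.uint64(0x9E3779B97F4A7C15))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def _next_uniform(state):
    s = state
    s ^= s << np.uint64(13)
    s ^= s >> np.uint64(7)
    s ^= s << np.uint64(17)
    u = (s * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)
    return s, float(u) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _ray_triangle(ox, oy, oz, dx, dy, dz, v0, e1, e2, i):
    """Möller–Trumbore; returns hit distance or -1."""
    px = dy * e2[i, 2] - dz * e2[i, 1]
    py = dz * e2[i, 0] - dx * e2[i, 2]
    pz = dx * e2[i, 1] - dy * e2[i, 0]
    det = e1[i, 0] * px + e1[i, 1] * py + e1[i, 2] * pz
    if -1e-14 < det < 1e-14:
        return -1.0
    inv = 1.0 / det
    tx = ox - v0[i, 0]
    ty = oy - v0[i, 1]
    tz = oz - v0[i, 2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return -1.0
    qx = ty * e1[i, 2] - tz * e1[i, 1]
    qy = tz * e1[i, 0] - tx * e1[i, 2]
    qz = tx * e1[i, 1] - ty * e1[i, 0]
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return -1.0
    t = (e2[i, 0] * qx + e2[i, 1] * qy + e2[i, 2] * qz) * inv
    if t <= _EPS_T:
        return -1.0
    return t


@njit(cache=True)
def _nearest_hit(ox, oy, oz, dx, dy, dz, t_limit,
                 v0, e1, e2,
                 grid_origin, cell_size, grid_dims, cell_start, cell_items):
    """Nearest triangle along the ray within t_limit, via DDA grid traversal."""
    best_t = -1.0
    best_i = -1
    nx, ny, nz = grid_dims[0], grid_dims[1], grid_dims[2]
    if nx == 0:
        return best_t, best_i
    gx1 = grid_origin[0] + nx * cell_size[0]
    gy1 = grid_origin[1] + ny * cell_size[1]
    gz1 = grid_origin[2] + nz * cell_size[2]

    # clip ray to the grid bounding box
    t0 = 0.0
    t1 = t_limit
    for axis in range(3):
        o = ox if axis == 0 else (oy if axis == 1 else oz)
        d = dx if axis == 0 else (dy if axis == 1 else dz)
        lo = grid_origin[axis]
        hi = gx1 if axis == 0 else (gy1 if axis == 1 else gz1)
        if abs(d) < 1e-15:
            if o < lo or o > hi:
                return best_t, best_i
        else:
            ta = (lo - o) / d
            tb = (hi - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 > t1:
        return best_t, best_i

    t_enter = t0 + 1e-12
    px = ox + t_enter * dx
    py = oy + t_enter * dy
    pz = oz + t_enter * dz
    ix = int((px - grid_origin[0]) / cell_size[0])
    iy = int((py - grid_origin[1]) / cell_size[1])
    iz = int((pz - grid_origin[2]) / cell_size[2])
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= nx:
        ix = nx - 1
    if iy >= ny:
        iy = ny - 1
    if iz >= nz:
        iz = nz - 1

    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    step_z = 1 if dz > 0 else -1
    big = 1e30
    if abs(dx) > 1e-15:
        nxt = grid_origin[0] + (ix + (1 if dx > 0 else 0)) * cell_size[0]
        tmax_x = (nxt - ox) / dx
        tdel_x = cell_size[0] / abs(dx)
    else:
        tmax_x = big
        tdel_x = big
    if abs(dy) > 1e-15:
        nxt = grid_origin[1] + (iy + (1 if dy > 0 else 0)) * cell_size[1]
        tmax_y = (nxt - oy) / dy
        tdel_y = cell_size[1] / abs(dy)
    else:
        tmax_y = big
        tdel_y = big
    if abs(dz) > 1e-15:
        nxt = grid_origin[2] + (iz + (1 if dz > 0 else 0)) * cell_size[2]
        tmax_z = (nxt - oz) / dz
        tdel_z = cell_size[2] / abs(dz)
    else:
        tmax_z = big
        tdel_z = big

    while True:
        cell = (ix * ny + iy) * nz + iz
        s = cell_start[cell]
        e = cell_start[cell + 1]
        for k in range(s, e):
            i = cell_items[k]
            t = _ray_triangle(ox, oy, oz, dx, dy, dz, v0, e1, e2, i)
            if t > 0.0 and t <= t_limit and (best_t < 0.0 or t < best_t):
                best_t = t
                best_i = i
        t_exit = min(tmax_x, min(tmax_y, tmax_z))
        if best_t > 0.0 and best_t <= t_exit + 1e-12:
            return best_t, best_i
        if t_exit > t1:
            return best_t, best_i
        if tmax_x <= tmax_y and tmax_x <= tmax_z:
            ix += step_x
            tmax_x += tdel_x
            if ix < 0 or ix >= nx:
                return best_t, best_i
        elif tmax_y <= tmax_z:
            iy += step_y
            tmax_y += tdel_y
            if iy < 0 or iy >= ny:
                return best_t, best_i
        else:
            iz += step_z
            tmax_z += tdel_z
            if iz < 0 or iz >= nz:
                return best_t, best_i


@njit(cache=True)
def _cosine_hemisphere(nx_, ny_, nz_, state):
    """Cosine-weighted direction in the hemisphere around unit normal n."""
    state, u1 = _next_uniform(state)
    state, u2 = _next_uniform(state)
    r = np.sqrt(u1)
    phi = 2.0 * np.pi * u2
    lx = r * np.cos(phi)
    ly = r * np.sin(phi)
    lz = np.sqrt(max(0.0, 1.0 - u1))
    # orthonormal frame around n
    if abs(nz_) < 0.999:
        bx, by, bz = -ny_, nx_, 0.0
    else:
        bx, by, bz = 1.0, 0.0, 0.0
    nb = np.sqrt(bx * bx + by * by + bz * bz)
    bx /= nb
    by /= nb
    bz /= nb
    cx = ny_ * bz - nz_ * by
    cy = nz_ * bx - nx_ * bz
    cz = nx_ * by - ny_ * bx
    dx = lx * bx + ly * cx + lz * nx_
    dy = lx * by + ly * cy + lz * ny_
    dz = lx * bz + ly * cz + lz * nz_
    return state, dx, dy, dz


@njit(cache=True)
def trace_kernel(v0, e1, e2, tri_norm,
                 leaflet_id, optics_index, surface_class,
                 optics_R, optics_T, optics_R_ab, optics_T_ab,
                 grid_origin, cell_size, grid_dims, cell_start, cell_items,
                 box, z_ceiling,
                 origins, dirs, w0,
                 max_recursions, seed,
                 leaf_tally, class_tally):
    """Trace all rays; accumulate per-(leaflet, band) and per-class tallies.

    class_tally rows: 0 floor, 1 stems, 2 escaped, 3 truncated.
    """
    n_rays = origins.shape[0]
    n_bands = w0.shape[0]
    x0, x1, y0, y1 = box[0], box[1], box[2], box[3]
    w = np.empty(n_bands)

    for ray in range(n_rays):
        state = _seed_stream(seed, ray)
        ox, oy, oz = origins[ray, 0], origins[ray, 1], origins[ray, 2]
        dx, dy, dz = dirs[ray, 0], dirs[ray, 1], dirs[ray, 2]
        for b in range(n_bands):
            w[b] = w0[b]
        bounces = 0
        wall_bounces = 0

        while True:
            # analytic boundaries: mirror walls, floor, open ceiling
            t_wall = 1e30
            wall_axis = -1
            if dx > 1e-15:
                t = (x1 - ox) / dx
                if t < t_wall:
                    t_wall = t
                    wall_axis = 0
            elif dx < -1e-15:
                t = (x0 - ox) / dx
                if t < t_wall:
                    t_wall = t
                    wall_axis = 0
            if dy > 1e-15:
                t = (y1 - oy) / dy
                if t < t_wall:
                    t_wall = t
                    wall_axis = 1
            elif dy < -1e-15:
                t = (y0 - oy) / dy
                if t < t_wall:
                    t_wall = t
                    wall_axis = 1
            t_floor = 1e30
            if dz < -1e-15:
                t_floor = -oz / dz
            t_ceil = 1e30
            if dz > 1e-15:
                t_ceil = (z_ceiling - oz) / dz
            t_limit = min(t_wall, min(t_floor, t_ceil)) + 1e-9

            t_hit, i_hit = _nearest_hit(ox, oy, oz, dx, dy, dz, t_limit,
                                        v0, e1, e2,
                                        grid_origin, cell_size, grid_dims,
                                        cell_start, cell_items)

            if t_hit > 0.0 and t_hit <= min(t_wall, min(t_floor, t_ceil)):
                # surface interaction
                ox += t_hit * dx
                oy += t_hit * dy
                oz += t_hit * dz
                oid = optics_index[i_hit]
                nxr, nyr, nzr = tri_norm[i_hit, 0], tri_norm[i_hit, 1], tri_norm[i_hit, 2]
                # incident on the side the ray comes from
                front = (dx * nxr + dy * nyr + dz * nzr) < 0.0
                if not front:
                    nxr, nyr, nzr = -nxr, -nyr, -nzr
                # adaxial side is the +normal (front) side
                if front:
                    R = optics_R[oid]
                    T = optics_T[oid]
                else:
                    R = optics_R_ab[oid]
                    T = optics_T_ab[oid]

                lid = leaflet_id[i_hit]
                surv = 0.0
                refl = 0.0
                for b in range(n_bands):
                    rt = R[b] + T[b]
                    absorbed = w[b] * (1.0 - rt)
                    if lid >= 0:
                        leaf_tally[lid, b] += absorbed
                    else:
                        class_tally[1, b] += absorbed
                    w[b] *= rt
                    surv += w[b]
                    if rt > 0.0:
                        refl += w[b] * (R[b] / rt)

                bounces += 1
                if surv <= 1e-14:
                    for b in range(n_bands):
                        class_tally[3, b] += w[b]
                    break
                if bounces >= max_recursions:
                    for b in range(n_bands):
                        class_tally[3, b] += w[b]
                    break

                p_refl = refl / surv
                state, u = _next_uniform(state)
                if u < p_refl:
                    # reflect on the incident side
                    inv_p = 1.0 / p_refl
                    for b in range(n_bands):
                        rt = R[b] + T[b]
                        if rt > 0.0:
                            w[b] *= (R[b] / rt) * inv_p
                    side_nx, side_ny, side_nz = nxr, nyr, nzr
                else:
                    inv_p = 1.0 / (1.0 - p_refl)
                    for b in range(n_bands):
                        rt = R[b] + T[b]
                        if rt > 0.0:
                            w[b] *= (T[b] / rt) * inv_p
                    side_nx, side_ny, side_nz = -nxr, -nyr, -nzr

                state, dx, dy, dz = _cosine_hemisphere(side_nx, side_ny, side_nz, state)
                ox += _EPS_OFFSET * side_nx
                oy += _EPS_OFFSET * side_ny
                oz += _EPS_OFFSET * side_nz
            elif t_floor <= t_wall and t_floor <= t_ceil:
                for b in range(n_bands):
                    class_tally[0, b] += w[b]
                break
            elif t_ceil < t_wall:
                for b in range(n_bands):
                    class_tally[2, b] += w[b]
                break
            else:
                # specular mirror wall, lossless
                ox += t_wall * dx
                oy += t_wall * dy
                oz += t_wall * dz
                if wall_axis == 0:
                    dx = -dx
                    ox = min(max(ox, x0 + 1e-9), x1 - 1e-9)
                else:
                    dy = -dy
                    oy = min(max(oy, y0 + 1e-9), y1 - 1e-9)
                wall_bounces += 1
                if wall_bounces >= _MAX_WALL_BOUNCES:
                    for b in range(n_bands):
                        class_tally[3, b] += w[b]
                    break
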