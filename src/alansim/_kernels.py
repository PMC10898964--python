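"""Numba-compiled core of the MCRT engine.

Everything here operates on plain ndarrays prepared by :mod:`alansim.engine`.
The PCG32 stream implemented in `_rng.py` is mirrored here bit-for-bit so
compiled and interpreted paths draw identical variates from the same seed.
"""
from __future__ import annotations

import numpy as np
from numba import njit

SPEED_OF_LIGHT = 299792458.0
RAY_EPS = 1e-9
MAX_EVENTS = 1_000_000

U64 = np.uint64
_PCG_MULT = U64(6364136223846793005)
_PCG_INC = U64(1442695040888963407)


# ---------------------------------------------------------------------------
# PCG32 / splitmix64
# ---------------------------------------------------------------------------

@njit(cache=True)
def splitmix64(x):
    x = U64(x) + U64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> U64(27))) * U64(0x94D049BB133111EB)
    return x ^ (x >> U64(31))


@njit(cache=True)
def pcg_init(seed):
    """State from a 64-bit stream seed (matches _rng.PcgStream)."""
    return splitmix64(U64(seed)) | U64(1)


@njit(cache=True)
def pcg_next(state):
    """Advance; returns (new_state, uniform in [0, 1))."""
    s = state
    new_state = s * _PCG_MULT + _PCG_INC
    xorshifted = (((s >> U64(18)) ^ s) >> U64(27)) & U64(0xFFFFFFFF)
    rot = s >> U64(59)
    out = ((xorshifted >> rot) | (xorshifted << ((U64(0) - rot) & U64(31)))) & U64(0xFFFFFFFF)
    return new_state, np.float64(out) * 2.0**-32


@njit(cache=True)
def pcg_open(state):
    """Advance; returns (new_state, uniform in (0, 1])."""
    state, u = pcg_next(state)
    return state, u + 2.0**-32 if u + 2.0**-32 <= 1.0 else 1.0


# ---------------------------------------------------------------------------
# ray-triangle and octree traversal
# ---------------------------------------------------------------------------

@njit(cache=True)
def ray_triangle(ox, oy, oz, dx, dy, dz, v0, v1, v2):
    """Moller-Trumbore; returns hit distance or inf."""
    e1x = v1[0] - v0[0]; e1y = v1[1] - v0[1]; e1z = v1[2] - v0[2]
    e2x = v2[0] - v0[0]; e2y = v2[1] - v0[1]; e2z = v2[2] - v0[2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -1e-14 < det < 1e-14:
        return np.inf
    inv = 1.0 / det
    tx = ox - v0[0]; ty = oy - v0[1]; tz = oz - v0[2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-12 or u > 1.0 + 1e-12:
        return np.inf
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return np.inf
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= RAY_EPS:
        return np.inf
    return t


@njit(cache=True)
def _ray_box(ox, oy, oz, idx, idy, idz, bmin, bmax, t_best):
    """Slab test; True if the box is intersected at distance < t_best."""
    t0 = 0.0
    t1 = t_best
    tx0 = (bmin[0] - ox) * idx
    tx1 = (bmax[0] - ox) * idx
    if tx0 > tx1:
        tx0, tx1 = tx1, tx0
    t0 = max(t0, tx0)
    t1 = min(t1, tx1)
    ty0 = (bmin[1] - oy) * idy
    ty1 = (bmax[1] - oy) * idy
    if ty0 > ty1:
        ty0, ty1 = ty1, ty0
    t0 = max(t0, ty0)
    t1 = min(t1, ty1)
    tz0 = (bmin[2] - oz) * idz
    tz1 = (bmax[2] - oz) * idz
    if tz0 > tz1:
        tz0, tz1 = tz1, tz0
    t0 = max(t0, tz0)
    t1 = min(t1, tz1)
    return t0 <= t1


@njit(cache=True)
def nearest_hit(ox, oy, oz, dx, dy, dz,
                tri_v0, tri_v1, tri_v2,
                node_min, node_max, node_child0,
                leaf_start, leaf_count, leaf_tris):
    """Nearest ray-triangle hit via octree; returns (distance, triangle id)."""
    best_t = np.inf
    best_tri = -1
    n_nodes = node_min.shape[0]
    if n_nodes == 0:
        return best_t, best_tri
    idx = 1.0 / dx if dx != 0.0 else np.inf
    idy = 1.0 / dy if dy != 0.0 else np.inf
    idz = 1.0 / dz if dz != 0.0 else np.inf
    stack = np.empty(4096, dtype=np.int64)
    sp = 0
    stack[sp] = 0
    sp += 1
    while sp > 0:
        sp -= 1
        node = stack[sp]
        if not _ray_box(ox, oy, oz, idx, idy, idz, node_min[node], node_max[node], best_t):
            continue
        c0 = node_child0[node]
        if c0 < 0:
            s = leaf_start[node]
            for i in range(leaf_count[node]):
                tri = leaf_tris[s + i]
                t = ray_triangle(ox, oy, oz, dx, dy, dz, tri_v0[tri], tri_v1[tri], tri_v2[tri])
                if t < best_t:
                    best_t = t
                    best_tri = tri
        else:
            for k in range(8):
                stack[sp] = c0 + k
                sp += 1
    return best_t, best_tri


@njit(cache=True)
def triangle_normal_against(tri_v0, tri_v1, tri_v2, tri, dx, dy, dz):
    """Unit normal of triangle `tri`, oriented to oppose direction d."""
    v0 = tri_v0[tri]; v1 = tri_v1[tri]; v2 = tri_v2[tri]
    e1x = v1[0] - v0[0]; e1y = v1[1] - v0[1]; e1z = v1[2] - v0[2]
    e2x = v2[0] - v0[0]; e2y = v2[1] - v0[1]; e2z = v2[2] - v0[2]
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    norm = (nx * nx + ny * ny + nz * nz) ** 0.5
    nx /= norm; ny /= norm; nz /= norm
    if nx * dx + ny * dy + nz * dz > 0.0:
        nx = -nx; ny = -ny; nz = -nz
    return nx, ny, nz


# ---------------------------------------------------------------------------
# direction sampling helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def tangent_frame(nx, ny, nz):
    """Orthonormal (b1, b2) perpendicular to unit n (branchless ONB)."""
    if nz < -0.9999999:
        return 0.0, -1.0, 0.0, -1.0, 0.0, 0.0
    a = 1.0 / (1.0 + nz)
    b = -nx * ny * a
    return 1.0 - nx * nx * a, b, -nx, b, 1.0 - ny * ny * a, -ny


@njit(cache=True)
def cosine_hemisphere(nx, ny, nz, u1, u2):
    """Cosine-weighted direction about normal n."""
    r = np.sqrt(u1)
    phi = 2.0 * np.pi * u2
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    z = np.sqrt(max(0.0, 1.0 - u1))
    b1x, b1y, b1z, b2x, b2y, b2z = tangent_frame(nx, ny, nz)
    return (x * b1x + y * b2x + z * nx,
            x * b1y + y * b2y + z * ny,
            x * b1z + y * b2z + z * nz)


@njit(cache=True)
def uniform_hemisphere(nx, ny, nz, u1, u2):
    """Uniform direction in the hemisphere about n (fidelity option)."""
    z = u1
    r = np.sqrt(max(0.0, 1.0 - z * z))
    phi = 2.0 * np.pi * u2
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    b1x, b1y, b1z, b2x, b2y, b2z = tangent_frame(nx, ny, nz)
    return (x * b1x + y * b2x + z * nx,
            x * b1y + y * b2y + z * ny,
            x * b1z + y * b2z + z * nz)


@njit(cache=True)
def hg_cosine(g, u):
    """Henyey-Greenstein deflection cosine (isotropic when g = 0)."""
    if abs(g) < 1e-12:
        return 1.0 - 2.0 * u
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - frac * frac) / (2.0 * g)
    return min(1.0, max(-1.0, c))


@njit(cache=True)
def deflect(dx, dy, dz, cos_theta, phi):
    """Rotate direction d by deflection angle theta, azimuth phi about d."""
    sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    b1x, b1y, b1z, b2x, b2y, b2z = tangent_frame(dx, dy, dz)
    cx = np.cos(phi) * sin_theta
    cy = np.sin(phi) * sin_theta
    nxx = cx * b1x + cy * b2x + cos_theta * dx
    nyy = cx * b1y + cy * b2y + cos_theta * dy
    nzz = cx * b1z + cy * b2z + cos_theta * dz
    norm = (nxx * nxx + nyy * nyy + nzz * nzz) ** 0.5
    return nxx / norm, nyy / norm, nzz / norm


@njit(cache=True)
def refract(dx, dy, dz, nx, ny, nz, n1, n2):
    """Snell refraction; returns (dir, crossed).

    `crossed` is False on total internal reflection, in which case the
    returned direction is the specular mirror.
    """
    cosi = -(dx * nx + dy * ny + dz * nz)
    eta = n1 / n2
    sin2t = eta * eta * (1.0 - cosi * cosi)
    if sin2t > 1.0:
        rx = dx + 2.0 * cosi * nx
        ry = dy + 2.0 * cosi * ny
        rz = dz + 2.0 * cosi * nz
        return rx, ry, rz, False
    cost = np.sqrt(1.0 - sin2t)
    tx = eta * dx + (eta * cosi - cost) * nx
    ty = eta * dy + (eta * cosi - cost) * ny
    tz = eta * dz + (eta * cosi - cost) * nz
    norm = (tx * tx + ty * ty + tz * tz) ** 0.5
    return tx / norm, ty / norm, tz / norm, True


# ---------------------------------------------------------------------------
# emission sampling (inverse-CDF tables prepared in Python)
# ---------------------------------------------------------------------------

@njit(cache=True)
def sample_emission_direction(state, az_cdf, az_angles, az_widths, polar_angles, polar_cdfs):
    """Draw (state, local unit direction) from the LID sampler tables."""
    state, u1 = pcg_next(state)
    j = np.searchsorted(az_cdf, u1)
    if j >= az_cdf.shape[0]:
        j = az_cdf.shape[0] - 1
    state, u2 = pcg_next(state)
    theta = az_angles[j] + (u2 - 0.5) * az_widths[j]
    state, u3 = pcg_next(state)
    cdf = polar_cdfs[j]
    K = cdf.shape[0]
    i = np.searchsorted(cdf, u3)
    if i < 1:
        i = 1
    if i > K - 1:
        i = K - 1
    dc = cdf[i] - cdf[i - 1]
    if dc > 0.0:
        phi = polar_angles[i - 1] + (u3 - cdf[i - 1]) / dc * (polar_angles[i] - polar_angles[i - 1])
    else:
        phi = polar_angles[i]
    phi_r = phi * np.pi / 180.0
    th_r = (theta % 360.0) * np.pi / 180.0
    s = np.sin(phi_r)
    return state, s * np.cos(th_r), s * np.sin(th_r), np.cos(phi_r)


@njit(cache=True)
def sample_emission_wavelength(state, spec_wl, spec_f, spec_cdf):
    """Draw (state, wavelength nm) with exact linear-density segment inversion."""
    state, u = pcg_next(state)
    n = spec_wl.shape[0]
    i = np.searchsorted(spec_cdf, u)
    if i < 1:
        i = 1
    if i > n - 1:
        i = n - 1
    mass = spec_cdf[i] - spec_cdf[i - 1]
    if mass <= 0.0:
        return state, spec_wl[i]
    ul = (u - spec_cdf[i - 1]) / mass
    x0 = spec_wl[i - 1]; x1 = spec_wl[i]
    f0 = spec_f[i - 1]; f1 = spec_f[i]
    h = x1 - x0
    area = 0.5 * (f0 + f1) * h
    if area <= 0.0:
        return state, x0 + ul * h
    df = f1 - f0
    if abs(df) < 1e-300:
        return state, x0 + ul * h
    a = df / (2.0 * h)
    disc = f0 * f0 + 4.0 * a * ul * area
    if disc < 0.0:
        disc = 0.0
    t = (-f0 + np.sqrt(disc)) / (2.0 * a)
    if t < 0.0:
        t = 0.0
    if t > h:
        t = h
    return state, x0 + t


# ---------------------------------------------------------------------------
# voxel deposition
# ---------------------------------------------------------------------------

@njit(cache=True)
def deposit_segment_walk(grid, gx0, gy0, gz0, h,
                         px, py, pz, dx, dy, dz, seg_end, dep_coeff):
    """Amanatides-Woo walk from p along d, depositing dep_coeff * chord into
    each voxel crossed, up to parameter seg_end (which may be inf).

    Returns (t_stop, exited) where exited is True if the walk left the grid
    before reaching seg_end; t_stop is the parameter at which it stopped.
    """
    nx, ny, nz = grid.shape
    ix = int(np.floor((px - gx0) / h))
    iy = int(np.floor((py - gy0) / h))
    iz = int(np.floor((pz - gz0) / h))
    if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
        return 0.0, True
    if dx > 0.0:
        step_x = 1; tmax_x = (gx0 + (ix + 1) * h - px) / dx; tdel_x = h / dx
    elif dx < 0.0:
        step_x = -1; tmax_x = (gx0 + ix * h - px) / dx; tdel_x = -h / dx
    else:
        step_x = 0; tmax_x = np.inf; tdel_x = np.inf
    if dy > 0.0:
        step_y = 1; tmax_y = (gy0 + (iy + 1) * h - py) / dy; tdel_y = h / dy
    elif dy < 0.0:
        step_y = -1; tmax_y = (gy0 + iy * h - py) / dy; tdel_y = -h / dy
    else:
        step_y = 0; tmax_y = np.inf; tdel_y = np.inf
    if dz > 0.0:
        step_z = 1; tmax_z = (gz0 + (iz + 1) * h - pz) / dz; tdel_z = h / dz
    elif dz < 0.0:
        step_z = -1; tmax_z = (gz0 + iz * h - pz) / dz; tdel_z = -h / dz
    else:
        step_z = 0; tmax_z = np.inf; tdel_z = np.inf
    t_prev = 0.0
    while True:
        t_next = tmax_x
        axis = 0
        if tmax_y < t_next:
            t_next = tmax_y; axis = 1
        if tmax_z < t_next:
            t_next = tmax_z; axis = 2
        if seg_end <= t_next:
            if seg_end > t_prev:
                grid[ix, iy, iz] += dep_coeff * (seg_end - t_prev)
            return seg_end, False
        if t_next > t_prev:
            grid[ix, iy, iz] += dep_coeff * (t_next - t_prev)
        t_prev = t_next
        if axis == 0:
            ix += step_x; tmax_x += tdel_x
            if ix < 0 or ix >= nx:
                return t_prev, True
        elif axis == 1:
            iy += step_y; tmax_y += tdel_y
            if iy < 0 or iy >= ny:
                return t_prev, True
        else:
            iz += step_z; tmax_z += tdel_z
            if iz < 0 or iz >= nz:
                return t_prev, True


# ---------------------------------------------------------------------------
# full per-source propagation
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_source(
    # geometry
    tri_v0, tri_v1, tri_v2, tri_attr,
    node_min, node_max, node_child0, leaf_start, leaf_count, leaf_tris,
    # attributes (per attribute index)
    attr_spec, attr_spec_refl, attr_diff_refl, attr_iface, diffuse_uniform,
    # materials
    mat_n, mat_mu_s, mat_g,
    # voxel grid
    grid, gx0, gy0, gz0, h,
    # source
    src_x, src_y, src_z, rot,
    az_cdf, az_angles, az_widths, polar_angles, polar_cdfs,
    spec_wl, spec_f, spec_cdf,
    packet_power, n_packets, seed, wl0, wl_step,
):
    """Propagate n_packets from one source; deposits into `grid` in place.

    Returns (n_pruned, n_killed, n_exhausted).
    """
    state = pcg_init(seed)
    n_wl = attr_spec_refl.shape[1]
    vol = h * h * h
    n_pruned = 0
    n_killed = 0
    n_exhausted = 0
    for _ in range(n_packets):
        state, lx, ly, lz = sample_emission_direction(
            state, az_cdf, az_angles, az_widths, polar_angles, polar_cdfs)
        dx = rot[0, 0] * lx + rot[0, 1] * ly + rot[0, 2] * lz
        dy = rot[1, 0] * lx + rot[1, 1] * ly + rot[1, 2] * lz
        dz = rot[2, 0] * lx + rot[2, 1] * ly + rot[2, 2] * lz
        state, wl = sample_emission_wavelength(state, spec_wl, spec_f, spec_cdf)
        wl_idx = int(round((wl - wl0) / wl_step))
        if wl_idx < 0:
            wl_idx = 0
        if wl_idx >= n_wl:
            wl_idx = n_wl - 1
        px = src_x; py = src_y; pz = src_z
        mat = 0
        alive = True
        for _ev in range(MAX_EVENTS):
            mu = mat_mu_s[mat]
            if mu > 0.0:
                state, u = pcg_open(state)
                t_scat = -np.log(u) / mu
            else:
                t_scat = np.inf
            t_surf, tri = nearest_hit(px, py, pz, dx, dy, dz,
                                      tri_v0, tri_v1, tri_v2,
                                      node_min, node_max, node_child0,
                                      leaf_start, leaf_count, leaf_tris)
            seg_end = t_scat if t_scat < t_surf else t_surf
            dep = packet_power * mat_n[mat] / (SPEED_OF_LIGHT * vol)
            t_stop, exited = deposit_segment_walk(
                grid, gx0, gy0, gz0, h, px, py, pz, dx, dy, dz, seg_end, dep)
            if exited:
                n_pruned += 1
                alive = False
                break
            px += dx * seg_end
            py += dy * seg_end
            pz += dz * seg_end
            if t_surf <= t_scat:
                # surface event
                a = tri_attr[tri]
                nxv, nyv, nzv = triangle_normal_against(tri_v0, tri_v1, tri_v2, tri, dx, dy, dz)
                m1 = attr_iface[a, 0]
                if m1 >= 0:
                    m2 = attr_iface[a, 1]
                    other = m2 if mat == m1 else m1
                    rdx, rdy, rdz, crossed = refract(dx, dy, dz, nxv, nyv, nzv,
                                                     mat_n[mat], mat_n[other])
                    dx, dy, dz = rdx, rdy, rdz
                    if crossed:
                        mat = other
                        px -= nxv * RAY_EPS; py -= nyv * RAY_EPS; pz -= nzv * RAY_EPS
                    else:
                        px += nxv * RAY_EPS; py += nyv * RAY_EPS; pz += nzv * RAY_EPS
                else:
                    state, u_mode = pcg_next(state)
                    state, u_surv = pcg_next(state)
                    if u_mode < attr_spec[a]:
                        refl = attr_spec_refl[a, wl_idx]
                        if u_surv < refl:
                            cosi = -(dx * nxv + dy * nyv + dz * nzv)
                            dx += 2.0 * cosi * nxv
                            dy += 2.0 * cosi * nyv
                            dz += 2.0 * cosi * nzv
                        else:
                            n_killed += 1
                            alive = False
                            break
                    else:
                        refl = attr_diff_refl[a, wl_idx]
                        if u_surv < refl:
                            state, u1 = pcg_next(state)
                            state, u2 = pcg_next(state)
                            if diffuse_uniform:
                                dx, dy, dz = uniform_hemisphere(nxv, nyv, nzv, u1, u2)
                            else:
                                dx, dy, dz = cosine_hemisphere(nxv, nyv, nzv, u1, u2)
                        else:
                            n_killed += 1
                            alive = False
                            break
                    px += nxv * RAY_EPS; py += nyv * RAY_EPS; pz += nzv * RAY_EPS
            else:
                # scattering event
                state, u1 = pcg_next(state)
                state, u2 = pcg_next(state)
                cos_t = hg_cosine(mat_g[mat], u1)
                dx, dy, dz = deflect(dx, dy, dz, cos_t, 2.0 * np.pi * u2)
        if alive:
            n_exhausted += 1
    return n_pruned, n_killed, n_exhausted
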