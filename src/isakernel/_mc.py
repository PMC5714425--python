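"""Numba core for the voxelized photon-transport oracle.

Scene geometry is compiled to flat arrays (world frame; all seed axes
parallel to z).  Photons are emitted from the active region, fly with free
paths sampled from the water cross section, and undergo photoelectric
absorption or Klein-Nishina Compton scattering at collision sites.  Seed
components never host collisions; instead each traversed chord multiplies
the photon weight by exp(-(mu_material - mu_parent) * chord), the excess
attenuation over the displaced medium.  Because seeds only modify weights
and never consume random numbers, runs with and without dummy seeds share
identical trajectories for a fixed RNG seed (common random numbers).

Kerma is scored with a track-length estimator in water:
tally += weight * chord * E * (mu_en/rho)_water per voxel, normalized per
history and per voxel volume by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# shape codes
CYL, SPH, HEMI, FRUSTUM = 0, 1, 2, 3
# physics codes
PRIMARY_ONLY, COMPTON_PE = 0, 1

MAX_INTERVALS = 64


@njit(cache=False)
def _loglog(e_log, table_log, log_e0, dlog):
    """Linear interpolation of a log-valued table on a uniform log-E grid."""
    x = (e_log - log_e0) / dlog
    n = table_log.shape[0]
    if x <= 0.0:
        return np.exp(table_log[0])
    if x >= n - 1:
        return np.exp(table_log[n - 1])
    i = int(x)
    f = x - i
    return np.exp(table_log[i] * (1.0 - f) + table_log[i + 1] * f)


@njit(cache=False)
def _lin(e_log, table, log_e0, dlog):
    x = (e_log - log_e0) / dlog
    n = table.shape[0]
    if x <= 0.0:
        return table[0]
    if x >= n - 1:
        return table[n - 1]
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=False)
def _shape_interval(kind, p, ox, oy, oz, dx, dy, dz):
    """(lo, hi) ray interval inside one world-frame component; lo > hi = miss."""
    INF = 1e30
    if kind == CYL:
        cx, cy, r, z0, z1 = p[0], p[1], p[2], p[3], p[4]
        rx = ox - cx
        ry = oy - cy
        a = dx * dx + dy * dy
        lo = -INF
        hi = INF
        if a < 1e-18:
            if rx * rx + ry * ry > r * r:
                return INF, -INF
        else:
            b = 2.0 * (rx * dx + ry * dy)
            c = rx * rx + ry * ry - r * r
            disc = b * b - 4.0 * a * c
            if disc <= 0.0:
                return INF, -INF
            sq = np.sqrt(disc)
            lo = (-b - sq) / (2.0 * a)
            hi = (-b + sq) / (2.0 * a)
        if abs(dz) < 1e-15:
            if oz < z0 or oz > z1:
                return INF, -INF
        else:
            ta = (z0 - oz) / dz
            tb = (z1 - oz) / dz
            if ta > tb:
                ta, tb = tb, ta
            if ta > lo:
                lo = ta
            if tb < hi:
                hi = tb
        return lo, hi
    if kind == SPH or kind == HEMI:
        cx, cy, cz, r = p[0], p[1], p[2], p[3]
        rx = ox - cx
        ry = oy - cy
        rz = oz - cz
        b = 2.0 * (rx * dx + ry * dy + rz * dz)
        c = rx * rx + ry * ry + rz * rz - r * r
        disc = b * b - 4.0 * c
        if disc <= 0.0:
            return INF, -INF
        sq = np.sqrt(disc)
        lo = (-b - sq) / 2.0
        hi = (-b + sq) / 2.0
        if kind == HEMI:
            sign = p[4]
            if abs(dz) < 1e-15:
                if sign * rz < 0.0:
                    return INF, -INF
            else:
                tstar = (cz - oz) / dz
                if dz * sign > 0.0:
                    if tstar > lo:
                        lo = tstar
                else:
                    if tstar < hi:
                        hi = tstar
        return lo, hi
    # frustum: radius linear in z between (z0, r0) and (z1, r1)
    cx, cy, z0, z1, r0, r1 = p[0], p[1], p[2], p[3], p[4], p[5]
    rx = ox - cx
    ry = oy - cy
    k = (r1 - r0) / (z1 - z0)
    m = r0 + k * (oz - z0)
    A = dx * dx + dy * dy - k * k * dz * dz
    B = 2.0 * (rx * dx + ry * dy - k * dz * m)
    C = rx * rx + ry * ry - m * m
    zl = min(z0, z1)
    zh = max(z0, z1)
    if abs(dz) < 1e-15:
        if oz < zl or oz > zh:
            return INF, -INF
        slo = -INF
        shi = INF
    else:
        slo = (zl - oz) / dz
        shi = (zh - oz) / dz
        if slo > shi:
            slo, shi = shi, slo
    q0 = slo
    q1 = slo
    if abs(A) < 1e-18:
        if abs(B) >= 1e-18:
            q0 = -C / B
            q1 = q0
    else:
        disc = B * B - 4.0 * A * C
        if disc > 0.0:
            sq = np.sqrt(disc)
            q0 = (-B - sq) / (2.0 * A)
            q1 = (-B + sq) / (2.0 * A)
            if q0 > q1:
                q0, q1 = q1, q0
        # disc <= 0 with A < 0: inside everywhere or nowhere; midpoint test
    if q0 < slo:
        q0 = slo
    if q0 > shi:
        q0 = shi
    if q1 < slo:
        q1 = slo
    if q1 > shi:
        q1 = shi
    lo = INF
    hi = -INF
    t_prev = slo
    for t_next in (q0, q1, shi):
        if t_next > t_prev:
            tm = 0.5 * (t_prev + t_next)
            x = rx + tm * dx
            y = ry + tm * dy
            z = oz + tm * dz
            rad = r0 + k * (z - z0)
            if x * x + y * y <= rad * rad:
                if t_prev < lo:
                    lo = t_prev
                if t_next > hi:
                    hi = t_next
            t_prev = t_next
    return lo, hi


@njit(cache=False)
def _collect_intervals(comp_kind, comp_par, comp_dmu, seg,
                       ox, oy, oz, dx, dy, dz,
                       int_lo, int_hi, int_dmu):
    """Clip every component interval to [0, seg]; return count.

    ``comp_dmu`` holds (mu_comp - mu_parent) at the current energy.
    """
    n = 0
    for i in range(comp_kind.shape[0]):
        lo, hi = _shape_interval(comp_kind[i], comp_par[i],
                                 ox, oy, oz, dx, dy, dz)
        if lo < 0.0:
            lo = 0.0
        if hi > seg:
            hi = seg
        if hi - lo > 1e-7 and abs(comp_dmu[i]) > 0.0:
            int_lo[n] = lo
            int_hi[n] = hi
            int_dmu[n] = comp_dmu[i]
            n += 1
            if n == MAX_INTERVALS:
                break
    return n


@njit(cache=False)
def _att_at(t, n_int, int_lo, int_hi, int_dmu):
    """Accumulated excess optical depth from 0 to t over seed intervals."""
    a = 0.0
    for i in range(n_int):
        lo = int_lo[i]
        hi = int_hi[i]
        if t > lo:
            top = t if t < hi else hi
            a += int_dmu[i] * (top - lo)
    return a


@njit(cache=False)
def _deposit(tally, origin, voxel, nx, ny, nz,
             ox, oy, oz, dx, dy, dz, seg, w, score,
             n_int, int_lo, int_hi, int_dmu):
    """Track-length deposition with mid-chord weight evaluation.

    Returns the total deposited score for bookkeeping.
    """
    # grid box in t
    INF = 1e30
    t0 = 0.0
    t1 = seg
    lox = origin[0] - 0.5 * voxel
    loy = origin[1] - 0.5 * voxel
    loz = origin[2] - 0.5 * voxel
    hix = lox + nx * voxel
    hiy = loy + ny * voxel
    hiz = loz + nz * voxel
    # slab clipping
    for axis in range(3):
        if axis == 0:
            o, d, lo, hi = ox, dx, lox, hix
        elif axis == 1:
            o, d, lo, hi = oy, dy, loy, hiy
        else:
            o, d, lo, hi = oz, dz, loz, hiz
        if abs(d) < 1e-15:
            if o < lo or o > hi:
                return 0.0
        else:
            ta = (lo - o) / d
            tb = (hi - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 <= t0:
        return 0.0
    total = 0.0
    t = t0
    eps = 1e-9
    while t < t1 - eps:
        px = ox + (t + eps) * dx
        py = oy + (t + eps) * dy
        pz = oz + (t + eps) * dz
        ix = int((px - lox) / voxel)
        iy = int((py - loy) / voxel)
        iz = int((pz - loz) / voxel)
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            # numerical edge; advance minimally
            t += voxel * 1e-3
            continue
        # next boundary crossing
        tn = t1
        if dx > 1e-15:
            cand = (lox + (ix + 1) * voxel - ox) / dx
            if cand < tn:
                tn = cand
        elif dx < -1e-15:
            cand = (lox + ix * voxel - ox) / dx
            if cand < tn:
                tn = cand
        if dy > 1e-15:
            cand = (loy + (iy + 1) * voxel - oy) / dy
            if cand < tn:
                tn = cand
        elif dy < -1e-15:
            cand = (loy + iy * voxel - oy) / dy
            if cand < tn:
                tn = cand
        if dz > 1e-15:
            cand = (loz + (iz + 1) * voxel - oz) / dz
            if cand < tn:
                tn = cand
        elif dz < -1e-15:
            cand = (loz + iz * voxel - oz) / dz
            if cand < tn:
                tn = cand
        if tn <= t:
            tn = t + voxel * 1e-3
        chord = min(tn, t1) - t
        tm = t + 0.5 * chord
        wloc = w * np.exp(-_att_at(tm, n_int, int_lo, int_hi, int_dmu))
        val = wloc * chord * score
        tally[ix, iy, iz] += val
        total += val
        t = tn
    return total


@njit(cache=False)
def run_histories(n_hist, rng_seed,
                  emit_kind, emit_par, emit_cum,
                  spec_e, spec_cdf,
                  comp_kind, comp_par, comp_mat, comp_parent,
                  log_e0, dlog, mu_log, muen_w, fc_w, mu_w_log,
                  origin, voxel, nx, ny, nz,
                  phantom_r, physics, cutoff_kev,
                  tally):
    """Transport ``n_hist`` photon histories; returns (emitted, deposited).

    ``mu_log`` is (n_materials, nE) log linear-attenuation for seed
    materials; ``mu_w_log`` the water column; ``fc_w`` the Compton fraction.
    """
    np.random.seed(rng_seed)
    int_lo = np.empty(MAX_INTERVALS)
    int_hi = np.empty(MAX_INTERVALS)
    int_dmu = np.empty(MAX_INTERVALS)
    comp_dmu = np.empty(comp_kind.shape[0])
    emitted = 0.0
    deposited = 0.0
    for _ in range(n_hist):
        # ---- emission point
        u = np.random.random()
        k = 0
        while emit_cum[k] < u:
            k += 1
        if emit_kind[k] == 0:  # sphere: cx, cy, cz, r
            r = emit_par[k, 3]
            while True:
                px = (2.0 * np.random.random() - 1.0)
                py = (2.0 * np.random.random() - 1.0)
                pz = (2.0 * np.random.random() - 1.0)
                if px * px + py * py + pz * pz <= 1.0:
                    break
            x = emit_par[k, 0] + r * px
            y = emit_par[k, 1] + r * py
            z = emit_par[k, 2] + r * pz
        else:  # cylinder: cx, cy, z0, z1, r
            r = emit_par[k, 4]
            while True:
                px = (2.0 * np.random.random() - 1.0)
                py = (2.0 * np.random.random() - 1.0)
                if px * px + py * py <= 1.0:
                    break
            x = emit_par[k, 0] + r * px
            y = emit_par[k, 1] + r * py
            z = emit_par[k, 2] + (emit_par[k, 3] - emit_par[k, 2]) * np.random.random()
        # ---- direction (isotropic) and energy (line spectrum)
        cz = 2.0 * np.random.random() - 1.0
        sz = np.sqrt(max(0.0, 1.0 - cz * cz))
        phi = 2.0 * np.pi * np.random.random()
        dx = sz * np.cos(phi)
        dy = sz * np.sin(phi)
        dz = cz
        u = np.random.random()
        k = 0
        while spec_cdf[k] < u:
            k += 1
        e = spec_e[k]
        emitted += e
        w = 1.0
        # ---- random walk
        while True:
            e_log = np.log(e)
            mu_w = np.exp(_lin(e_log, mu_w_log, log_e0, dlog))
            s = -np.log(np.random.random()) / mu_w
            # clip at phantom sphere (origin-centered)
            b = x * dx + y * dy + z * dz
            c = x * x + y * y + z * z - phantom_r * phantom_r
            disc = b * b - c
            t_exit = 1e30
            if disc > 0.0:
                t_exit = -b + np.sqrt(disc)
                if t_exit < 0.0:
                    t_exit = 0.0
            escaped = s >= t_exit
            seg = t_exit if escaped else s
            # seed-material excess attenuation at this energy
            for i in range(comp_kind.shape[0]):
                mu_c = np.exp(_lin(e_log, mu_log[comp_mat[i]], log_e0, dlog))
                if comp_parent[i] < 0:
                    mu_p = mu_w
                else:
                    mu_p = np.exp(_lin(e_log, mu_log[comp_parent[i]],
                                       log_e0, dlog))
                comp_dmu[i] = mu_c - mu_p
            n_int = _collect_intervals(comp_kind, comp_par, comp_dmu, seg,
                                       x, y, z, dx, dy, dz,
                                       int_lo, int_hi, int_dmu)
            score = e * _lin(e_log, muen_w, log_e0, dlog)
            deposited += _deposit(tally, origin, voxel, nx, ny, nz,
                                  x, y, z, dx, dy, dz, seg, w, score,
                                  n_int, int_lo, int_hi, int_dmu)
            # weight after traversing all seed chords of this segment
            w *= np.exp(-_att_at(seg, n_int, int_lo, int_hi, int_dmu))
            if escaped:
                break
            x += seg * dx
            y += seg * dy
            z += seg * dz
            if physics == PRIMARY_ONLY:
                break  # every collision absorbs
            fc = _lin(e_log, fc_w, log_e0, dlog)
            if np.random.random() >= fc:
                break  # photoelectric
            # Kahn sampling of the Klein-Nishina ratio x = E/E'
            a = e / 510.999
            ratio = 1.0
            cth = 1.0
            while True:
                u1 = np.random.random()
                u2 = np.random.random()
                u3 = np.random.random()
                if u1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
                    ratio = 1.0 + 2.0 * a * u2
                    if u3 <= 4.0 * (1.0 / ratio - 1.0 / (ratio * ratio)):
                        cth = 1.0 - (ratio - 1.0) / a
                        break
                else:
                    ratio = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * u2)
                    cth = 1.0 - (ratio - 1.0) / a
                    if u3 <= 0.5 * (cth * cth + 1.0 / ratio):
                        break
            e = e / ratio
            if e < cutoff_kev:
                break  # Russian-roulette cutoff (absorb)
            # rotate direction by (theta, uniform phi)
            sth = np.sqrt(max(0.0, 1.0 - cth * cth))
            phi = 2.0 * np.pi * np.random.random()
            sp = np.sin(phi)
            cp = np.cos(phi)
            if abs(dz) < 0.99999:
                # orthonormal frame around current direction
                ux = -dy
                uy = dx
                uz = 0.0
                norm = np.sqrt(ux * ux + uy * uy)
                ux /= norm
                uy /= norm
                vx = dy * uz - dz * uy
                vy = dz * ux - dx * uz
                vz = dx * uy - dy * ux
            else:
                ux, uy, uz = 1.0, 0.0, 0.0
                vx = dy * uz - dz * uy
                vy = dz * ux - dx * uz
                vz = dx * uy - dy * ux
            ndx = cth * dx + sth * (cp * ux + sp * vx)
            ndy = cth * dy + sth * (cp * uy + sp * vy)
            ndz = cth * dz + sth * (cp * uz + sp * vz)
            norm = np.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
            dx = ndx / norm
            dy = ndy / norm
            dz = ndz / norm
    return emitted, deposited
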