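"""Numba forward-tracing kernel.

One compiled routine traces all rays of one run.  Rays start on a source-
oriented disk circumscribing the scene's bounding sphere and carry a
per-bin weight vector.  Surface interactions use *pilot-bin spectral
splitting*: a pilot bin is drawn proportional to the current weight
vector, the scatter branch (diffuse/specular reflection or diffuse
transmission) and outgoing direction are sampled from the pilot bin's
mixture kernel, and every bin's weight is multiplied by

    w'_b = w_b * s_pilot * k_b(wo) / k_pilot(wo)

where ``s_pilot`` is the pilot bin's survival probability and ``k_b`` the
bin's scattering kernel (BRDF for reflection, tau/pi for transmission) at
the sampled direction; the mixture pdf makes the direction factors cancel
to exactly this BRDF ratio.  The difference w_b - w'_b is deposited as
absorbed at the surface, which makes the run's energy ledger

    emitted = absorbed + ground + escaped + truncated

telescoping and therefore exact to float precision, while every tally
stays unbiased.  Rays emitted with a single non-zero bin (per-bin mode)
always pick that bin as pilot, so the scheme degrades gracefully to
deterministic survival weighting.

Sensors are passive disks: every segment is tested against every sensor
and crossings from the facing side accumulate the current weight.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np

__all__ = ["trace_kernel"]

_EPS = 1e-9
_OFFSET = 1e-7          # surface offset after scattering, metres
_W_CUT = 1e-13          # relative weight cutoff
_MAX_LOBE_TRIES = 256


@nb.njit(cache=True, inline="always")
def _dot(ax, ay, az, bx, by, bz):
    return ax * bx + ay * by + az * bz


@nb.njit(cache=True)
def _intersect_tri(ox, oy, oz, dx, dy, dz, v0, v1, v2, i):
    """Moller-Trumbore; returns hit distance or -1."""
    e1x = v1[i, 0] - v0[i, 0]; e1y = v1[i, 1] - v0[i, 1]; e1z = v1[i, 2] - v0[i, 2]
    e2x = v2[i, 0] - v0[i, 0]; e2y = v2[i, 1] - v0[i, 1]; e2z = v2[i, 2] - v0[i, 2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -1e-14 < det < 1e-14:
        return -1.0
    inv = 1.0 / det
    tx = ox - v0[i, 0]; ty = oy - v0[i, 1]; tz = oz - v0[i, 2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-12 or u > 1.0 + 1e-12:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return -1.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= _EPS:
        return -1.0
    return t


@nb.njit(cache=True, inline="always")
def _box_hit(ox, oy, oz, ix, iy, iz, bmin, bmax, n, tmax):
    """Slab test against node n; returns entry distance or -1."""
    t0 = (bmin[n, 0] - ox) * ix
    t1 = (bmax[n, 0] - ox) * ix
    tlo = min(t0, t1); thi = max(t0, t1)
    t0 = (bmin[n, 1] - oy) * iy
    t1 = (bmax[n, 1] - oy) * iy
    tlo = max(tlo, min(t0, t1)); thi = min(thi, max(t0, t1))
    t0 = (bmin[n, 2] - oz) * iz
    t1 = (bmax[n, 2] - oz) * iz
    tlo = max(tlo, min(t0, t1)); thi = min(thi, max(t0, t1))
    if thi < tlo or thi < _EPS or tlo > tmax:
        return -1.0
    return max(tlo, 0.0)


@nb.njit(cache=True)
def _nearest_hit(ox, oy, oz, dx, dy, dz, v0, v1, v2,
                 node_min, node_max, node_left, node_right,
                 node_start, node_count, tri_order, stack):
    ix = 1.0 / dx if abs(dx) > 1e-300 else 1e300
    iy = 1.0 / dy if abs(dy) > 1e-300 else 1e300
    iz = 1.0 / dz if abs(dz) > 1e-300 else 1e300
    best_t = 1e300
    best_tri = -1
    if node_min.shape[0] == 0:
        return best_t, best_tri
    top = 0
    stack[top] = 0
    top += 1
    while top > 0:
        top -= 1
        n = stack[top]
        if _box_hit(ox, oy, oz, ix, iy, iz, node_min, node_max, n, best_t) < 0:
            continue
        cnt = node_count[n]
        if cnt > 0:
            s = node_start[n]
            for k in range(cnt):
                tri = tri_order[s + k]
                t = _intersect_tri(ox, oy, oz, dx, dy, dz, v0, v1, v2, tri)
                if 0.0 < t < best_t:
                    best_t = t
                    best_tri = tri
        else:
            stack[top] = node_left[n]; top += 1
            stack[top] = node_right[n]; top += 1
    return best_t, best_tri


@nb.njit(cache=True)
def _cosine_dir(nx, ny, nz):
    """Cosine-weighted direction in the hemisphere around (nx, ny, nz)."""
    if abs(nz) > 0.9:
        ax, ay, az = 1.0, 0.0, 0.0
    else:
        ax, ay, az = 0.0, 0.0, 1.0
    tx = ay * nz - az * ny
    ty = az * nx - ax * nz
    tz = ax * ny - ay * nx
    tl = math.sqrt(tx * tx + ty * ty + tz * tz)
    tx /= tl; ty /= tl; tz /= tl
    bx = ny * tz - nz * ty
    by = nz * tx - nx * tz
    bz = nx * ty - ny * tx
    u1 = np.random.random()
    u2 = np.random.random()
    r = math.sqrt(u1)
    phi = 2.0 * math.pi * u2
    c = math.sqrt(max(0.0, 1.0 - u1))
    x = r * math.cos(phi)
    y = r * math.sin(phi)
    return (x * tx + y * bx + c * nx,
            x * ty + y * by + c * ny,
            x * tz + y * bz + c * nz)


@nb.njit(cache=True)
def _lobe_dir(mx, my, mz, nx, ny, nz, n_exp):
    """Sample the clipped cosine-power lobe around the mirror direction.

    Proposal cos^n around (mx,my,mz), thinned by cos(theta_o) and clipped
    to the upper hemisphere of (nx,ny,nz).  Returns (ok, x, y, z).
    """
    if abs(mz) > 0.9:
        ax, ay, az = 1.0, 0.0, 0.0
    else:
        ax, ay, az = 0.0, 0.0, 1.0
    tx = ay * mz - az * my
    ty = az * mx - ax * mz
    tz = ax * my - ay * mx
    tl = math.sqrt(tx * tx + ty * ty + tz * tz)
    tx /= tl; ty /= tl; tz /= tl
    bx = my * tz - mz * ty
    by = mz * tx - mx * tz
    bz = mx * ty - my * tx
    for _ in range(_MAX_LOBE_TRIES):
        u1 = np.random.random()
        u2 = np.random.random()
        ca = u1 ** (1.0 / (n_exp + 1.0))
        sa = math.sqrt(max(0.0, 1.0 - ca * ca))
        phi = 2.0 * math.pi * u2
        x = sa * math.cos(phi)
        y = sa * math.sin(phi)
        wx = x * tx + y * bx + ca * mx
        wy = x * ty + y * by + ca * my
        wz = x * tz + y * bz + ca * mz
        cos_o = wx * nx + wy * ny + wz * nz
        if cos_o <= 0.0:
            continue
        if np.random.random() < cos_o:
            return True, wx, wy, wz
    return False, 0.0, 0.0, 0.0


@nb.njit(cache=True, inline="always")
def _s_lookup(s_table, side, b, theta_deg):
    """Linear interpolation of the clipped-lobe factor on a 1-deg grid."""
    x = theta_deg
    if x <= 0.0:
        return s_table[side, b, 0]
    if x >= 90.0:
        return s_table[side, b, 90]
    i = int(x)
    f = x - i
    return s_table[side, b, i] * (1.0 - f) + s_table[side, b, i + 1] * f


@nb.njit(cache=True)
def trace_kernel(v0, v1, v2, tri_group,
                 node_min, node_max, node_left, node_right,
                 node_start, node_count, tri_order,
                 ground_radius,
                 kd, ks, n_exp, tau, s_table, stem_refl,
                 sen_c, sen_n, sen_r2,
                 src_dir, src_nrays, src_w, ray_bin,
                 emit_center, emit_radius,
                 max_depth, reflections_enabled, seed,
                 absorbed, stem_abs, ground_abs, escaped, truncated,
                 emitted, sensor, sensor_direct):
    np.random.seed(seed)
    nbins = kd.shape[1]
    ns = sen_c.shape[0]
    stack = np.empty(256, dtype=np.int32)
    w = np.empty(nbins)
    for s in range(src_dir.shape[0]):
        dx0, dy0, dz0 = src_dir[s, 0], src_dir[s, 1], src_dir[s, 2]
        # frame perpendicular to the beam for the emission disk
        if abs(dz0) > 0.9:
            axx, axy, axz = 1.0, 0.0, 0.0
        else:
            axx, axy, axz = 0.0, 0.0, 1.0
        e1x = axy * dz0 - axz * dy0
        e1y = axz * dx0 - axx * dz0
        e1z = axx * dy0 - axy * dx0
        el = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= el; e1y /= el; e1z /= el
        e2x = dy0 * e1z - dz0 * e1y
        e2y = dz0 * e1x - dx0 * e1z
        e2z = dx0 * e1y - dy0 * e1x
        back = emit_radius + 0.05
        cx = emit_center[0] - dx0 * back
        cy = emit_center[1] - dy0 * back
        cz = emit_center[2] - dz0 * back
        for r in range(src_nrays[s]):
            # start on the disk
            u1 = np.random.random()
            u2 = np.random.random()
            rad = emit_radius * math.sqrt(u1)
            phi = 2.0 * math.pi * u2
            ox = cx + rad * (math.cos(phi) * e1x + math.sin(phi) * e2x)
            oy = cy + rad * (math.cos(phi) * e1y + math.sin(phi) * e2y)
            oz = cz + rad * (math.cos(phi) * e1z + math.sin(phi) * e2z)
            dx, dy, dz = dx0, dy0, dz0
            rb = ray_bin[s]
            w_tot0 = 0.0
            for b in range(nbins):
                if rb >= 0 and b != rb:
                    w[b] = 0.0
                else:
                    w[b] = src_w[s, b]
                emitted[b] += w[b]
                w_tot0 += w[b]
            depth = 0
            while True:
                t_hit, tri = _nearest_hit(ox, oy, oz, dx, dy, dz, v0, v1, v2,
                                          node_min, node_max, node_left,
                                          node_right, node_start, node_count,
                                          tri_order, stack)
                # black ground plane at z = 0 (finite disk)
                t_ground = 1e300
                if dz < -1e-12 and oz > 0.0:
                    tg = -oz / dz
                    if tg > _EPS:
                        t_ground = tg
                t_end = min(t_hit, t_ground)
                # passive sensor crossings along this segment
                for k in range(ns):
                    dn = dx * sen_n[k, 0] + dy * sen_n[k, 1] + dz * sen_n[k, 2]
                    if dn < -1e-12:
                        ts = ((sen_c[k, 0] - ox) * sen_n[k, 0]
                              + (sen_c[k, 1] - oy) * sen_n[k, 1]
                              + (sen_c[k, 2] - oz) * sen_n[k, 2]) / dn
                        if _EPS < ts < t_end:
                            px = ox + ts * dx - sen_c[k, 0]
                            py = oy + ts * dy - sen_c[k, 1]
                            pz = oz + ts * dz - sen_c[k, 2]
                            if px * px + py * py + pz * pz <= sen_r2:
                                for b in range(nbins):
                                    sensor[k, b] += w[b]
                                if depth == 0:
                                    for b in range(nbins):
                                        sensor_direct[k, b] += w[b]
                if tri < 0 and t_ground >= 1e299:
                    for b in range(nbins):
                        escaped[b] += w[b]
                    break
                if t_ground < t_hit:
                    gx = ox + t_ground * dx
                    gy = oy + t_ground * dy
                    if gx * gx + gy * gy <= ground_radius * ground_radius:
                        for b in range(nbins):
                            ground_abs[b] += w[b]
                    else:
                        for b in range(nbins):
                            escaped[b] += w[b]
                    break
                # surface hit
                hx = ox + t_hit * dx
                hy = oy + t_hit * dy
                hz = oz + t_hit * dz
                e1tx = v1[tri, 0] - v0[tri, 0]
                e1ty = v1[tri, 1] - v0[tri, 1]
                e1tz = v1[tri, 2] - v0[tri, 2]
                e2tx = v2[tri, 0] - v0[tri, 0]
                e2ty = v2[tri, 1] - v0[tri, 1]
                e2tz = v2[tri, 2] - v0[tri, 2]
                ngx = e1ty * e2tz - e1tz * e2ty
                ngy = e1tz * e2tx - e1tx * e2tz
                ngz = e1tx * e2ty - e1ty * e2tx
                nl = math.sqrt(ngx * ngx + ngy * ngy + ngz * ngz)
                ngx /= nl; ngy /= nl; ngz /= nl
                cos_in = -(dx * ngx + dy * ngy + dz * ngz)
                if cos_in >= 0.0:
                    side = 0
                    nx, ny, nz = ngx, ngy, ngz
                else:
                    side = 1
                    nx, ny, nz = -ngx, -ngy, -ngz
                    cos_in = -cos_in
                if cos_in > 1.0:
                    cos_in = 1.0
                g = tri_group[tri]
                if g < 0:
                    # stem: broadband diffuse reflection, non-transmitting
                    if not reflections_enabled:
                        for b in range(nbins):
                            stem_abs[b] += w[b] * (1.0 - stem_refl)
                            truncated[b] += w[b] * stem_refl
                        break
                    if depth >= max_depth:
                        for b in range(nbins):
                            truncated[b] += w[b]
                        break
                    w_tot = 0.0
                    for b in range(nbins):
                        stem_abs[b] += w[b] * (1.0 - stem_refl)
                        w[b] *= stem_refl
                        w_tot += w[b]
                    if w_tot <= _W_CUT * w_tot0:
                        for b in range(nbins):
                            stem_abs[b] += w[b]
                        break
                    dx, dy, dz = _cosine_dir(nx, ny, nz)
                    ox = hx + _OFFSET * nx
                    oy = hy + _OFFSET * ny
                    oz = hz + _OFFSET * nz
                    depth += 1
                    continue
                theta = math.degrees(math.acos(cos_in))
                if not reflections_enabled:
                    # first interaction terminates the path: deposit the
                    # per-bin absorbed fraction, rest is truncated weight
                    for b in range(nbins):
                        sb = (kd[side, b]
                              + ks[side, b] * _s_lookup(s_table, side, b, theta)
                              + tau[side, b])
                        absorbed[g, b] += w[b] * (1.0 - sb)
                        truncated[b] += w[b] * sb
                    break
                if depth >= max_depth:
                    for b in range(nbins):
                        truncated[b] += w[b]
                    break
                # pilot bin proportional to current weight
                w_tot = 0.0
                for b in range(nbins):
                    w_tot += w[b]
                if w_tot <= _W_CUT * w_tot0 or w_tot <= 0.0:
                    for b in range(nbins):
                        absorbed[g, b] += w[b]
                    break
                upick = np.random.random() * w_tot
                j = 0
                acc = 0.0
                for b in range(nbins):
                    acc += w[b]
                    if upick <= acc:
                        j = b
                        break
                sj_spec = ks[side, j] * _s_lookup(s_table, side, j, theta)
                pdj = kd[side, j]
                ptj = tau[side, j]
                sj = pdj + sj_spec + ptj
                if sj <= 1e-14:
                    for b in range(nbins):
                        absorbed[g, b] += w[b]
                    break
                u = np.random.random() * sj
                mx = dx + 2.0 * cos_in * nx
                my = dy + 2.0 * cos_in * ny
                mz = dz + 2.0 * cos_in * nz
                if u < pdj + sj_spec:
                    # reflection: sample the pilot mixture of cosine and lobe
                    if u < pdj:
                        wx, wy, wz = _cosine_dir(nx, ny, nz)
                        ok = True
                    else:
                        ok, wx, wy, wz = _lobe_dir(mx, my, mz, nx, ny, nz,
                                                   n_exp[side, j])
                    if not ok:
                        for b in range(nbins):
                            absorbed[g, b] += w[b]
                        break
                    # BRDF ratio correction: w'_b = w_b * s_j * f_b / f_j
                    ca = wx * mx + wy * my + wz * mz
                    if ca < 0.0:
                        ca = 0.0
                    elif ca > 1.0:
                        ca = 1.0
                    fj = (kd[side, j] / math.pi
                          + ks[side, j] * (n_exp[side, j] + 2.0)
                          / (2.0 * math.pi) * ca ** n_exp[side, j])
                    for b in range(nbins):
                        fb = (kd[side, b] / math.pi
                              + ks[side, b] * (n_exp[side, b] + 2.0)
                              / (2.0 * math.pi) * ca ** n_exp[side, b])
                        wnew = w[b] * sj * fb / fj
                        absorbed[g, b] += w[b] - wnew
                        w[b] = wnew
                    dx, dy, dz = wx, wy, wz
                    ox = hx + _OFFSET * nx
                    oy = hy + _OFFSET * ny
                    oz = hz + _OFFSET * nz
                else:
                    # diffuse transmission through the lamina
                    for b in range(nbins):
                        wnew = w[b] * sj * tau[side, b] / ptj
                        absorbed[g, b] += w[b] - wnew
                        w[b] = wnew
                    dx, dy, dz = _cosine_dir(-nx, -ny, -nz)
                    ox = hx - _OFFSET * nx
                    oy = hy - _OFFSET * ny
                    oz = hz - _OFFSET * nz
                depth += 1
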