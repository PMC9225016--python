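"""Numba kernels: ray traversal, projection, photon transport, single scatter.

All geometry is in mm, scanner-centred.  The voxel traversal is the classic
incremental (Amanatides-Woo) formulation of Siddon ray tracing with half-open
voxel intervals along each axis (ties advance x before y before z), so exact
plane hits are deterministic.
"""

import math

import numpy as np
from numba import njit

_EPS = 1e-12


# --------------------------------------------------------------------------
# ray / grid traversal
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _clip_segment(x1, y1, z1, dx, dy, dz, gx0, gy0, gz0, gx1, gy1, gz1):
    """Clip the parametric segment t in [0,1] to the grid box; returns (tmin, tmax).

    ``tmin >= tmax`` means the segment misses the box.
    """
    tmin = 0.0
    tmax = 1.0
    for axis in range(3):
        if axis == 0:
            p, d, lo, hi = x1, dx, gx0, gx1
        elif axis == 1:
            p, d, lo, hi = y1, dy, gy0, gy1
        else:
            p, d, lo, hi = z1, dz, gz0, gz1
        if abs(d) < _EPS:
            if p < lo or p >= hi:
                return 1.0, 0.0
        else:
            t0 = (lo - p) / d
            t1 = (hi - p) / d
            if t0 > t1:
                t0, t1 = t1, t0
            if t0 > tmin:
                tmin = t0
            if t1 < tmax:
                tmax = t1
    return tmin, tmax


@njit(cache=True)
def fwd_ray(vol, gx0, gy0, gz0, vx, vy, vz,
            x1, y1, z1, x2, y2, z2):
    """Line integral of ``vol`` along the segment p1 -> p2 (value * mm)."""
    nx, ny, nz = vol.shape
    dx = x2 - x1
    dy = y2 - y1
    dz = z2 - z1
    length = math.sqrt(dx * dx + dy * dy + dz * dz)
    if length < _EPS:
        return 0.0
    tmin, tmax = _clip_segment(x1, y1, z1, dx, dy, dz,
                               gx0, gy0, gz0,
                               gx0 + nx * vx, gy0 + ny * vy, gz0 + nz * vz)
    if tmin >= tmax:
        return 0.0
    t = tmin
    px = x1 + (t + 1e-9 / length) * dx
    py = y1 + (t + 1e-9 / length) * dy
    pz = z1 + (t + 1e-9 / length) * dz
    i = int(math.floor((px - gx0) / vx))
    j = int(math.floor((py - gy0) / vy))
    k = int(math.floor((pz - gz0) / vz))
    if i < 0:
        i = 0
    if j < 0:
        j = 0
    if k < 0:
        k = 0
    if i > nx - 1:
        i = nx - 1
    if j > ny - 1:
        j = ny - 1
    if k > nz - 1:
        k = nz - 1
    stepx = 1 if dx > 0 else -1
    stepy = 1 if dy > 0 else -1
    stepz = 1 if dz > 0 else -1
    big = 1e30
    tdx = vx / abs(dx) if abs(dx) > _EPS else big
    tdy = vy / abs(dy) if abs(dy) > _EPS else big
    tdz = vz / abs(dz) if abs(dz) > _EPS else big
    if abs(dx) > _EPS:
        bx = gx0 + (i + (1 if stepx > 0 else 0)) * vx
        tmx = (bx - x1) / dx
    else:
        tmx = big
    if abs(dy) > _EPS:
        by = gy0 + (j + (1 if stepy > 0 else 0)) * vy
        tmy = (by - y1) / dy
    else:
        tmy = big
    if abs(dz) > _EPS:
        bz = gz0 + (k + (1 if stepz > 0 else 0)) * vz
        tmz = (bz - z1) / dz
    else:
        tmz = big
    acc = 0.0
    while True:
        tnext = tmx
        if tmy < tnext:
            tnext = tmy
        if tmz < tnext:
            tnext = tmz
        if tnext > tmax:
            tnext = tmax
        seg = (tnext - t) * length
        if seg > 0.0:
            acc += vol[i, j, k] * seg
        if tnext >= tmax:
            break
        t = tnext
        if tmx <= tmy and tmx <= tmz:
            i += stepx
            tmx += tdx
            if i < 0 or i >= nx:
                break
        elif tmy <= tmz:
            j += stepy
            tmy += tdy
            if j < 0 or j >= ny:
                break
        else:
            k += stepz
            tmz += tdz
            if k < 0 or k >= nz:
                break
    return acc


@njit(cache=True)
def back_ray(vol, gx0, gy0, gz0, vx, vy, vz,
             x1, y1, z1, x2, y2, z2, w):
    """Adjoint of :func:`fwd_ray`: add ``w * segment_length`` into each voxel."""
    nx, ny, nz = vol.shape
    dx = x2 - x1
    dy = y2 - y1
    dz = z2 - z1
    length = math.sqrt(dx * dx + dy * dy + dz * dz)
    if length < _EPS:
        return
    tmin, tmax = _clip_segment(x1, y1, z1, dx, dy, dz,
                               gx0, gy0, gz0,
                               gx0 + nx * vx, gy0 + ny * vy, gz0 + nz * vz)
    if tmin >= tmax:
        return
    t = tmin
    px = x1 + (t + 1e-9 / length) * dx
    py = y1 + (t + 1e-9 / length) * dy
    pz = z1 + (t + 1e-9 / length) * dz
    i = int(math.floor((px - gx0) / vx))
    j = int(math.floor((py - gy0) / vy))
    k = int(math.floor((pz - gz0) / vz))
    if i < 0:
        i = 0
    if j < 0:
        j = 0
    if k < 0:
        k = 0
    if i > nx - 1:
        i = nx - 1
    if j > ny - 1:
        j = ny - 1
    if k > nz - 1:
        k = nz - 1
    stepx = 1 if dx > 0 else -1
    stepy = 1 if dy > 0 else -1
    stepz = 1 if dz > 0 else -1
    big = 1e30
    tdx = vx / abs(dx) if abs(dx) > _EPS else big
    tdy = vy / abs(dy) if abs(dy) > _EPS else big
    tdz = vz / abs(dz) if abs(dz) > _EPS else big
    if abs(dx) > _EPS:
        tmx = (gx0 + (i + (1 if stepx > 0 else 0)) * vx - x1) / dx
    else:
        tmx = big
    if abs(dy) > _EPS:
        tmy = (gy0 + (j + (1 if stepy > 0 else 0)) * vy - y1) / dy
    else:
        tmy = big
    if abs(dz) > _EPS:
        tmz = (gz0 + (k + (1 if stepz > 0 else 0)) * vz - z1) / dz
    else:
        tmz = big
    while True:
        tnext = tmx
        if tmy < tnext:
            tnext = tmy
        if tmz < tnext:
            tnext = tmz
        if tnext > tmax:
            tnext = tmax
        seg = (tnext - t) * length
        if seg > 0.0:
            vol[i, j, k] += w * seg
        if tnext >= tmax:
            break
        t = tnext
        if tmx <= tmy and tmx <= tmz:
            i += stepx
            tmx += tdx
            if i < 0 or i >= nx:
                break
        elif tmy <= tmz:
            j += stepy
            tmy += tdy
            if j < 0 or j >= ny:
                break
        else:
            k += stepz
            tmz += tdz
            if k < 0 or k >= nz:
                break


@njit(cache=True)
def trace_ray(gx0, gy0, gz0, vx, vy, vz, nx, ny, nz,
              x1, y1, z1, x2, y2, z2, out_idx, out_len):
    """Siddon trace: fill (voxel index triple, intersection length) lists.

    Returns the number of voxels crossed; voxels are unique and ordered along
    the ray.
    """
    dx = x2 - x1
    dy = y2 - y1
    dz = z2 - z1
    length = math.sqrt(dx * dx + dy * dy + dz * dz)
    if length < _EPS:
        return 0
    tmin, tmax = _clip_segment(x1, y1, z1, dx, dy, dz,
                               gx0, gy0, gz0,
                               gx0 + nx * vx, gy0 + ny * vy, gz0 + nz * vz)
    if tmin >= tmax:
        return 0
    t = tmin
    px = x1 + (t + 1e-9 / length) * dx
    py = y1 + (t + 1e-9 / length) * dy
    pz = z1 + (t + 1e-9 / length) * dz
    i = int(math.floor((px - gx0) / vx))
    j = int(math.floor((py - gy0) / vy))
    k = int(math.floor((pz - gz0) / vz))
    if i < 0:
        i = 0
    if j < 0:
        j = 0
    if k < 0:
        k = 0
    if i > nx - 1:
        i = nx - 1
    if j > ny - 1:
        j = ny - 1
    if k > nz - 1:
        k = nz - 1
    stepx = 1 if dx > 0 else -1
    stepy = 1 if dy > 0 else -1
    stepz = 1 if dz > 0 else -1
    big = 1e30
    tdx = vx / abs(dx) if abs(dx) > _EPS else big
    tdy = vy / abs(dy) if abs(dy) > _EPS else big
    tdz = vz / abs(dz) if abs(dz) > _EPS else big
    tmx = (gx0 + (i + (1 if stepx > 0 else 0)) * vx - x1) / dx if abs(dx) > _EPS else big
    tmy = (gy0 + (j + (1 if stepy > 0 else 0)) * vy - y1) / dy if abs(dy) > _EPS else big
    tmz = (gz0 + (k + (1 if stepz > 0 else 0)) * vz - z1) / dz if abs(dz) > _EPS else big
    n = 0
    while True:
        tnext = tmx
        if tmy < tnext:
            tnext = tmy
        if tmz < tnext:
            tnext = tmz
        if tnext > tmax:
            tnext = tmax
        seg = (tnext - t) * length
        if seg > 0.0:
            out_idx[n, 0] = i
            out_idx[n, 1] = j
            out_idx[n, 2] = k
            out_len[n] = seg
            n += 1
        if tnext >= tmax:
            break
        t = tnext
        if tmx <= tmy and tmx <= tmz:
            i += stepx
            tmx += tdx
            if i < 0 or i >= nx:
                break
        elif tmy <= tmz:
            j += stepy
            tmy += tdy
            if j < 0 or j >= ny:
                break
        else:
            k += stepz
            tmz += tdz
            if k < 0 or k >= nz:
                break
    return n


# --------------------------------------------------------------------------
# sinogram-wide projection
# --------------------------------------------------------------------------

@njit(cache=True)
def fwd_project_3d(vol, gx0, gy0, gz0, vx, vy, vz,
                   pos, tang, detA, detB, valid, mask, maxrd,
                   offs_t, offs_z, out):
    """Forward project into a (R, R, V, T) sinogram; only bins where
    ``mask`` is non-zero are computed.

    Each bin averages the rays of a small sub-LOR bundle: both endpoints are
    shifted by the same fractional offsets along their crystal-face tangents
    (``offs_t``, in mm) and along z (``offs_z``), modelling the finite
    crystal aperture.  Single-ray tracing is the special case of one zero
    offset each.
    """
    R = pos.shape[0]
    V, T = detA.shape
    nt = offs_t.shape[0]
    nz = offs_z.shape[0]
    wray = 1.0 / (nt * nz)
    for r1 in range(R):
        for r2 in range(R):
            if abs(r1 - r2) > maxrd:
                continue
            for v in range(V):
                for ti in range(T):
                    if not valid[v, ti] or mask[r1, r2, v, ti] == 0:
                        continue
                    a = detA[v, ti]
                    b = detB[v, ti]
                    acc = 0.0
                    for it in range(nt):
                        ot = offs_t[it]
                        ax = pos[r1, a, 0] + ot * tang[a, 0]
                        ay = pos[r1, a, 1] + ot * tang[a, 1]
                        bx = pos[r2, b, 0] + ot * tang[b, 0]
                        by = pos[r2, b, 1] + ot * tang[b, 1]
                        for iz in range(nz):
                            oz = offs_z[iz]
                            acc += fwd_ray(vol, gx0, gy0, gz0, vx, vy, vz,
                                           ax, ay, pos[r1, a, 2] + oz,
                                           bx, by, pos[r2, b, 2] + oz)
                    out[r1, r2, v, ti] = acc * wray


@njit(cache=True)
def back_project_3d(data, gx0, gy0, gz0, vx, vy, vz,
                    pos, tang, detA, detB, valid, maxrd,
                    offs_t, offs_z, out_vol):
    R = pos.shape[0]
    V, T = detA.shape
    nt = offs_t.shape[0]
    nz = offs_z.shape[0]
    wray = 1.0 / (nt * nz)
    for r1 in range(R):
        for r2 in range(R):
            if abs(r1 - r2) > maxrd:
                continue
            for v in range(V):
                for ti in range(T):
                    if not valid[v, ti]:
                        continue
                    w = data[r1, r2, v, ti]
                    if w == 0.0:
                        continue
                    w *= wray
                    a = detA[v, ti]
                    b = detB[v, ti]
                    for it in range(nt):
                        ot = offs_t[it]
                        ax = pos[r1, a, 0] + ot * tang[a, 0]
                        ay = pos[r1, a, 1] + ot * tang[a, 1]
                        bx = pos[r2, b, 0] + ot * tang[b, 0]
                        by = pos[r2, b, 1] + ot * tang[b, 1]
                        for iz in range(nz):
                            oz = offs_z[iz]
                            back_ray(out_vol, gx0, gy0, gz0, vx, vy, vz,
                                     ax, ay, pos[r1, a, 2] + oz,
                                     bx, by, pos[r2, b, 2] + oz, w)


@njit(cache=True)
def fwd_project_2d(vol, gx0, gy0, gz0, vx, vy, vz,
                   posxy, tang, slice_z, detA, detB, valid, mask,
                   offs_t, out):
    """Forward project rebinned (S, V, T) data: in-plane rays at each slice z."""
    S = slice_z.shape[0]
    V, T = detA.shape
    nt = offs_t.shape[0]
    wray = 1.0 / nt
    for s in range(S):
        z = slice_z[s]
        for v in range(V):
            for ti in range(T):
                if not valid[v, ti] or mask[s, v, ti] == 0:
                    continue
                a = detA[v, ti]
                b = detB[v, ti]
                acc = 0.0
                for it in range(nt):
                    ot = offs_t[it]
                    acc += fwd_ray(vol, gx0, gy0, gz0, vx, vy, vz,
                                   posxy[a, 0] + ot * tang[a, 0],
                                   posxy[a, 1] + ot * tang[a, 1], z,
                                   posxy[b, 0] + ot * tang[b, 0],
                                   posxy[b, 1] + ot * tang[b, 1], z)
                out[s, v, ti] = acc * wray


@njit(cache=True)
def back_project_2d(data, gx0, gy0, gz0, vx, vy, vz,
                    posxy, tang, slice_z, detA, detB, valid,
                    offs_t, out_vol):
    S = slice_z.shape[0]
    V, T = detA.shape
    nt = offs_t.shape[0]
    wray = 1.0 / nt
    for s in range(S):
        z = slice_z[s]
        for v in range(V):
            for ti in range(T):
                if not valid[v, ti]:
                    continue
                w = data[s, v, ti]
                if w == 0.0:
                    continue
                w *= wray
                a = detA[v, ti]
                b = detB[v, ti]
                for it in range(nt):
                    ot = offs_t[it]
                    back_ray(out_vol, gx0, gy0, gz0, vx, vy, vz,
                             posxy[a, 0] + ot * tang[a, 0],
                             posxy[a, 1] + ot * tang[a, 1], z,
                             posxy[b, 0] + ot * tang[b, 0],
                             posxy[b, 1] + ot * tang[b, 1], z, w)


# --------------------------------------------------------------------------
# Compton physics
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def klein_nishina(cos_t, e_in):
    """Unnormalised Klein-Nishina differential cross-section in cos(theta)."""
    k = e_in / 511.0
    ratio = 1.0 / (1.0 + k * (1.0 - cos_t))
    sin2 = 1.0 - cos_t * cos_t
    return ratio * ratio * (ratio + 1.0 / ratio - sin2)


@njit(cache=True)
def kn_sample_cos(e_in):
    """Draw cos(theta) from the Klein-Nishina density by rejection.

    The density is bounded by its forward-scattering value (= 2 in these
    units), so uniform proposals on cos(theta) with acceptance f/2 are exact.
    """
    while True:
        c = 1.0 - 2.0 * np.random.random()
        if np.random.random() * 2.0 <= klein_nishina(c, e_in):
            return c


@njit(cache=True, inline="always")
def _interp_tab(x, xs, ys):
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    f = (x - xs[lo]) / (xs[hi] - xs[lo])
    return ys[lo] + f * (ys[hi] - ys[lo])


# --------------------------------------------------------------------------
# Monte Carlo photon transport and detection
# --------------------------------------------------------------------------

@njit(cache=True)
def _transport(x, y, z, dx, dy, dz, e,
               mu, gx0, gy0, gz0, vx, vy, vz,
               e_tab, r_tab, e_floor):
    """Track one photon through the attenuation map.

    Returns (alive, x, y, z, dx, dy, dz, e, n_compton): the exit state of the
    photon, or ``alive = 0`` if it fell below the tracking energy floor.
    Interactions are all Compton (photoelectric absorption in water is
    negligible at these energies).
    """
    nx, ny, nz = mu.shape
    nc = 0
    while True:
        scale = _interp_tab(e, e_tab, r_tab)  # mu(E)/mu(511)
        target = -math.log(np.random.random())
        # march along a segment long enough to leave the grid from anywhere
        far = 4.0 * (nx * vx + ny * vy + nz * vz)
        tmin, tmax = _clip_segment(x, y, z, dx * far, dy * far, dz * far,
                                   gx0, gy0, gz0,
                                   gx0 + nx * vx, gy0 + ny * vy, gz0 + nz * vz)
        if tmin >= tmax:
            return 1, x, y, z, dx, dy, dz, e, nc
        t = tmin if tmin > 0.0 else 0.0
        px = x + (t * far + 1e-9) * dx
        py = y + (t * far + 1e-9) * dy
        pz = z + (t * far + 1e-9) * dz
        i = int(math.floor((px - gx0) / vx))
        j = int(math.floor((py - gy0) / vy))
        k = int(math.floor((pz - gz0) / vz))
        if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
            return 1, x, y, z, dx, dy, dz, e, nc
        stepx = 1 if dx > 0 else -1
        stepy = 1 if dy > 0 else -1
        stepz = 1 if dz > 0 else -1
        big = 1e30
        adx = abs(dx * far)
        ady = abs(dy * far)
        adz = abs(dz * far)
        tdx = vx / adx if adx > _EPS else big
        tdy = vy / ady if ady > _EPS else big
        tdz = vz / adz if adz > _EPS else big
        tmx = (gx0 + (i + (1 if stepx > 0 else 0)) * vx - x) / (dx * far) if adx > _EPS else big
        tmy = (gy0 + (j + (1 if stepy > 0 else 0)) * vy - y) / (dy * far) if ady > _EPS else big
        tmz = (gz0 + (k + (1 if stepz > 0 else 0)) * vz - z) / (dz * far) if adz > _EPS else big
        acc = 0.0
        interacted = False
        while True:
            tnext = tmx
            if tmy < tnext:
                tnext = tmy
            if tmz < tnext:
                tnext = tmz
            if tnext > tmax:
                tnext = tmax
            seg = (tnext - t) * far
            m = mu[i, j, k] * scale
            if seg > 0.0 and m > 0.0:
                d_acc = m * seg
                if acc + d_acc >= target:
                    # interaction inside this voxel
                    travel = (target - acc) / m
                    tint = t + travel / far
                    x = x + tint * far * dx
                    y = y + tint * far * dy
                    z = z + tint * far * dz
                    interacted = True
                    break
                acc += d_acc
            if tnext >= tmax:
                break
            t = tnext
            if tmx <= tmy and tmx <= tmz:
                i += stepx
                tmx += tdx
                if i < 0 or i >= nx:
                    break
            elif tmy <= tmz:
                j += stepy
                tmy += tdy
                if j < 0 or j >= ny:
                    break
            else:
                k += stepz
                tmz += tdz
                if k < 0 or k >= nz:
                    break
        if not interacted:
            return 1, x, y, z, dx, dy, dz, e, nc
        # Compton scatter
        cos_t = kn_sample_cos(e)
        e = e / (1.0 + (e / 511.0) * (1.0 - cos_t))
        nc += 1
        if e < e_floor:
            return 0, x, y, z, dx, dy, dz, e, nc
        # rotate direction by theta about a random azimuth
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
        psi = 2.0 * math.pi * np.random.random()
        # orthonormal basis (u, w) perpendicular to d
        if abs(dz) < 0.9:
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
        wx = dy * uz - dz * uy
        wy = dz * ux - dx * uz
        wz = dx * uy - dy * ux
        ndx = cos_t * dx + sin_t * (math.cos(psi) * ux + math.sin(psi) * wx)
        ndy = cos_t * dy + sin_t * (math.cos(psi) * uy + math.sin(psi) * wy)
        ndz = cos_t * dz + sin_t * (math.cos(psi) * uz + math.sin(psi) * wz)
        nrm = math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
        dx = ndx / nrm
        dy = ndy / nrm
        dz = ndz / nrm


@njit(cache=True, inline="always")
def _detect(x, y, z, dx, dy, dz,
            det_mode, face_cos, face_sin, apothem, half_face, pitch_t, cpf,
            z_lo, pitch_ax, n_rings, depth, mu_det):
    """Volumetric intercept with the crystal layer.

    The photon is tracked into the crystal slab (flat faces for blocks,
    annulus for the cylinder interpretation); the interaction point is drawn
    from the exponential free-path distribution with linear attenuation
    ``mu_det``, so oblique rays can penetrate laterally into neighbouring
    crystals or pass through undetected.  Returns the crystal id of the
    interaction, or -1 when the photon escapes.  ``det_mode`` 1 = flat
    polygon faces (blocks), 0 = cylinder of radius ``apothem`` with
    equal-angle crystals.
    """
    n_sectors = face_cos.shape[0]
    n_det = n_sectors * cpf
    z_hi = z_lo + n_rings * pitch_ax
    if det_mode == 1:
        # collect slab-chord intervals per face, process in ray order
        tAs = np.empty(8)
        tBs = np.empty(8)
        faces = np.empty(8, dtype=np.int64)
        ncand = 0
        for ksec in range(n_sectors):
            nxv = face_cos[ksec]
            nyv = face_sin[ksec]
            denom = dx * nxv + dy * nyv
            if denom <= _EPS:
                continue
            p_n = x * nxv + y * nyv
            t0 = (apothem - p_n) / denom
            t1 = (apothem + depth - p_n) / denom
            if t1 < 0.0:
                continue
            if t0 < 0.0:
                t0 = 0.0
            # lateral coordinate u(t) and axial z(t) are linear in t
            u0 = -x * nyv + y * nxv
            du = -dx * nyv + dy * nxv
            ta, tb = t0, t1
            if abs(du) > _EPS:
                ua = (-half_face - u0) / du
                ub = (half_face - u0) / du
                if ua > ub:
                    ua, ub = ub, ua
                if ua > ta:
                    ta = ua
                if ub < tb:
                    tb = ub
            elif u0 < -half_face or u0 >= half_face:
                continue
            if abs(dz) > _EPS:
                za = (z_lo - z) / dz
                zb = (z_hi - z) / dz
                if za > zb:
                    za, zb = zb, za
                if za > ta:
                    ta = za
                if zb < tb:
                    tb = zb
            elif z < z_lo or z >= z_hi:
                continue
            if tb <= ta:
                continue
            tAs[ncand] = ta
            tBs[ncand] = tb
            faces[ncand] = ksec
            ncand += 1
        # insertion sort by entry parameter
        for i in range(1, ncand):
            j = i
            while j > 0 and tAs[j - 1] > tAs[j]:
                tAs[j - 1], tAs[j] = tAs[j], tAs[j - 1]
                tBs[j - 1], tBs[j] = tBs[j], tBs[j - 1]
                faces[j - 1], faces[j] = faces[j], faces[j - 1]
                j -= 1
        for i in range(ncand):
            chord = tBs[i] - tAs[i]
            s_int = -math.log(np.random.random()) / mu_det
            if s_int > chord:
                continue
            tt = tAs[i] + s_int
            hx = x + tt * dx
            hy = y + tt * dy
            hz = z + tt * dz
            ksec = faces[i]
            u = -hx * face_sin[ksec] + hy * face_cos[ksec]
            col = int(math.floor((u + half_face) / pitch_t))
            if col < 0:
                col = 0
            if col >= cpf:
                col = cpf - 1
            ring = int(math.floor((hz - z_lo) / pitch_ax))
            if ring < 0:
                ring = 0
            if ring >= n_rings:
                ring = n_rings - 1
            return ring * n_det + ksec * cpf + col
        return -1
    # cylinder: annulus apothem <= r < apothem + depth
    a = dx * dx + dy * dy
    if a < _EPS:
        return -1
    b = 2.0 * (x * dx + y * dy)
    c_in = x * x + y * y - apothem * apothem
    disc = b * b - 4.0 * a * c_in
    if disc <= 0.0:
        return -1
    t0 = (-b + math.sqrt(disc)) / (2.0 * a)
    if t0 < 0.0:
        return -1
    c_out = x * x + y * y - (apothem + depth) ** 2
    disc2 = b * b - 4.0 * a * c_out
    t1 = (-b + math.sqrt(disc2)) / (2.0 * a) if disc2 > 0.0 else t0
    ta, tb = t0, t1
    if abs(dz) > _EPS:
        za = (z_lo - z) / dz
        zb = (z_hi - z) / dz
        if za > zb:
            za, zb = zb, za
        if za > ta:
            ta = za
        if zb < tb:
            tb = zb
    elif z < z_lo or z >= z_hi:
        return -1
    if tb <= ta:
        return -1
    s_int = -math.log(np.random.random()) / mu_det
    if s_int > tb - ta:
        return -1
    tt = ta + s_int
    hx = x + tt * dx
    hy = y + tt * dy
    hz = z + tt * dz
    alpha = math.atan2(hy, hx)
    dalpha = 2.0 * math.pi / n_det
    idx = int(math.floor(alpha / dalpha + cpf / 2.0)) % n_det
    ring = int(math.floor((hz - z_lo) / pitch_ax))
    if ring < 0:
        ring = 0
    if ring >= n_rings:
        ring = n_rings - 1
    return ring * n_det + idx


@njit(cache=True)
def mc_kernel(n_ann, seed,
              act_cdf, anx, any_, anz, agx0, agy0, agz0, avx, avy, avz,
              mu, mgx0, mgy0, mgz0, mvx, mvy, mvz,
              e_tab, r_tab, e_floor,
              det_mode, n_sectors, apothem, half_face, pitch_t, cpf,
              z_lo, pitch_ax, n_rings, depth, mu_det,
              e_low, e_high,
              out_id1, out_id2, out_e1, out_e2, out_nc1, out_nc2,
              singles):
    """Simulate ``n_ann`` annihilations; returns the number of coincidences.

    Emission positions are sampled proportional to activity (uniform within a
    voxel); the two photons are exactly anti-parallel at 511 keV with an
    isotropic direction (no positron range, no non-colinearity).  Each photon
    is tracked through the attenuation map with Compton-only interactions and
    detected by geometric intercept with the crystal surface; singles are
    tallied for every in-window detected photon, coincidences for pairs.
    """
    np.random.seed(seed)
    face_cos = np.empty(n_sectors)
    face_sin = np.empty(n_sectors)
    for k in range(n_sectors):
        face_cos[k] = math.cos(2.0 * math.pi * k / n_sectors)
        face_sin[k] = math.sin(2.0 * math.pi * k / n_sectors)
    n_out = 0
    n_vox = anx * any_ * anz
    for _ in range(n_ann):
        # sample emission voxel by inverse CDF (binary search), then uniform
        u = np.random.random()
        lo = 0
        hi = n_vox - 1
        while hi > lo:
            mid = (lo + hi) // 2
            if act_cdf[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        iv = lo
        k = iv % anz
        j = (iv // anz) % any_
        i = iv // (anz * any_)
        x = agx0 + (i + np.random.random()) * avx
        y = agy0 + (j + np.random.random()) * avy
        z = agz0 + (k + np.random.random()) * avz
        # isotropic direction
        cz = 1.0 - 2.0 * np.random.random()
        sz = math.sqrt(max(0.0, 1.0 - cz * cz))
        ph = 2.0 * math.pi * np.random.random()
        dx = sz * math.cos(ph)
        dy = sz * math.sin(ph)
        dz = cz

        a1, x1, y1, z1, d1x, d1y, d1z, e1, nc1 = _transport(
            x, y, z, dx, dy, dz, 511.0,
            mu, mgx0, mgy0, mgz0, mvx, mvy, mvz, e_tab, r_tab, e_floor)
        a2, x2, y2, z2, d2x, d2y, d2z, e2, nc2 = _transport(
            x, y, z, -dx, -dy, -dz, 511.0,
            mu, mgx0, mgy0, mgz0, mvx, mvy, mvz, e_tab, r_tab, e_floor)

        id1 = -1
        id2 = -1
        if a1 == 1:
            id1 = _detect(x1, y1, z1, d1x, d1y, d1z,
                          det_mode, face_cos, face_sin, apothem, half_face,
                          pitch_t, cpf, z_lo, pitch_ax, n_rings, depth, mu_det)
        if a2 == 1:
            id2 = _detect(x2, y2, z2, d2x, d2y, d2z,
                          det_mode, face_cos, face_sin, apothem, half_face,
                          pitch_t, cpf, z_lo, pitch_ax, n_rings, depth, mu_det)
        ok1 = id1 >= 0 and e_low <= e1 <= e_high
        ok2 = id2 >= 0 and e_low <= e2 <= e_high
        if ok1:
            singles[id1] += 1
        if ok2:
            singles[id2] += 1
        if ok1 and ok2 and id1 != id2:
            out_id1[n_out] = id1
            out_id2[n_out] = id2
            out_e1[n_out] = e1
            out_e2[n_out] = e2
            out_nc1[n_out] = nc1
            out_nc2[n_out] = nc2
            n_out += 1
    return n_out


# --------------------------------------------------------------------------
# single scatter simulation
# --------------------------------------------------------------------------

@njit(cache=True)
def sss_leg_integrals(det_pos, pts,
                      act, agx0, agy0, agz0, avx, avy, avz,
                      mu, mgx0, mgy0, mgz0, mvx, mvy, mvz,
                      em, tau):
    """Per (detector, scatter point) emission and 511 keV optical-depth
    integrals along the straight leg."""
    D = det_pos.shape[0]
    S = pts.shape[0]
    for d in range(D):
        for s in range(S):
            em[d, s] = fwd_ray(act, agx0, agy0, agz0, avx, avy, avz,
                               det_pos[d, 0], det_pos[d, 1], det_pos[d, 2],
                               pts[s, 0], pts[s, 1], pts[s, 2])
            tau[d, s] = fwd_ray(mu, mgx0, mgy0, mgz0, mvx, mvy, mvz,
                                det_pos[d, 0], det_pos[d, 1], det_pos[d, 2],
                                pts[s, 0], pts[s, 1], pts[s, 2])


@njit(cache=True)
def sss_direct_planes(det_pos, det_norm, n_det,
                      pts, mu_pt,
                      em, tau,
                      detA, detB, valid,
                      e_tab, r_tab, e_low, e_high,
                      out):
    """Single-scatter estimate on direct (ring1 == ring2) sinogram planes.

    For each detector pair (A, B) and scatter point S the two single-scatter
    terms are added: annihilation on the A-S leg with the second photon
    scattering at S toward B, and vice versa.  Each term combines the
    emission integral of the unscattered leg, full 511 keV attenuation of
    that leg, attenuation of the scattered leg at the down-shifted energy,
    the Klein-Nishina probability of the deflection, inverse-square and
    face-cosine solid-angle factors, and the energy-window acceptance.
    """
    R = out.shape[0]
    V, T = detA.shape
    S = pts.shape[0]
    for r in range(R):
        for v in range(V):
            for ti in range(T):
                if not valid[v, ti]:
                    continue
                da = r * n_det + detA[v, ti]
                db = r * n_det + detB[v, ti]
                ax = det_pos[da, 0]
                ay = det_pos[da, 1]
                az = det_pos[da, 2]
                bx = det_pos[db, 0]
                by = det_pos[db, 1]
                bz = det_pos[db, 2]
                acc = 0.0
                for s in range(S):
                    sx = pts[s, 0]
                    sy = pts[s, 1]
                    sz = pts[s, 2]
                    asx = sx - ax
                    asy = sy - ay
                    asz = sz - az
                    sbx = bx - sx
                    sby = by - sy
                    sbz = bz - sz
                    ras2 = asx * asx + asy * asy + asz * asz
                    rsb2 = sbx * sbx + sby * sby + sbz * sbz
                    ras = math.sqrt(ras2)
                    rsb = math.sqrt(rsb2)
                    if ras < 1.0 or rsb < 1.0:
                        continue
                    cos_t = (asx * sbx + asy * sby + asz * sbz) / (ras * rsb)
                    e_sc = 511.0 / (1.0 + (1.0 - cos_t))
                    if e_sc < e_low or e_sc > e_high:
                        continue
                    ratio = _interp_tab(e_sc, e_tab, r_tab)
                    kn = klein_nishina(cos_t, 511.0)
                    # face cosines for the two legs
                    ca = abs(asx * det_norm[da, 0] + asy * det_norm[da, 1]
                             + asz * det_norm[da, 2]) / ras
                    cb = abs(sbx * det_norm[db, 0] + sby * det_norm[db, 1]
                             + sbz * det_norm[db, 2]) / rsb
                    att_a = math.exp(-tau[da, s])
                    att_b = math.exp(-tau[db, s])
                    att_a_sc = math.exp(-tau[da, s] * ratio)
                    att_b_sc = math.exp(-tau[db, s] * ratio)
                    term = (em[da, s] * att_a * att_b_sc
                            + em[db, s] * att_b * att_a_sc)
                    acc += kn * mu_pt[s] * ca * cb * term / (ras2 * rsb2)
                out[r, v, ti] = acc
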