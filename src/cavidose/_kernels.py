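"""Numba kernels for photon-packet transport in star-shaped cavities.

Geometry is evaluated through the signed radial field
u(p) = |p| - R(p/|p|); regions are radial bands of u (void < 0,
wall [0, t_wall), adipose [t_wall, t_out), outside beyond). Free
flights use a conservative safe-step scheme: the distance from a point
to any u-level set is at least |u - level| / sup|grad u|, with
sup|grad u| <= 1 + L_R / rho (L_R the angular Lipschitz bound of the
radius function), so steps shorter than that bound provably cannot
cross a boundary. Near boundaries the flight falls back to short
marches with bisection refinement of the crossing point.

Absorption uses packet-weight attenuation at scatter events
(w -> w * albedo); packets below the weight cutoff deposit their
residual weight locally, which keeps the absorbed + escaped ledger
exactly equal to the launched weight on every run.
"""

import math

import numpy as np
from numba import njit

# region codes
VOID, WALL, ADIPOSE, OUTSIDE = 0, 1, 2, 3

# sensor angular-response codes
SENS_COS2 = 0  # cos^2 response over the void-facing hemisphere
SENS_CONE = 1  # top-hat acceptance within the NA cone


@njit(cache=True, inline="always")
def _dir_radius(kind, params, lobe_dirs, lobe_amps, lobe_kappas, dx, dy, dz):
    if kind == 0:  # sphere
        return params[0]
    elif kind == 1:  # ellipsoid
        return 1.0 / math.sqrt(
            (dx / params[0]) ** 2 + (dy / params[1]) ** 2 + (dz / params[2]) ** 2
        )
    elif kind == 2:  # superellipsoid
        e = params[3]
        s = (
            abs(dx / params[0]) ** e
            + abs(dy / params[1]) ** e
            + abs(dz / params[2]) ** e
        )
        return s ** (-1.0 / e)
    else:  # lobulated
        r = 1.0
        for i in range(lobe_amps.shape[0]):
            dot = dx * lobe_dirs[i, 0] + dy * lobe_dirs[i, 1] + dz * lobe_dirs[i, 2]
            r += lobe_amps[i] * math.exp(lobe_kappas[i] * (dot - 1.0))
        return params[0] * r


@njit(cache=True, inline="always")
def _ufield(kind, params, ld, la, lk, x, y, z):
    rho = math.sqrt(x * x + y * y + z * z)
    if rho < 1e-12:
        return -_dir_radius(kind, params, ld, la, lk, 0.0, 0.0, 1.0)
    inv = 1.0 / rho
    return rho - _dir_radius(kind, params, ld, la, lk, x * inv, y * inv, z * inv)


@njit(cache=True, inline="always")
def _region_of(u, t_wall, t_out):
    if u < 0.0:
        return VOID
    elif u < t_wall:
        return WALL
    elif u < t_out:
        return ADIPOSE
    return OUTSIDE


@njit(cache=True)
def _normal(kind, params, ld, la, lk, x, y, z):
    """Unit gradient of u (outward normal of the level sets)."""
    h = 1e-4
    gx = (
        _ufield(kind, params, ld, la, lk, x + h, y, z)
        - _ufield(kind, params, ld, la, lk, x - h, y, z)
    ) / (2.0 * h)
    gy = (
        _ufield(kind, params, ld, la, lk, x, y + h, z)
        - _ufield(kind, params, ld, la, lk, x, y - h, z)
    ) / (2.0 * h)
    gz = (
        _ufield(kind, params, ld, la, lk, x, y, z + h)
        - _ufield(kind, params, ld, la, lk, x, y, z - h)
    ) / (2.0 * h)
    norm = math.sqrt(gx * gx + gy * gy + gz * gz)
    if norm < 1e-12:
        return 0.0, 0.0, 1.0
    return gx / norm, gy / norm, gz / norm


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - f * f) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _fresnel_unpolarized(n1, n2, ci):
    """Unpolarized Fresnel power reflectance; ci = |cos incidence|."""
    if ci > 1.0:
        ci = 1.0
    si2 = 1.0 - ci * ci
    st2 = (n1 / n2) ** 2 * si2  # sin^2 transmitted (Snell)
    if st2 >= 1.0:
        return 1.0  # total internal reflection
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _rotate_direction(ux, uy, uz, ct, phi):
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz > 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _nearest_patch(patch_dirs, x, y, z):
    rho = math.sqrt(x * x + y * y + z * z)
    if rho < 1e-12:
        return 0
    best = -2.0
    ib = 0
    for i in range(patch_dirs.shape[0]):
        d = (
            patch_dirs[i, 0] * x + patch_dirs[i, 1] * y + patch_dirs[i, 2] * z
        ) / rho
        if d > best:
            best = d
            ib = i
    return ib


@njit(cache=True)
def transport_kernel(
    kind,
    params,
    lobe_dirs,
    lobe_amps,
    lobe_kappas,
    t_wall,
    t_out,
    l_angular,
    r_min,
    mua,
    mus,
    gg,
    nn,
    sx,
    sy,
    sz,
    patch_dirs,
    n_packets,
    n_half,
    seed,
    weight_cutoff,
    max_path,
    depth_bin,
    sens_axes,
    sens_kind,
    sens_coscut,
    ps_ptr,
    ps_idx,
    patch_w,
    patch_w_half,
    primary_w,
    depth_abs,
    sens_accum,
):
    """Track n_packets photon packets; fills scoring arrays in place.

    Returns (absorbed_weight, escaped_weight). mua/mus/gg/nn are indexed
    by region code (void, wall, adipose). Sensor arrays may be empty.
    """
    np.random.seed(seed)
    n_depth = depth_abs.shape[0]
    absorbed = 0.0
    escaped = 0.0
    h_min = 0.05  # mm, marching floor near boundaries
    max_events = 1_000_000

    for ip in range(n_packets):
        # isotropic launch
        ct = 2.0 * np.random.random() - 1.0
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * math.pi * np.random.random()
        ux = st * math.cos(phi)
        uy = st * math.sin(phi)
        uz = ct
        x, y, z = sx, sy, sz
        w = 1.0
        region = _region_of(_ufield(kind, params, lobe_dirs, lobe_amps, lobe_kappas, x, y, z), t_wall, t_out)
        primary = True
        path = 0.0
        events = 0
        in_first_half = ip < n_half

        alive = True
        while alive:
            mut = mua[region] + mus[region]
            if mut < 1e-12:
                s = 1e12
            else:
                s = -math.log(1.0 - np.random.random()) / mut

            # ---- free flight with conservative safe steps ----
            remaining = s
            hit = False
            new_region = region
            while remaining > 1e-12:
                u = _ufield(kind, params, lobe_dirs, lobe_amps, lobe_kappas, x, y, z)
                # distance (in u) to the nearest boundary of this region
                if region == VOID:
                    d_near = -u
                elif region == WALL:
                    d_near = u if u < t_wall - u else t_wall - u
                else:
                    d_near = u - t_wall if (u - t_wall) < (t_out - u) else t_out - u
                if d_near < 0.0:
                    d_near = 0.0
                # local bound on |grad u| over the candidate step
                rho = math.sqrt(x * x + y * y + z * z)
                l_cap = remaining if remaining < d_near else d_near
                rho_seg = rho - l_cap
                floor = 0.3 * r_min
                if rho_seg < floor:
                    rho_seg = floor
                gb = 1.0 + l_angular / rho_seg
                safe = d_near / (gb * 1.05)
                if remaining <= safe:
                    x += remaining * ux
                    y += remaining * uy
                    z += remaining * uz
                    path += remaining
                    remaining = 0.0
                    break
                step = safe * 0.95
                if step < h_min:
                    step = h_min
                if step > remaining:
                    step = remaining
                x2 = x + step * ux
                y2 = y + step * uy
                z2 = z + step * uz
                u2 = _ufield(kind, params, lobe_dirs, lobe_amps, lobe_kappas, x2, y2, z2)
                r2 = _region_of(u2, t_wall, t_out)
                if r2 == region:
                    x, y, z = x2, y2, z2
                    path += step
                    remaining -= step
                    continue
                # bisect the crossing
                lo = 0.0
                hi = step
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    um = _ufield(
                        kind, params, lobe_dirs, lobe_amps, lobe_kappas,
                        x + mid * ux, y + mid * uy, z + mid * uz,
                    )
                    if _region_of(um, t_wall, t_out) == region:
                        lo = mid
                    else:
                        hi = mid
                new_region = _region_of(
                    _ufield(
                        kind, params, lobe_dirs, lobe_amps, lobe_kappas,
                        x + hi * ux, y + hi * uy, z + hi * uz,
                    ),
                    t_wall,
                    t_out,
                )
                x += lo * ux
                y += lo * uy
                z += lo * uz
                path += lo
                hit = True
                break

            if path > max_path:
                absorbed += w
                alive = False
                continue

            if hit:
                # score irradiance exiting the void at the inner surface
                if region == VOID and new_region == WALL:
                    ipatch = _nearest_patch(patch_dirs, x, y, z)
                    patch_w[ipatch] += w
                    if in_first_half:
                        patch_w_half[ipatch] += w
                    if primary:
                        primary_w[ipatch] += w
                        primary = False
                    # virtual sensors attached to this patch
                    for k in range(ps_ptr[ipatch], ps_ptr[ipatch + 1]):
                        js = ps_idx[k]
                        ca = -(
                            ux * sens_axes[js, 0]
                            + uy * sens_axes[js, 1]
                            + uz * sens_axes[js, 2]
                        )
                        if ca > 0.0:
                            if sens_kind[js] == SENS_COS2:
                                sens_accum[js] += w * ca * ca
                            elif sens_kind[js] == SENS_CONE:
                                if ca >= sens_coscut[js]:
                                    sens_accum[js] += w
                            else:  # ideal cosine response
                                sens_accum[js] += w * ca

                if new_region == OUTSIDE:
                    escaped += w
                    alive = False
                    continue

                n1 = nn[region]
                n2 = nn[new_region]
                nx, ny, nz = _normal(kind, params, lobe_dirs, lobe_amps, lobe_kappas, x, y, z)
                # orient the normal against the direction of travel
                dn = ux * nx + uy * ny + uz * nz
                if dn > 0.0:
                    nx, ny, nz = -nx, -ny, -nz
                    dn = -dn
                ci = -dn  # cos incidence, >= 0
                if abs(n1 - n2) > 1e-12:
                    refl = _fresnel_unpolarized(n1, n2, ci)
                    if np.random.random() < refl:
                        # specular reflection, stay in current region
                        ux -= 2.0 * dn * nx
                        uy -= 2.0 * dn * ny
                        uz -= 2.0 * dn * nz
                    else:
                        eta = n1 / n2
                        st2 = eta * eta * (1.0 - ci * ci)
                        ctt = math.sqrt(max(0.0, 1.0 - st2))
                        ux = eta * ux + (eta * ci - ctt) * nx
                        uy = eta * uy + (eta * ci - ctt) * ny
                        uz = eta * uz + (eta * ci - ctt) * nz
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                # nudge off the boundary and re-evaluate the region
                x += 1e-6 * ux
                y += 1e-6 * uy
                z += 1e-6 * uz
                region = _region_of(
                    _ufield(kind, params, lobe_dirs, lobe_amps, lobe_kappas, x, y, z),
                    t_wall,
                    t_out,
                )
                if region == OUTSIDE:
                    escaped += w
                    alive = False
                else:
                    events += 1
                    if events >= max_events:
                        absorbed += w
                        alive = False
                continue

            # ---- scatter / absorption event ----
            mut = mua[region] + mus[region]
            if mut < 1e-12:
                # nothing to interact with (should not happen: s huge)
                absorbed += w
                alive = False
                continue
            dep = w * mua[region] / mut
            w -= dep
            absorbed += dep
            if region != VOID:
                u = _ufield(kind, params, lobe_dirs, lobe_amps, lobe_kappas, x, y, z)
                ib = int(u / depth_bin)
                if ib < 0:
                    ib = 0
                elif ib >= n_depth:
                    ib = n_depth - 1
                depth_abs[ib] += dep
            ct = _hg_cos(gg[region], np.random.random())
            phi = 2.0 * math.pi * np.random.random()
            ux, uy, uz = _rotate_direction(ux, uy, uz, ct, phi)
            primary = False
            events += 1
            if w < weight_cutoff or events >= max_events:
                # terminal deposit keeps the energy ledger exact
                absorbed += w
                if region != VOID:
                    u = _ufield(kind, params, lobe_dirs, lobe_amps, lobe_kappas, x, y, z)
                    ib = int(u / depth_bin)
                    if ib < 0:
                        ib = 0
                    elif ib >= n_depth:
                        ib = n_depth - 1
                    depth_abs[ib] += w
                alive = False

    return absorbed, escaped


@njit(cache=True)
def lambertian_kernel(
    radius,
    sx,
    sy,
    sz,
    rho_wall,
    patch_dirs,
    n_packets,
    n_half,
    seed,
    max_bounces,
    patch_w,
    patch_w_half,
    primary_w,
):
    """Idealized integrating-sphere mode: clear void, diffusely
    reflecting spherical wall with reflectance rho_wall.

    Every wall incidence scores; the packet is re-emitted with a
    cosine-weighted (Lambertian) direction with probability rho_wall,
    else absorbed. Returns (absorbed_weight, escaped_weight=0).
    """
    np.random.seed(seed)
    absorbed = 0.0
    for ip in range(n_packets):
        ct = 2.0 * np.random.random() - 1.0
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * math.pi * np.random.random()
        ux = st * math.cos(phi)
        uy = st * math.sin(phi)
        uz = ct
        x, y, z = sx, sy, sz
        first = True
        for _ in range(max_bounces):
            # ray-sphere intersection from inside: t = -b + sqrt(b^2 - c)
            b = x * ux + y * uy + z * uz
            c = x * x + y * y + z * z - radius * radius
            disc = b * b - c
            t = -b + math.sqrt(max(disc, 0.0))
            x += t * ux
            y += t * uy
            z += t * uz
            ipatch = _nearest_patch(patch_dirs, x, y, z)
            patch_w[ipatch] += 1.0
            if ip < n_half:
                patch_w_half[ipatch] += 1.0
            if first:
                primary_w[ipatch] += 1.0
                first = False
            if np.random.random() >= rho_wall:
                absorbed += 1.0
                break
            # Lambertian re-emission about the inward normal
            nx = -x / radius
            ny = -y / radius
            nz = -z / radius
            ctl = math.sqrt(np.random.random())
            phl = 2.0 * math.pi * np.random.random()
            ux, uy, uz = _rotate_direction(nx, ny, nz, ctl, phl)
            # pull slightly inside to avoid grazing re-intersection at t~0
            x += 1e-9 * ux
            y += 1e-9 * uy
            z += 1e-9 * uz
    return absorbed, 0.0


@njit(cache=True)
def hg_samples(g, n, seed):
    """n Henyey-Greenstein cos(theta) draws (for moment checks)."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _hg_cos(g, np.random.random())
    return out
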