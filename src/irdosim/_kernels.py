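"""Numba kernels for the analog photon transport engine.

Everything here operates on plain ndarrays prepared by :mod:`irdosim.mc_engine`.
Geometry is cylindrically symmetric: source regions are (r, z) boxes, the
phantom is a finite cylinder centered on the source, and tally cells are
annular rings.  Collision kerma is scored with a track-length estimator
(track length x E x mu_en/rho / volume); a collision-density estimator is
scored in parallel for cross-checking.

Transport modes: 0 = full analog, 1 = primary-only (any interaction
terminates the photon), 2 = streaming (no interactions; pure geometry).
"""
from __future__ import annotations

import numpy as np
from numba import njit

M_EC2 = 0.51099895


@njit(cache=True, inline="always")
def _interp_grid(arr, fi):
    i = int(fi)
    f = fi - i
    return arr[i] * (1.0 - f) + arr[i + 1] * f


@njit(cache=True, inline="always")
def _energy_index(e, log_e0, inv_dlog, ng):
    fi = (np.log(e) - log_e0) * inv_dlog
    if fi < 0.0:
        fi = 0.0
    elif fi > ng - 1.000001:
        fi = ng - 1.000001
    return fi


@njit(cache=True, inline="always")
def _classify(x, y, z, reg_rmin2, reg_rmax2, reg_zmin, reg_zmax, reg_mat, medium_mat):
    s2 = x * x + y * y
    for k in range(reg_mat.size):
        if (reg_rmin2[k] <= s2 < reg_rmax2[k]
                and reg_zmin[k] <= z < reg_zmax[k]):
            return reg_mat[k]
    return medium_mat


@njit(cache=True, inline="always")
def _step_boundary(x, y, z, ux, uy, uz, radii, zplanes):
    best = 1.0e30
    a = ux * ux + uy * uy
    if a > 0.0:
        b = x * ux + y * uy
        c0 = x * x + y * y
        for k in range(radii.size):
            rr = radii[k]
            disc = b * b - a * (c0 - rr * rr)
            if disc > 0.0:
                sq = np.sqrt(disc)
                t1 = (-b - sq) / a
                if 1e-12 < t1 < best:
                    best = t1
                t2 = (-b + sq) / a
                if 1e-12 < t2 < best:
                    best = t2
    if uz != 0.0:
        for k in range(zplanes.size):
            t = (zplanes[k] - z) / uz
            if 1e-12 < t < best:
                best = t
    return best


@njit(cache=True, inline="always")
def _phantom_exit(x, y, z, ux, uy, uz, rp, hp):
    """Distance to exit of the phantom cylinder (radius rp, |z| <= hp)."""
    best = 1.0e30
    a = ux * ux + uy * uy
    if a > 0.0:
        b = x * ux + y * uy
        disc = b * b - a * (x * x + y * y - rp * rp)
        if disc > 0.0:
            t = (-b + np.sqrt(disc)) / a
            if t > 0.0:
                best = t
    if uz > 0.0:
        t = (hp - z) / uz
        if 0.0 < t < best:
            best = t
    elif uz < 0.0:
        t = (-hp - z) / uz
        if 0.0 < t < best:
            best = t
    return best


@njit(cache=True, inline="always")
def _source_entry(x, y, z, ux, uy, uz, rb, zb_lo, zb_hi):
    """Entry distance into the source bounding cylinder, or a huge number."""
    t_lo = 1e-12
    t_hi = 1.0e30
    a = ux * ux + uy * uy
    if a > 0.0:
        b = x * ux + y * uy
        disc = b * b - a * (x * x + y * y - rb * rb)
        if disc <= 0.0:
            return 1.0e30
        sq = np.sqrt(disc)
        t1 = (-b - sq) / a
        t2 = (-b + sq) / a
        if t1 > t_lo:
            t_lo = t1
        if t2 < t_hi:
            t_hi = t2
    else:
        if x * x + y * y >= rb * rb:
            return 1.0e30
    if uz != 0.0:
        t1 = (zb_lo - z) / uz
        t2 = (zb_hi - z) / uz
        lo = min(t1, t2)
        hi = max(t1, t2)
        if lo > t_lo:
            t_lo = lo
        if hi < t_hi:
            t_hi = hi
    else:
        if not (zb_lo <= z <= zb_hi):
            return 1.0e30
    if t_hi <= t_lo:
        return 1.0e30
    return t_lo


@njit(cache=True)
def _tally_segment(tally, x, y, z, ux, uy, uz, tmax, w,
                   cz_lo, cz_hi, cs_lo2, cs_hi2, inv_vol,
                   gz_lo, gz_hi, gs_hi2):
    """Add track-length kerma contributions of one flight segment."""
    # segment bounding quick reject in z
    z2 = z + uz * tmax
    seg_zlo = min(z, z2)
    seg_zhi = max(z, z2)
    if seg_zhi < gz_lo or seg_zlo > gz_hi:
        return
    a = ux * ux + uy * uy
    b = x * ux + y * uy
    c0 = x * x + y * y
    # closest approach of the segment to the axis
    if a > 0.0:
        tstar = -b / a
        if tstar < 0.0:
            tstar = 0.0
        elif tstar > tmax:
            tstar = tmax
        s2_min = c0 + tstar * (a * tstar + 2.0 * b)
    else:
        s2_min = c0
    if s2_min > gs_hi2:
        return
    for c in range(cz_lo.size):
        # z-slab interval
        if uz != 0.0:
            t1 = (cz_lo[c] - z) / uz
            t2 = (cz_hi[c] - z) / uz
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 < 0.0:
                t1 = 0.0
            if t2 > tmax:
                t2 = tmax
            if t1 >= t2:
                continue
        else:
            if not (cz_lo[c] <= z <= cz_hi[c]):
                continue
            t1, t2 = 0.0, tmax
        # outer cylinder interval
        if a > 0.0:
            disc = b * b - a * (c0 - cs_hi2[c])
            if disc <= 0.0:
                continue
            sq = np.sqrt(disc)
            o1 = (-b - sq) / a
            o2 = (-b + sq) / a
            if o1 > t1:
                t1o = o1
            else:
                t1o = t1
            if o2 < t2:
                t2o = o2
            else:
                t2o = t2
            if t1o >= t2o:
                continue
            # inner cylinder exclusion
            length = t2o - t1o
            if cs_lo2[c] > 0.0:
                disc_i = b * b - a * (c0 - cs_lo2[c])
                if disc_i > 0.0:
                    sqi = np.sqrt(disc_i)
                    i1 = (-b - sqi) / a
                    i2 = (-b + sqi) / a
                    lo = max(i1, t1o)
                    hi = min(i2, t2o)
                    if hi > lo:
                        length -= hi - lo
            if length > 0.0:
                tally[c] += length * w * inv_vol[c]
        else:
            # axial segment: inside annulus only if s in [s_lo, s_hi]
            if cs_lo2[c] <= c0 < cs_hi2[c]:
                tally[c] += (t2 - t1) * w * inv_vol[c]


@njit(cache=True, inline="always")
def _kn_sample(e):
    """Kahn rejection sampling of the Klein-Nishina distribution.

    Returns (scattered energy, cos of the polar scattering angle)."""
    a = e / M_EC2
    p_branch = (1.0 + 2.0 * a) / (9.0 + 2.0 * a)
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= p_branch:
            eta = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / eta - 1.0 / (eta * eta)):
                mu = 1.0 - (eta - 1.0) / a
                return e / eta, mu
        else:
            eta = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2)
            mu = 1.0 - (eta - 1.0) / a
            if r3 <= 0.5 * (mu * mu + 1.0 / eta):
                return e / eta, mu


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, mu, phi):
    """Rotate a unit vector by polar angle acos(mu) and azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - mu * mu))
    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    if abs(uz) < 0.99999:
        denom = np.sqrt(1.0 - uz * uz)
        vx = mu * ux + sin_t * (cos_p * ux * uz - sin_p * uy) / denom
        vy = mu * uy + sin_t * (cos_p * uy * uz + sin_p * ux) / denom
        vz = mu * uz - sin_t * cos_p * denom
    else:
        sign = 1.0 if uz > 0.0 else -1.0
        vx = sin_t * cos_p
        vy = sin_t * sin_p
        vz = sign * mu
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(cache=True)
def run_batch(
    n, seed,
    spec_e, spec_cdf,
    log_e0, inv_dlog, ng,
    mu_tot, cum_pe, cum_inc, muen_med,
    coh_e_log0, coh_inv_dlog, coh_tab,
    reg_rmin2, reg_rmax2, reg_zmin, reg_zmax, reg_mat,
    radii, zplanes, rb, zb_lo, zb_hi,
    core_radius, core_half_z, medium_mat,
    rp, hp,
    cz_lo, cz_hi, cs_lo2, cs_hi2, inv_vol,
    e_cut, mode, use_geom,
):
    """Transport ``n`` histories; returns (track tally, collision tally,
    scored energy bookkeeping sum) with tallies already per history."""
    np.random.seed(seed)
    nc = cz_lo.size
    tally = np.zeros(nc)
    tally_col = np.zeros(nc)
    gz_lo = 1.0e30
    gz_hi = -1.0e30
    gs_hi2 = 0.0
    for c in range(nc):
        if cz_lo[c] < gz_lo:
            gz_lo = cz_lo[c]
        if cz_hi[c] > gz_hi:
            gz_hi = cz_hi[c]
        if cs_hi2[c] > gs_hi2:
            gs_hi2 = cs_hi2[c]
    rb2 = rb * rb
    nq = coh_tab.shape[2]

    for _ in range(n):
        # --- emission
        if use_geom == 1:
            s = core_radius * np.sqrt(np.random.random())
            phi = 2.0 * np.pi * np.random.random()
            x = s * np.cos(phi)
            y = s * np.sin(phi)
            z = core_half_z * (2.0 * np.random.random() - 1.0)
        else:
            x = 0.0
            y = 0.0
            z = 0.0
        cos_t = 2.0 * np.random.random() - 1.0
        sin_t = np.sqrt(1.0 - cos_t * cos_t)
        phi = 2.0 * np.pi * np.random.random()
        ux = sin_t * np.cos(phi)
        uy = sin_t * np.sin(phi)
        uz = cos_t
        # energy from the line spectrum
        u = np.random.random()
        lo = 0
        hi = spec_cdf.size - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if spec_cdf[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        e = spec_e[lo]

        fi = _energy_index(e, log_e0, inv_dlog, ng)
        w_tally = e * _interp_grid(muen_med, fi)
        tau = -np.log(np.random.random())
        alive = True
        while alive:
            s2 = x * x + y * y
            if use_geom == 1 and s2 < rb2 and zb_lo < z < zb_hi:
                mat = _classify(x, y, z, reg_rmin2, reg_rmax2,
                                reg_zmin, reg_zmax, reg_mat, medium_mat)
                d_b = _step_boundary(x, y, z, ux, uy, uz, radii, zplanes)
                at_exit = False
            else:
                mat = medium_mat
                d_exit = _phantom_exit(x, y, z, ux, uy, uz, rp, hp)
                d_b = d_exit
                at_exit = True
                if use_geom == 1:
                    d_src = _source_entry(x, y, z, ux, uy, uz, rb, zb_lo, zb_hi)
                    if d_src < d_exit:
                        d_b = d_src
                        at_exit = False
            if mode == 2:
                mu_lin = 0.0
            else:
                mu_lin = _interp_grid(mu_tot[mat], fi)
            if mu_lin * d_b >= tau:
                # collision inside this segment
                t = tau / mu_lin
                if mat == medium_mat:
                    _tally_segment(tally, x, y, z, ux, uy, uz, t, w_tally,
                                   cz_lo, cz_hi, cs_lo2, cs_hi2, inv_vol,
                                   gz_lo, gz_hi, gs_hi2)
                x += ux * t
                y += uy * t
                z += uz * t
                if mat == medium_mat:
                    # collision-density cross-check estimator
                    s2c = x * x + y * y
                    for c in range(nc):
                        if (cz_lo[c] <= z < cz_hi[c]
                                and cs_lo2[c] <= s2c < cs_hi2[c]):
                            tally_col[c] += w_tally * inv_vol[c] / mu_lin
                            break
                if mode == 1:
                    alive = False
                    break
                # channel selection
                uch = np.random.random()
                f_pe = _interp_grid(cum_pe[mat], fi)
                f_inc = _interp_grid(cum_inc[mat], fi)
                if uch < f_pe:
                    alive = False  # photoelectric absorption (local deposit)
                elif uch < f_inc:
                    e_new, mu_s = _kn_sample(e)
                    if e_new < e_cut:
                        alive = False
                    else:
                        e = e_new
                        phi_s = 2.0 * np.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, mu_s, phi_s)
                        fi = _energy_index(e, log_e0, inv_dlog, ng)
                        w_tally = e * _interp_grid(muen_med, fi)
                        tau = -np.log(np.random.random())
                else:
                    # coherent: energy unchanged, small-angle deflection
                    fe = (np.log(e) - coh_e_log0) * coh_inv_dlog
                    ie = int(fe + 0.5)
                    if ie < 0:
                        ie = 0
                    elif ie >= coh_tab.shape[1]:
                        ie = coh_tab.shape[1] - 1
                    fq = np.random.random() * (nq - 1)
                    iq = int(fq)
                    frac = fq - iq
                    mu_s = (coh_tab[mat, ie, iq] * (1.0 - frac)
                            + coh_tab[mat, ie, iq + 1] * frac)
                    phi_s = 2.0 * np.pi * np.random.random()
                    ux, uy, uz = _rotate(ux, uy, uz, mu_s, phi_s)
                    tau = -np.log(np.random.random())
            else:
                # traverse the whole sub-segment
                if mat == medium_mat:
                    _tally_segment(tally, x, y, z, ux, uy, uz, d_b, w_tally,
                                   cz_lo, cz_hi, cs_lo2, cs_hi2, inv_vol,
                                   gz_lo, gz_hi, gs_hi2)
                tau -= mu_lin * d_b
                step = d_b + 1e-9
                x += ux * step
                y += uy * step
                z += uz * step
                if at_exit and (x * x + y * y >= rp * rp * 0.999999
                                or z >= hp or z <= -hp):
                    alive = False
    inv_n = 1.0 / n
    return tally * inv_n, tally_col * inv_n


@njit(cache=True)
def kn_sample_many(e, n, seed):
    """Draw n Klein-Nishina samples at energy e; returns (E', cos theta)."""
    np.random.seed(seed)
    out_e = np.empty(n)
    out_mu = np.empty(n)
    for i in range(n):
        out_e[i], out_mu[i] = _kn_sample(e)
    return out_e, out_mu
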