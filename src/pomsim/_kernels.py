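"""Numba-compiled Gillespie kernels.

The event-driven core of the lattice model lives here.  Three kernels cover
the simulation protocols:

``_run_lattice``
    finite nucleoid + cluster, arbitrary dimer number; cluster mobile or
    frozen; optional position-conditioned accumulation of density/flux
    profiles and of the spring force on the cluster.
``_run_one_particle``
    frozen cluster, a single dimer repeatedly released on one side;
    records per-encounter stretch, duration and time-integrated force.
``_run_friction``
    unbounded lattices, a fixed set of permanently bound dimers and a
    constant external force; records the cluster trajectory.

Rates are frozen between events (the propensities are evaluated at the
time of the previous event); an optional null-event rate shortens steps to
bound the error of that approximation.  Cluster motion between events is
integrated in closed form, so there is no time-stepping error in the
overdamped force-balance dynamics.

State encoding per dimer: 0 = cytosolic, 1 = nucleoid-only, 2 = bound to
nucleoid and cluster.  Nucleoid sites sit at ``a*(i + 1/2)``; cluster site
``j`` sits at ``x_c - L_c/2 + a*(j + 1/2)``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["build_binding_table", "pruning_distance",
           "_run_lattice", "_run_one_particle", "_run_friction"]

#: Boltzmann factors below this value are pruned from the candidate-site sum.
PRUNE_FACTOR = 1e-12


def pruning_distance(k: float, kBT: float) -> float:
    """Stretch beyond which the binding Boltzmann factor is below the cutoff."""
    return math.sqrt(-2.0 * kBT * math.log(PRUNE_FACTOR) / k)


def build_binding_table(k: float, kBT: float, ka0: float, a: float,
                        n_cluster_sites: int, resolution: int = 64):
    """Tabulate the total cluster-binding rate vs. nucleoid-site offset.

    Returns ``(v0, dv, table)`` where the total rate for a dimer whose
    nucleoid site sits at offset ``v`` from cluster site 0 is the linear
    interpolation of ``table`` at ``v``.  The table resolves the Gaussian
    of width ``sqrt(kBT/k)`` with ``resolution`` points per lattice
    spacing; the interpolation error is O((dv/sigma)^2) relative.
    """
    smax = pruning_distance(k, kBT)
    v0 = -smax - a
    v1 = (n_cluster_sites - 1) * a + smax + a
    dv = a / resolution
    v = np.arange(v0, v1 + dv, dv)
    sites = np.arange(n_cluster_sites) * a
    en = (sites[None, :] - v[:, None]) ** 2 * (k / (2.0 * kBT))
    table = ka0 * np.exp(-np.minimum(en, 60.0)).sum(axis=1)
    table[np.exp(-np.minimum(en, 60.0)).max(axis=1) < PRUNE_FACTOR] = 0.0
    return v0, dv, table


@njit(cache=True, inline="always")
def _table_lookup(v, v0, dv, tab):
    idx = (v - v0) / dv
    if idx <= 0.0 or idx >= tab.shape[0] - 1:
        return 0.0
    i = int(idx)
    f = idx - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True, inline="always")
def _p_nuc_only(i_site, M, eps_n, koff, xpos, t0, v0, dv, tab):
    """Total propensity of a nucleoid-only dimer."""
    p = koff
    if i_site > 0:
        p += eps_n
    if i_site < M - 1:
        p += eps_n
    p += _table_lookup(xpos - t0, v0, dv, tab)
    return p


@njit(cache=True, inline="always")
def _p_bound(i_site, j_site, M, Mc, eps_n, eps_c, kh, s, c1, kas2):
    """Total propensity of a doubly-bound dimer with stretch ``s``."""
    E = math.exp(kas2 * s)
    p = kh
    if i_site < M - 1:          # nucleoid hop right: s -> s - a
        p += eps_n * c1 * E
    if i_site > 0:              # nucleoid hop left: s -> s + a
        p += eps_n * c1 / E
    if j_site < Mc - 1:         # cluster hop right: s -> s + a
        p += eps_c * c1 / E
    if j_site > 0:              # cluster hop left: s -> s - a
        p += eps_c * c1 * E
    return p


@njit(cache=True)
def _run_lattice(seed, N, M, Mc, a, L, Lc,
                 eps_n, eps_c, kh, koff, kon, kspr, kBT,
                 gamma_c, F_ext, lam_null,
                 x_c0, mobile, t_freeze, t_end, record_dt,
                 v0, dv, tab, smax,
                 cond_on, cond_enter_lo, cond_enter_hi,
                 cond_exit_lo, cond_exit_hi):
    np.random.seed(seed)
    c1 = math.exp(-kspr * a * a / (4.0 * kBT))
    kas2 = kspr * a / (2.0 * kBT)
    ka2 = kspr / (2.0 * kBT)

    state = np.zeros(N, dtype=np.int8)
    inuc = np.zeros(N, dtype=np.int64)
    jclu = np.zeros(N, dtype=np.int64)
    ori = np.zeros(N, dtype=np.int8)
    P = np.zeros(N)
    tl = np.zeros(N)           # last-change time for residence bookkeeping

    n_cyto = N
    n_nuc = 0
    n_bound = 0
    S = 0.0                    # total stretch of bound dimers
    x_c = x_c0
    t = 0.0

    # accumulators (absolute and cluster-relative coordinates)
    occ_n = np.zeros(M)
    occ_c = np.zeros(M)
    flux_net = np.zeros(M - 1)
    occ_n_rel = np.zeros(2 * M + 1)
    occ_c_rel = np.zeros(2 * M + 1)
    flux_rel = np.zeros(2 * M + 1)
    occ_s = np.zeros(2 * M + 1)    # time-weighted stretch occupancy (bound)
    force_dt = 0.0
    nb_dt = 0.0
    T_acc = 0.0
    n_epochs = 0

    n_rec_max = int(t_end / record_dt) + 2
    t_rec = np.zeros(n_rec_max)
    xc_rec = np.zeros(n_rec_max)
    nb_rec = np.zeros(n_rec_max, dtype=np.int64)
    nn_rec = np.zeros(n_rec_max, dtype=np.int64)
    t_rec[0] = 0.0
    xc_rec[0] = x_c
    n_rec = 1
    next_rec = record_dt

    xc_min = x_c
    xc_max = x_c

    active = False
    frac_acc = (L - Lc) / L
    need_refresh = False
    refresh_counter = 0
    t0 = x_c - Lc / 2.0 + 0.5 * a   # position of cluster site 0

    while t < t_end:
        if need_refresh:
            # cluster moved during the previous step: refresh every
            # propensity that depends on x_c (bound dimers; nucleoid-only
            # dimers inside the binding band around the footprint)
            band_lo = x_c - Lc / 2.0 - smax - 2.0 * a
            band_hi = x_c + Lc / 2.0 + smax + 2.0 * a
            for m2 in range(N):
                if state[m2] == 2:
                    sm = t0 + jclu[m2] * a - (inuc[m2] + 0.5) * a
                    P[m2] = _p_bound(inuc[m2], jclu[m2], M, Mc, eps_n,
                                     eps_c, kh, sm, c1, kas2)
                elif state[m2] == 1:
                    xp = (inuc[m2] + 0.5) * a
                    if band_lo <= xp <= band_hi:
                        P[m2] = _p_nuc_only(inuc[m2], M, eps_n, koff, xp,
                                            t0, v0, dv, tab)
            need_refresh = False
        refresh_counter += 1
        if refresh_counter >= 1 << 20:
            refresh_counter = 0
            S = 0.0
            for m2 in range(N):
                if state[m2] == 2:
                    S += t0 + jclu[m2] * a - (inuc[m2] + 0.5) * a

        # total propensity (rates frozen at the current time)
        att = kon * n_cyto * frac_acc
        alpha = att + lam_null
        for i in range(N):
            alpha += P[i]
        if alpha <= 0.0:
            t_new = t_end          # absorbing for the stochastic part
            dt = t_new - t
        else:
            xi = 1.0 - np.random.random()
            dt = -math.log(xi) / alpha
            t_new = t + dt
            if t_new > t_end:
                t_new = t_end
                dt = t_new - t

        # closed-form cluster displacement over the moving part of dt
        tau = 0.0
        if mobile:
            start_move = t if t > t_freeze else t_freeze
            if t_new > start_move:
                tau = t_new - start_move
        if tau > 0.0:
            if n_bound > 0:
                r = kspr * n_bound / gamma_c
                xstar = (F_ext - kspr * S) / (kspr * n_bound)
                dxc = xstar * (1.0 - math.exp(-r * tau))
                int_dx = xstar * (tau - (1.0 - math.exp(-r * tau)) / r)
            else:
                dxc = F_ext * tau / gamma_c
                int_dx = 0.5 * F_ext * tau * tau / gamma_c
        else:
            dxc = 0.0
            int_dx = 0.0

        # trajectory samples inside (t, t_new]
        while next_rec <= t_new and n_rec < n_rec_max:
            tau_s = 0.0
            if mobile:
                start_move = t if t > t_freeze else t_freeze
                if next_rec > start_move:
                    tau_s = next_rec - start_move
            if tau_s > 0.0:
                if n_bound > 0:
                    r = kspr * n_bound / gamma_c
                    xstar = (F_ext - kspr * S) / (kspr * n_bound)
                    xs = x_c + xstar * (1.0 - math.exp(-r * tau_s))
                else:
                    xs = x_c + F_ext * tau_s / gamma_c
            else:
                xs = x_c
            t_rec[n_rec] = next_rec
            xc_rec[n_rec] = xs
            nb_rec[n_rec] = n_bound
            nn_rec[n_rec] = n_nuc
            n_rec += 1
            next_rec += record_dt

        # accumulate over [t, t_new] while the recording condition holds
        if active:
            T_acc += dt
            nb_dt += n_bound * dt
            force_dt += -kspr * (S * dt + n_bound * int_dx)

        # apply cluster motion
        if dxc != 0.0:
            x_c += dxc
            S += n_bound * dxc
            t0 = x_c - Lc / 2.0 + 0.5 * a
            need_refresh = True
            if x_c < xc_min:
                xc_min = x_c
            if x_c > xc_max:
                xc_max = x_c
        t = t_new
        if t >= t_end:
            break

        # toggle the accumulation epoch (checked at event times; the
        # cluster moves a negligible distance within one event interval)
        was_active = active
        if cond_on:
            if active:
                if x_c < cond_exit_lo or x_c > cond_exit_hi:
                    active = False
            else:
                if cond_enter_lo <= x_c <= cond_enter_hi and t >= t_freeze:
                    active = True
                    n_epochs += 1
        else:
            active = t >= t_freeze
            if active and not was_active:
                n_epochs += 1
        if active != was_active:
            for i in range(N):
                if state[i] == 0:
                    continue
                if was_active:
                    dwell = t - tl[i]
                    if state[i] == 1:
                        occ_n[inuc[i]] += dwell
                        ridx = inuc[i] - int(math.floor(x_c / a)) + M
                        if 0 <= ridx <= 2 * M:
                            occ_n_rel[ridx] += dwell
                    else:
                        ci = int(math.floor((t0 + jclu[i] * a) / a))
                        if ci < 0:
                            ci = 0
                        if ci > M - 1:
                            ci = M - 1
                        occ_c[ci] += dwell
                        ridx = ci - int(math.floor(x_c / a)) + M
                        if 0 <= ridx <= 2 * M:
                            occ_c_rel[ridx] += dwell
                        si = t0 + jclu[i] * a - (inuc[i] + 0.5) * a
                        sidx = int(round(si / a)) + M
                        if 0 <= sidx <= 2 * M:
                            occ_s[sidx] += dwell
                tl[i] = t

        # select the event with the frozen propensities
        if alpha <= 0.0:
            break
        u = np.random.random() * alpha
        if u < lam_null:
            continue
        u -= lam_null
        if u < att:
            # cytosolic dimer attaches uniformly outside the footprint
            zl = (x_c - Lc / 2.0) / a - 0.5
            n_left = int(math.ceil(zl))
            if n_left < 0:
                n_left = 0
            if n_left > M:
                n_left = M
            zr = (x_c + Lc / 2.0) / a - 0.5
            i_right0 = int(math.floor(zr)) + 1
            if i_right0 < 0:
                i_right0 = 0
            n_right = M - i_right0
            if n_right < 0:
                n_right = 0
            n_elig = n_left + n_right
            if n_elig > 0 and n_cyto > 0:
                pick = int(np.random.random() * n_elig)
                if pick >= n_elig:
                    pick = n_elig - 1
                site = pick if pick < n_left else i_right0 + (pick - n_left)
                idx = -1
                for i in range(N):
                    if state[i] == 0:
                        idx = i
                        break
                if idx >= 0:
                    state[idx] = 1
                    inuc[idx] = site
                    ori[idx] = -1 if (site + 0.5) * a < x_c else 1
                    tl[idx] = t
                    n_cyto -= 1
                    n_nuc += 1
                    xpos = (site + 0.5) * a
                    P[idx] = _p_nuc_only(site, M, eps_n, koff, xpos, t0,
                                         v0, dv, tab)
            continue
        u -= att
        sel = -1
        for i in range(N):
            if u < P[i]:
                sel = i
                break
            u -= P[i]
        if sel < 0:
            continue  # float round-off: treat as a null event

        i = sel
        if state[i] == 1:
            site = inuc[i]
            xpos = (site + 0.5) * a
            # channel walk: hop left, hop right, detach, bind
            r_left = eps_n if site > 0 else 0.0
            r_right = eps_n if site < M - 1 else 0.0
            if u < r_left:
                if active:
                    dwell = t - tl[i]
                    occ_n[site] += dwell
                    ridx = site - int(math.floor(x_c / a)) + M
                    if 0 <= ridx <= 2 * M:
                        occ_n_rel[ridx] += dwell
                    flux_net[site - 1] -= 1.0
                    fr = site - 1 - int(math.floor(x_c / a)) + M
                    if 0 <= fr <= 2 * M:
                        flux_rel[fr] -= 1.0
                tl[i] = t
                inuc[i] = site - 1
                P[i] = _p_nuc_only(site - 1, M, eps_n, koff,
                                   xpos - a, t0, v0, dv, tab)
                continue
            u -= r_left
            if u < r_right:
                if active:
                    dwell = t - tl[i]
                    occ_n[site] += dwell
                    ridx = site - int(math.floor(x_c / a)) + M
                    if 0 <= ridx <= 2 * M:
                        occ_n_rel[ridx] += dwell
                    flux_net[site] += 1.0
                    fr = site - int(math.floor(x_c / a)) + M
                    if 0 <= fr <= 2 * M:
                        flux_rel[fr] += 1.0
                tl[i] = t
                inuc[i] = site + 1
                P[i] = _p_nuc_only(site + 1, M, eps_n, koff,
                                   xpos + a, t0, v0, dv, tab)
                continue
            u -= r_right
            if u < koff:
                if active:
                    dwell = t - tl[i]
                    occ_n[site] += dwell
                    ridx = site - int(math.floor(x_c / a)) + M
                    if 0 <= ridx <= 2 * M:
                        occ_n_rel[ridx] += dwell
                state[i] = 0
                P[i] = 0.0
                n_nuc -= 1
                n_cyto += 1
                continue
            # binding: choose the cluster site with exact Boltzmann weights
            jlo = int(math.ceil((xpos - smax - t0) / a))
            jhi = int(math.floor((xpos + smax - t0) / a))
            if jlo < 0:
                jlo = 0
            if jhi > Mc - 1:
                jhi = Mc - 1
            if jhi < jlo:
                continue
            wsum = 0.0
            for jj in range(jlo, jhi + 1):
                sij = t0 + jj * a - xpos
                wsum += math.exp(-ka2 * sij * sij)
            u3 = np.random.random() * wsum
            jsel = jhi
            for jj in range(jlo, jhi + 1):
                sij = t0 + jj * a - xpos
                w = math.exp(-ka2 * sij * sij)
                if u3 < w:
                    jsel = jj
                    break
                u3 -= w
            if active:
                dwell = t - tl[i]
                occ_n[site] += dwell
                ridx = site - int(math.floor(x_c / a)) + M
                if 0 <= ridx <= 2 * M:
                    occ_n_rel[ridx] += dwell
            tl[i] = t
            state[i] = 2
            jclu[i] = jsel
            n_nuc -= 1
            n_bound += 1
            s = t0 + jsel * a - xpos
            S += s
            P[i] = _p_bound(site, jsel, M, Mc, eps_n, eps_c, kh, s, c1, kas2)
            continue

        # state == 2: doubly bound
        site = inuc[i]
        j = jclu[i]
        xpos = (site + 0.5) * a
        s = t0 + j * a - xpos
        E = math.exp(kas2 * s)
        r_nr = eps_n * c1 * E if site < M - 1 else 0.0
        r_nl = eps_n * c1 / E if site > 0 else 0.0
        r_cr = eps_c * c1 / E if j < Mc - 1 else 0.0
        r_cl = eps_c * c1 * E if j > 0 else 0.0

        if active:
            dwell = t - tl[i]
            ci = int(math.floor((t0 + j * a) / a))
            if ci < 0:
                ci = 0
            if ci > M - 1:
                ci = M - 1
            occ_c[ci] += dwell
            ridx = ci - int(math.floor(x_c / a)) + M
            if 0 <= ridx <= 2 * M:
                occ_c_rel[ridx] += dwell
            sidx = int(round(s / a)) + M
            if 0 <= sidx <= 2 * M:
                occ_s[sidx] += dwell
        tl[i] = t

        if u < kh:
            # hydrolysis: release into the cytosol
            state[i] = 0
            P[i] = 0.0
            S -= s
            n_bound -= 1
            n_cyto += 1
        elif u < kh + r_nr:
            inuc[i] = site + 1
            S -= a
            P[i] = _p_bound(site + 1, j, M, Mc, eps_n, eps_c, kh,
                            s - a, c1, kas2)
        elif u < kh + r_nr + r_nl:
            inuc[i] = site - 1
            S += a
            P[i] = _p_bound(site - 1, j, M, Mc, eps_n, eps_c, kh,
                            s + a, c1, kas2)
        elif u < kh + r_nr + r_nl + r_cr:
            jclu[i] = j + 1
            S += a
            P[i] = _p_bound(site, j + 1, M, Mc, eps_n, eps_c, kh,
                            s + a, c1, kas2)
        elif u < kh + r_nr + r_nl + r_cr + r_cl:
            jclu[i] = j - 1
            S -= a
            P[i] = _p_bound(site, j - 1, M, Mc, eps_n, eps_c, kh,
                            s - a, c1, kas2)
        else:
            # propensity drift within the frozen-rate step: no-op
            P[i] = _p_bound(site, j, M, Mc, eps_n, eps_c, kh, s, c1, kas2)

    # final flush of open residences
    if active:
        t0 = x_c - Lc / 2.0 + 0.5 * a
        for i in range(N):
            if state[i] == 1:
                dwell = t - tl[i]
                occ_n[inuc[i]] += dwell
                ridx = inuc[i] - int(math.floor(x_c / a)) + M
                if 0 <= ridx <= 2 * M:
                    occ_n_rel[ridx] += dwell
            elif state[i] == 2:
                dwell = t - tl[i]
                ci = int(math.floor((t0 + jclu[i] * a) / a))
                if ci < 0:
                    ci = 0
                if ci > M - 1:
                    ci = M - 1
                occ_c[ci] += dwell
                ridx = ci - int(math.floor(x_c / a)) + M
                if 0 <= ridx <= 2 * M:
                    occ_c_rel[ridx] += dwell
                si = t0 + jclu[i] * a - (inuc[i] + 0.5) * a
                sidx = int(round(si / a)) + M
                if 0 <= sidx <= 2 * M:
                    occ_s[sidx] += dwell

    return (t_rec[:n_rec], xc_rec[:n_rec], nb_rec[:n_rec], nn_rec[:n_rec],
            occ_n, occ_c, flux_net, occ_n_rel, occ_c_rel, flux_rel, occ_s,
            force_dt, nb_dt, T_acc, n_epochs, xc_min, xc_max, x_c)


@njit(cache=True)
def _run_one_particle(seed, M, Mc, a, L, Lc,
                      eps_n, eps_c, kh, kspr, kBT,
                      x_c, i_start, n_int,
                      v0, dv, tab, smax):
    np.random.seed(seed)
    c1 = math.exp(-kspr * a * a / (4.0 * kBT))
    kas2 = kspr * a / (2.0 * kBT)
    ka2 = kspr / (2.0 * kBT)
    t0 = x_c - Lc / 2.0 + 0.5 * a

    s_attach = np.zeros(n_int)
    t_att_arr = np.zeros(n_int)
    t_det_arr = np.zeros(n_int)
    f_int_arr = np.zeros(n_int)
    count = 0

    t = 0.0
    bound = False
    site = i_start
    j = 0
    s = 0.0
    f_acc = 0.0
    t_att = 0.0

    while count < n_int:
        if bound:
            p = _p_bound(site, j, M, Mc, eps_n, eps_c, kh, s, c1, kas2)
        else:
            xpos = (site + 0.5) * a
            p = _p_nuc_only(site, M, eps_n, 0.0, xpos, t0, v0, dv, tab)
        xi = 1.0 - np.random.random()
        dt = -math.log(xi) / p
        t += dt
        if bound:
            f_acc += -kspr * s * dt
        u = np.random.random() * p
        if not bound:
            xpos = (site + 0.5) * a
            r_left = eps_n if site > 0 else 0.0
            r_right = eps_n if site < M - 1 else 0.0
            if u < r_left:
                site -= 1
            elif u < r_left + r_right:
                site += 1
            else:
                jlo = int(math.ceil((xpos - smax - t0) / a))
                jhi = int(math.floor((xpos + smax - t0) / a))
                if jlo < 0:
                    jlo = 0
                if jhi > Mc - 1:
                    jhi = Mc - 1
                if jhi < jlo:
                    continue
                wsum = 0.0
                for jj in range(jlo, jhi + 1):
                    sij = t0 + jj * a - xpos
                    wsum += math.exp(-ka2 * sij * sij)
                u3 = np.random.random() * wsum
                jsel = jhi
                for jj in range(jlo, jhi + 1):
                    sij = t0 + jj * a - xpos
                    w = math.exp(-ka2 * sij * sij)
                    if u3 < w:
                        jsel = jj
                        break
                    u3 -= w
                bound = True
                j = jsel
                s = t0 + j * a - xpos
                s_attach[count] = -s       # x_nuc - x_clu
                t_att = t
                f_acc = 0.0
        else:
            E = math.exp(kas2 * s)
            r_nr = eps_n * c1 * E if site < M - 1 else 0.0
            r_nl = eps_n * c1 / E if site > 0 else 0.0
            r_cr = eps_c * c1 / E if j < Mc - 1 else 0.0
            r_cl = eps_c * c1 * E if j > 0 else 0.0
            if u < kh:
                # hydrolysis: close the record, restart far on the right
                t_att_arr[count] = t_att
                t_det_arr[count] = t
                f_int_arr[count] = f_acc
                count += 1
                bound = False
                site = i_start
            elif u < kh + r_nr:
                site += 1
                s -= a
            elif u < kh + r_nr + r_nl:
                site -= 1
                s += a
            elif u < kh + r_nr + r_nl + r_cr:
                j += 1
                s += a
            elif u < kh + r_nr + r_nl + r_cr + r_cl:
                j -= 1
                s -= a
            # else: round-off no-op
    return s_attach, t_att_arr, t_det_arr, f_int_arr


@njit(cache=True)
def _run_friction(seed, Nb, a, eps_n, eps_c, kspr, kBT, gamma_c, F_ext,
                  t_end, record_dt):
    np.random.seed(seed)
    c1 = math.exp(-kspr * a * a / (4.0 * kBT))
    kas2 = kspr * a / (2.0 * kBT)

    u_rel = np.zeros(Nb)       # stretch relative to the accumulated offset
    off = 0.0                  # common stretch offset from cluster motion
    x_c = 0.0
    t = 0.0
    S = 0.0

    n_rec_max = int(t_end / record_dt) + 2
    t_rec = np.zeros(n_rec_max)
    xc_rec = np.zeros(n_rec_max)
    n_rec = 1
    next_rec = record_dt

    rates = np.zeros(4 * Nb)
    while t < t_end:
        alpha = 0.0
        for i in range(Nb):
            E = math.exp(kas2 * (u_rel[i] + off))
            rates[4 * i] = eps_n * c1 * E       # nucleoid hop right: s -= a
            rates[4 * i + 1] = eps_n * c1 / E   # nucleoid hop left:  s += a
            rates[4 * i + 2] = eps_c * c1 / E   # cluster hop right:  s += a
            rates[4 * i + 3] = eps_c * c1 * E   # cluster hop left:   s -= a
            alpha += (rates[4 * i] + rates[4 * i + 1] +
                      rates[4 * i + 2] + rates[4 * i + 3])
        if alpha <= 0.0 and Nb > 0:
            break
        if Nb == 0:
            # deterministic drift only
            x_c += F_ext * (t_end - t) / gamma_c
            while next_rec <= t_end and n_rec < n_rec_max:
                t_rec[n_rec] = next_rec
                xc_rec[n_rec] = F_ext * next_rec / gamma_c
                n_rec += 1
                next_rec += record_dt
            t = t_end
            break
        xi = 1.0 - np.random.random()
        dt = -math.log(xi) / alpha
        t_new = t + dt
        if t_new > t_end:
            t_new = t_end
        tau = t_new - t
        r = kspr * Nb / gamma_c
        xstar = (F_ext - kspr * S) / (kspr * Nb)
        dxc = xstar * (1.0 - math.exp(-r * tau))
        while next_rec <= t_new and n_rec < n_rec_max:
            tau_s = next_rec - t
            xs = x_c + xstar * (1.0 - math.exp(-r * tau_s))
            t_rec[n_rec] = next_rec
            xc_rec[n_rec] = xs
            n_rec += 1
            next_rec += record_dt
        x_c += dxc
        off += dxc
        S += Nb * dxc
        t = t_new
        if t >= t_end:
            break
        u = np.random.random() * alpha
        sel = -1
        for idx in range(4 * Nb):
            if u < rates[idx]:
                sel = idx
                break
            u -= rates[idx]
        if sel < 0:
            continue
        i = sel // 4
        ch = sel % 4
        if ch == 0 or ch == 3:
            u_rel[i] -= a
            S -= a
        else:
            u_rel[i] += a
            S += a
    return t_rec[:n_rec], xc_rec[:n_rec]
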