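"""Numba-compiled Monte Carlo integrator.

Operates on the flat arrays assembled by :mod:`heterosim.system`; the
per-move semantics mirror the reference operations in
:mod:`heterosim.engine`, :mod:`heterosim.binding` and
:mod:`heterosim.reactions`.  One step is one sweep:

1. every mobile unit, in freshly randomized order, gets Gaussian
   Metropolis moves accepted/rejected by hard-core and tether rules;
2. dissociation attempts on every bond;
3. association attempts for every eligible pair within capture radius;
4. reaction attempts (HMT methylation, then KDM demethylation);
5. sampling of methylation states / bond counts / positions.

Mobile units are either single beads (nucleosome cores, H3K9 sites, KDM)
or two-bead molecules (HP1 CD+CSD, HMT bind+cat).  A two-bead molecule
receives a *centre-of-mass* displacement drawn from the calibrated
species diffusivity — its internal tether is unchanged, so free-molecule
transport is essentially rejection-free and reproduces the species D —
plus a COM-preserving antisymmetric *internal* displacement (±e/2 on the
two beads) that relaxes the tether coordinate and gives the stationary
pair-distance density ∝ r²·w(r).

Neighbor search uses a linked-cell list with cell edge at least the
largest interaction distance; scans visit only the cells a given search
radius can reach, which stays exhaustive because the search radius never
exceeds the cell edge.

The kernel draws every random number from one numpy legacy stream seeded
once per replica, so a (config, seed) pair reproduces a trajectory
bit-for-bit.
"""

from __future__ import annotations

import math

import numba
import numpy as np

# particle kinds
CORE, H3K9, CD, CSD, BIND, CAT, KDM = 0, 1, 2, 3, 4, 5, 6
N_KINDS = 7
# enzymes
G9A, SUV, SETDB1, KDM_ENZ = 0, 1, 2, 3
# rule indices (order of config.RULE_IDS)
R_CD, R_CSD = 0, 1
R_BINDCSD = 2        # + enzyme
R_KME_G9A, R_KME_SETDB1 = 5, 6
R_CAT = 7            # + enzyme
R_KDM = 10
N_RULES = 11

# slot semantics: slot 0 = primary (reader slot on H3K9, dimer slot on CSD,
# the single slot on CD/BIND/CAT/KDM); slot 1 = cat slot on H3K9,
# HMT-recruitment slot on CSD.


@numba.njit(cache=True, inline="always", fastmath=True)
def _mi(d, box):
    if d > 0.5 * box:
        return d - box
    if d < -0.5 * box:
        return d + box
    return d


@numba.njit(cache=True, inline="always", fastmath=True)
def _wrap(x, box):
    if x >= box:
        return x - box
    if x < 0.0:
        return x + box
    return x


@numba.njit(cache=True, inline="always")
def _is_linked(i, j, sl_partner, t_indptr, t_partner):
    if sl_partner[i, 0] == j or sl_partner[i, 1] == j:
        return True
    for e in range(t_indptr[i], t_indptr[i + 1]):
        if t_partner[e] == j:
            return True
    return False


@numba.njit(cache=True, fastmath=True)
def _bead_weight(
    i, nx, ny, nz, skip,
    pos, radius, sl_partner, sl_rule,
    t_indptr, t_partner, t_min, t_free,
    damping_k, bond_slack, max_radius, box,
    use_cells, ce, ncell, heads, nxt, N,
):
    """Acceptance weight of bead ``i`` at a proposed position.

    Hard-core overlap with any non-linked particle gives 0; otherwise the
    product of tether/bond damping factors.  ``skip`` (a sibling moved in
    the same joint proposal) is excluded from every check — its
    contribution is evaluated by the caller on the new pair geometry.
    """
    ri = radius[i]
    rho = ri + max_radius
    if use_cells:
        cx = min(int(nx / ce), ncell - 1)
        cy = min(int(ny / ce), ncell - 1)
        cz = min(int(nz / ce), ncell - 1)
        lox = -1 if nx - cx * ce < rho else 0
        hix = 1 if (cx + 1) * ce - nx < rho else 0
        loy = -1 if ny - cy * ce < rho else 0
        hiy = 1 if (cy + 1) * ce - ny < rho else 0
        loz = -1 if nz - cz * ce < rho else 0
        hiz = 1 if (cz + 1) * ce - nz < rho else 0
        for ox in range(lox, hix + 1):
            cxx = cx + ox
            if cxx < 0:
                cxx += ncell
            elif cxx >= ncell:
                cxx -= ncell
            for oy in range(loy, hiy + 1):
                cyy = cy + oy
                if cyy < 0:
                    cyy += ncell
                elif cyy >= ncell:
                    cyy -= ncell
                for oz in range(loz, hiz + 1):
                    czz = cz + oz
                    if czz < 0:
                        czz += ncell
                    elif czz >= ncell:
                        czz -= ncell
                    j = heads[(cxx * ncell + cyy) * ncell + czz]
                    while j >= 0:
                        if j != i and j != skip:
                            rr = ri + radius[j]
                            ddx = _mi(nx - pos[j, 0], box)
                            if ddx * ddx < rr * rr:
                                ddy = _mi(ny - pos[j, 1], box)
                                ddz = _mi(nz - pos[j, 2], box)
                                if ddx * ddx + ddy * ddy + ddz * ddz < rr * rr:
                                    if not _is_linked(
                                        i, j, sl_partner, t_indptr, t_partner
                                    ):
                                        return 0.0
                        j = nxt[j]
    else:
        for j in range(N):
            if j == i or j == skip:
                continue
            ddx = _mi(nx - pos[j, 0], box)
            ddy = _mi(ny - pos[j, 1], box)
            ddz = _mi(nz - pos[j, 2], box)
            rr = ri + radius[j]
            if ddx * ddx + ddy * ddy + ddz * ddz < rr * rr:
                if not _is_linked(i, j, sl_partner, t_indptr, t_partner):
                    return 0.0

    w = 1.0
    for e in range(t_indptr[i], t_indptr[i + 1]):
        j = t_partner[e]
        if j == skip:
            continue
        ddx = _mi(nx - pos[j, 0], box)
        ddy = _mi(ny - pos[j, 1], box)
        ddz = _mi(nz - pos[j, 2], box)
        d = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
        if d < t_min[e]:
            return 0.0
        if d > t_free[e]:
            w *= math.exp(-damping_k * (d - t_free[e]))
    for s in range(2):
        j = sl_partner[i, s]
        if j >= 0 and j != skip:
            ddx = _mi(nx - pos[j, 0], box)
            ddy = _mi(ny - pos[j, 1], box)
            ddz = _mi(nz - pos[j, 2], box)
            d = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            mn = ri + radius[j]
            fr = mn + bond_slack
            if d < mn:
                return 0.0
            if d > fr:
                w *= math.exp(-damping_k * (d - fr))
    return w


@numba.njit(cache=True, inline="always", fastmath=True)
def _apply_move(
    i, dx, dy, dz, nx, ny, nz,
    pos, upos, use_cells, ce, ncell, heads, nxt, cell_of,
):
    upos[i, 0] += dx
    upos[i, 1] += dy
    upos[i, 2] += dz
    pos[i, 0] = nx
    pos[i, 1] = ny
    pos[i, 2] = nz
    if use_cells:
        cx = min(int(nx / ce), ncell - 1)
        cy = min(int(ny / ce), ncell - 1)
        cz = min(int(nz / ce), ncell - 1)
        c = (cx * ncell + cy) * ncell + cz
        co = cell_of[i]
        if c != co:
            h = heads[co]
            if h == i:
                heads[co] = nxt[i]
            else:
                while nxt[h] != i:
                    h = nxt[h]
                nxt[h] = nxt[i]
            nxt[i] = heads[c]
            heads[c] = i
            cell_of[i] = c


@numba.njit(cache=True, fastmath=True)
def run_kernel(
    # state (mutated in place)
    pos, upos, meth, sl_partner, sl_rule, sl_formed, sl_back,
    cat_active, cat_reactivate,
    # static particle attributes
    kind, enzyme, radius, sibling, nuc_of, perm,
    # mobile units: single beads (mv_b < 0) or two-bead molecules
    mv_a, mv_b, mv_sig, mv_sigint, mv_imin, mv_ifree,
    # permanent tethers (CSR, both directions)
    t_indptr, t_partner, t_min, t_free,
    # rule tables
    pa, pd, capture2, pt_hmt, pt_kdm, assoc_range,
    # geometry / run controls
    box, ncell, damping_k, bond_slack, max_step, max_radius,
    n_steps, report_interval, step_offset, refractory, seed,
    # outputs
    samp_meth, samp_bonds, samp_pos, record_positions,
    ev_step, ev_enzyme, ev_nuc, ev_from, ev_to,
    lt_rule, lt_dur, lt_n, lt_sum, cens_n, cens_sum,
):
    np.random.seed(seed)
    N = pos.shape[0]
    M = mv_a.shape[0]
    use_cells = ncell >= 3
    ncells = ncell * ncell * ncell
    ce = box / ncell if use_cells else box

    heads = np.full(ncells, -1, dtype=np.int32)
    nxt = np.full(N, -1, dtype=np.int32)
    cell_of = np.zeros(N, dtype=np.int32)
    if use_cells:
        for i in range(N):
            cx = min(int(pos[i, 0] / ce), ncell - 1)
            cy = min(int(pos[i, 1] / ce), ncell - 1)
            cz = min(int(pos[i, 2] / ce), ncell - 1)
            c = (cx * ncell + cy) * ncell + cz
            cell_of[i] = c
            nxt[i] = heads[c]
            heads[c] = i

    morder = np.arange(M).astype(np.int32)
    aorder = np.arange(N).astype(np.int32)
    cap2 = max_step * max_step
    ev_count = 0
    ev_cap = ev_step.shape[0]
    lt_count = 0
    lt_cap = lt_rule.shape[0]
    sample_i = 0

    for t0 in range(n_steps):
        t = step_offset + t0

        # ---------------- moves ----------------
        for a in range(M - 1, 0, -1):
            b = int(np.random.random() * (a + 1))
            tmp = morder[a]
            morder[a] = morder[b]
            morder[b] = tmp
        for om in range(M):
            m = morder[om]
            ia = mv_a[m]
            ib = mv_b[m]
            sg = mv_sig[m]
            if sg <= 0.0:
                continue
            if ib < 0:
                # single bead
                while True:
                    dx = sg * np.random.standard_normal()
                    dy = sg * np.random.standard_normal()
                    dz = sg * np.random.standard_normal()
                    if dx * dx + dy * dy + dz * dz <= cap2:
                        break
                nx = _wrap(pos[ia, 0] + dx, box)
                ny = _wrap(pos[ia, 1] + dy, box)
                nz = _wrap(pos[ia, 2] + dz, box)
                w = _bead_weight(
                    ia, nx, ny, nz, -1,
                    pos, radius, sl_partner, sl_rule,
                    t_indptr, t_partner, t_min, t_free,
                    damping_k, bond_slack, max_radius, box,
                    use_cells, ce, ncell, heads, nxt, N,
                )
                if w <= 0.0:
                    continue
                if w < 1.0 and np.random.random() >= w:
                    continue
                _apply_move(
                    ia, dx, dy, dz, nx, ny, nz,
                    pos, upos, use_cells, ce, ncell, heads, nxt, cell_of,
                )
            else:
                # --- centre-of-mass move of a two-bead molecule ---
                while True:
                    dx = sg * np.random.standard_normal()
                    dy = sg * np.random.standard_normal()
                    dz = sg * np.random.standard_normal()
                    if dx * dx + dy * dy + dz * dz <= cap2:
                        break
                nax = _wrap(pos[ia, 0] + dx, box)
                nay = _wrap(pos[ia, 1] + dy, box)
                naz = _wrap(pos[ia, 2] + dz, box)
                nbx = _wrap(pos[ib, 0] + dx, box)
                nby = _wrap(pos[ib, 1] + dy, box)
                nbz = _wrap(pos[ib, 2] + dz, box)
                w = _bead_weight(
                    ia, nax, nay, naz, ib,
                    pos, radius, sl_partner, sl_rule,
                    t_indptr, t_partner, t_min, t_free,
                    damping_k, bond_slack, max_radius, box,
                    use_cells, ce, ncell, heads, nxt, N,
                )
                if w > 0.0:
                    w *= _bead_weight(
                        ib, nbx, nby, nbz, ia,
                        pos, radius, sl_partner, sl_rule,
                        t_indptr, t_partner, t_min, t_free,
                        damping_k, bond_slack, max_radius, box,
                        use_cells, ce, ncell, heads, nxt, N,
                    )
                if w > 0.0 and (w >= 1.0 or np.random.random() < w):
                    _apply_move(
                        ia, dx, dy, dz, nax, nay, naz,
                        pos, upos, use_cells, ce, ncell, heads, nxt, cell_of,
                    )
                    _apply_move(
                        ib, dx, dy, dz, nbx, nby, nbz,
                        pos, upos, use_cells, ce, ncell, heads, nxt, cell_of,
                    )
                # --- COM-preserving internal relaxation move ---
                # (alternating steps; tether relaxation stays ~µs-scale,
                # orders of magnitude below any binding timescale)
                if (t + m) & 1:
                    continue
                sgi = mv_sigint[m]
                while True:
                    ex = sgi * np.random.standard_normal()
                    ey = sgi * np.random.standard_normal()
                    ez = sgi * np.random.standard_normal()
                    if ex * ex + ey * ey + ez * ez <= cap2:
                        break
                hx = 0.5 * ex
                hy = 0.5 * ey
                hz = 0.5 * ez
                nax = _wrap(pos[ia, 0] + hx, box)
                nay = _wrap(pos[ia, 1] + hy, box)
                naz = _wrap(pos[ia, 2] + hz, box)
                nbx = _wrap(pos[ib, 0] - hx, box)
                nby = _wrap(pos[ib, 1] - hy, box)
                nbz = _wrap(pos[ib, 2] - hz, box)
                ddx = _mi(nax - nbx, box)
                ddy = _mi(nay - nby, box)
                ddz = _mi(naz - nbz, box)
                d_ab = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                if d_ab < mv_imin[m]:
                    continue
                w = 1.0
                if d_ab > mv_ifree[m]:
                    w = math.exp(-damping_k * (d_ab - mv_ifree[m]))
                w2 = _bead_weight(
                    ia, nax, nay, naz, ib,
                    pos, radius, sl_partner, sl_rule,
                    t_indptr, t_partner, t_min, t_free,
                    damping_k, bond_slack, max_radius, box,
                    use_cells, ce, ncell, heads, nxt, N,
                )
                if w2 <= 0.0:
                    continue
                w *= w2
                w2 = _bead_weight(
                    ib, nbx, nby, nbz, ia,
                    pos, radius, sl_partner, sl_rule,
                    t_indptr, t_partner, t_min, t_free,
                    damping_k, bond_slack, max_radius, box,
                    use_cells, ce, ncell, heads, nxt, N,
                )
                if w2 <= 0.0:
                    continue
                w *= w2
                if w < 1.0 and np.random.random() >= w:
                    continue
                _apply_move(
                    ia, hx, hy, hz, nax, nay, naz,
                    pos, upos, use_cells, ce, ncell, heads, nxt, cell_of,
                )
                _apply_move(
                    ib, -hx, -hy, -hz, nbx, nby, nbz,
                    pos, upos, use_cells, ce, ncell, heads, nxt, cell_of,
                )

        # ---------------- dissociation ----------------
        for i in range(N):
            for s in range(2):
                j = sl_partner[i, s]
                if j <= i:
                    continue
                r = sl_rule[i, s]
                if np.random.random() < pd[r]:
                    dur = t - sl_formed[i, s]
                    lt_n[r] += 1
                    lt_sum[r] += dur
                    if lt_count < lt_cap:
                        lt_rule[lt_count] = r
                        lt_dur[lt_count] = dur
                        lt_count += 1
                    sb = sl_back[i, s]
                    sl_partner[j, sb] = -1
                    sl_rule[j, sb] = -1
                    sl_partner[i, s] = -1
                    sl_rule[i, s] = -1
                    if refractory == 0:
                        # dissociation-gated reactivation of the cat bead
                        if kind[i] == CAT:
                            cat_active[i] = True
                        elif kind[j] == CAT:
                            cat_active[j] = True

        # ---------------- association ----------------
        # Pairs are enumerated once per step from the target side (H3K9
        # sites and HP1-CSD beads) in randomized order; each eligible pair
        # in capture range gets one Bernoulli(pa) attempt.
        for a in range(N - 1, 0, -1):
            b = int(np.random.random() * (a + 1))
            tmp = aorder[a]
            aorder[a] = aorder[b]
            aorder[b] = tmp
        for oi in range(N):
            i = aorder[oi]
            ki = kind[i]
            if ki != H3K9 and ki != CSD:
                continue
            if sl_partner[i, 0] >= 0 and sl_partner[i, 1] >= 0:
                continue
            rho = assoc_range[ki]
            px = pos[i, 0]
            py = pos[i, 1]
            pz = pos[i, 2]
            done = False
            if use_cells:
                cx = min(int(px / ce), ncell - 1)
                cy = min(int(py / ce), ncell - 1)
                cz = min(int(pz / ce), ncell - 1)
                lox = -1 if px - cx * ce < rho else 0
                hix = 1 if (cx + 1) * ce - px < rho else 0
                loy = -1 if py - cy * ce < rho else 0
                hiy = 1 if (cy + 1) * ce - py < rho else 0
                loz = -1 if pz - cz * ce < rho else 0
                hiz = 1 if (cz + 1) * ce - pz < rho else 0
                for ox in range(lox, hix + 1):
                    cxx = cx + ox
                    if cxx < 0:
                        cxx += ncell
                    elif cxx >= ncell:
                        cxx -= ncell
                    for oy in range(loy, hiy + 1):
                        cyy = cy + oy
                        if cyy < 0:
                            cyy += ncell
                        elif cyy >= ncell:
                            cyy -= ncell
                        for oz in range(loz, hiz + 1):
                            czz = cz + oz
                            if czz < 0:
                                czz += ncell
                            elif czz >= ncell:
                                czz -= ncell
                            j = heads[(cxx * ncell + cyy) * ncell + czz]
                            while j >= 0:
                                if j != i:
                                    done = _try_bind_target(
                                        i, j, ki, t,
                                        pos, meth, nuc_of, kind, enzyme,
                                        sl_partner, sl_rule, sl_formed, sl_back,
                                        pa, capture2, box,
                                    )
                                    if done:
                                        break
                                j = nxt[j]
                            if done:
                                break
                        if done:
                            break
                    if done:
                        break
            else:
                for j in range(N):
                    if j == i:
                        continue
                    done = _try_bind_target(
                        i, j, ki, t,
                        pos, meth, nuc_of, kind, enzyme,
                        sl_partner, sl_rule, sl_formed, sl_back,
                        pa, capture2, box,
                    )
                    if done:
                        break

        # ---------------- reactions ----------------
        for i in range(N):
            ki = kind[i]
            if ki == CAT:
                j = sl_partner[i, 0]
                if j < 0:
                    continue
                nuc = nuc_of[j]
                m = meth[nuc]
                if m > 2:
                    continue
                if refractory > 0:
                    if t < cat_reactivate[i]:
                        continue
                elif not cat_active[i]:
                    continue
                bpar = sibling[i]
                p = sl_partner[bpar, 0]
                if p < 0:
                    continue
                anchored = False
                if kind[p] == H3K9:
                    anchored = True
                elif kind[p] == CSD:
                    cdb = sibling[p]
                    if sl_partner[cdb, 0] >= 0:
                        anchored = True
                if not anchored:
                    continue
                e = enzyme[i]
                if np.random.random() < pt_hmt[e, m]:
                    meth[nuc] = m + 1
                    if ev_count < ev_cap:
                        ev_step[ev_count] = t
                        ev_enzyme[ev_count] = e
                        ev_nuc[ev_count] = nuc
                        ev_from[ev_count] = m
                        ev_to[ev_count] = m + 1
                        ev_count += 1
                    if refractory > 0:
                        cat_reactivate[i] = t + refractory
                    else:
                        cat_active[i] = False
            elif ki == KDM:
                j = sl_partner[i, 0]
                if j < 0:
                    continue
                nuc = nuc_of[j]
                m = meth[nuc]
                if m < 1 or perm[nuc]:
                    continue
                if np.random.random() < pt_kdm[m - 1]:
                    meth[nuc] = m - 1
                    if ev_count < ev_cap:
                        ev_step[ev_count] = t
                        ev_enzyme[ev_count] = KDM_ENZ
                        ev_nuc[ev_count] = nuc
                        ev_from[ev_count] = m
                        ev_to[ev_count] = m - 1
                        ev_count += 1

        # ---------------- sampling ----------------
        if (t0 + 1) % report_interval == 0:
            for q in range(meth.shape[0]):
                samp_meth[sample_i, q] = meth[q]
            for i in range(N):
                for s in range(2):
                    j = sl_partner[i, s]
                    if j > i:
                        samp_bonds[sample_i, sl_rule[i, s]] += 1
            if record_positions:
                for i in range(N):
                    samp_pos[sample_i, i, 0] = upos[i, 0]
                    samp_pos[sample_i, i, 1] = upos[i, 1]
                    samp_pos[sample_i, i, 2] = upos[i, 2]
            sample_i += 1

    # censored bond lifetimes at trajectory end
    t_end = step_offset + n_steps
    for i in range(N):
        for s in range(2):
            j = sl_partner[i, s]
            if j > i:
                r = sl_rule[i, s]
                cens_n[r] += 1
                cens_sum[r] += t_end - sl_formed[i, s]

    return ev_count, lt_count


@numba.njit(cache=True, inline="always", fastmath=True)
def _try_bind_target(
    i, j, ki, t,
    pos, meth, nuc_of, kind, enzyme,
    sl_partner, sl_rule, sl_formed, sl_back,
    pa, capture2, box,
):
    """Attempt one association between target i (H3K9 site or CSD) and
    binder candidate j.  Returns True when both of i's slots are now
    occupied (the scan over candidates may stop)."""
    kj = kind[j]
    r = -1
    islot = -1
    if ki == H3K9:
        m = meth[nuc_of[i]]
        if kj == CD:
            if sl_partner[i, 0] < 0 and sl_partner[j, 0] < 0 and m >= 2:
                r = R_CD
                islot = 0
        elif kj == CAT:
            if sl_partner[i, 1] < 0 and sl_partner[j, 0] < 0 and m <= 2:
                r = R_CAT + enzyme[j]
                islot = 1
        elif kj == KDM:
            if sl_partner[i, 0] < 0 and sl_partner[j, 0] < 0 and m >= 1:
                r = R_KDM
                islot = 0
        elif kj == BIND:
            enz = enzyme[j]
            if (
                sl_partner[i, 0] < 0
                and sl_partner[j, 0] < 0
                and m >= 1
                and (enz == G9A or enz == SETDB1)
            ):
                r = R_KME_G9A if enz == G9A else R_KME_SETDB1
                islot = 0
    else:  # CSD target
        if kj == CSD:
            if j > i and sl_partner[i, 0] < 0 and sl_partner[j, 0] < 0:
                r = R_CSD
                islot = 0
        elif kj == BIND:
            if sl_partner[i, 1] < 0 and sl_partner[j, 0] < 0:
                r = R_BINDCSD + enzyme[j]
                islot = 1
    if r < 0:
        return False
    ddx = _mi(pos[i, 0] - pos[j, 0], box)
    ddy = _mi(pos[i, 1] - pos[j, 1], box)
    ddz = _mi(pos[i, 2] - pos[j, 2], box)
    if ddx * ddx + ddy * ddy + ddz * ddz > capture2[r]:
        return False
    if np.random.random() >= pa[r]:
        return False
    sl_partner[i, islot] = j
    sl_rule[i, islot] = r
    sl_formed[i, islot] = t
    sl_back[i, islot] = 0
    sl_partner[j, 0] = i
    sl_rule[j, 0] = r
    sl_formed[j, 0] = t
    sl_back[j, 0] = islot
    return sl_partner[i, 0] >= 0 and sl_partner[i, 1] >= 0
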