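"""Numba kernels for the cellular-Potts engine and the gap-junction label model.

Everything here operates on flat numpy arrays owned by
:class:`cardiolattice.lattice.LatticeState`; the public API lives in
:mod:`cardiolattice.ggh`.  The kernels are deliberately free of Python
objects so that a full Monte-Carlo step (N copy attempts, N = rows x cols)
runs at native speed.

Random-draw contract (reproducibility): every copy attempt consumes exactly
three uniforms from the passed generator -- target row, target column,
neighbour choice -- plus one more if and only if the Metropolis test is
reached with delta-H > 0.  Gap-junction swap attempts follow the same
pattern.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# outcome codes for a copy attempt
REJECTED, FORBIDDEN, ACCEPTED = 0, 1, 2

# 8-connected (Moore) neighbourhood used for adhesion energy and for
# source selection; 4-connectivity is used for the connectivity rule.
MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)
VON_NEUMANN = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)], dtype=np.int64)

# column layout of the per-cell float parameter table
PF_LAM, PF_TVOL, PF_G, PF_PDET, PF_PUNL, PF_LMAX2, PF_PN = range(7)


@njit(cache=True, inline="always")
def _protr_term(ar, ac, cm_r, cm_c, G, on_fibre, fibre_ang,
                cos_floor, rho_floor):
    """Energy of one focal adhesion at (ar, ac) for a cell with cm (cm_r, cm_c)."""
    dr = ar - cm_r
    dc = ac - cm_c
    rho = np.sqrt(dr * dr + dc * dc)
    if rho < rho_floor:
        rho = rho_floor
    if on_fibre:
        theta = np.arctan2(dr, dc)
        ca = np.abs(np.cos(fibre_ang - theta))
        if ca < cos_floor:
            ca = cos_floor
        return G / (rho * ca)
    return G / rho


@njit(cache=True)
def _delta_h(tr, tc, sr, sc, sigma, ctype, vol, sum_r, sum_c,
             cellf, adh_r, adh_c, adh_n, adh_grid,
             fibre_on, fibre_ang, J, cos_floor, rho_floor, nuc_r2):
    """Exact change in total energy for copying sigma[sr,sc] onto (tr,tc),
    including the P_detach / P_unleash transition penalties."""
    H, W = sigma.shape
    s = sigma[sr, sc]
    t = sigma[tr, tc]
    dH = 0.0

    # --- adhesive recount over the Moore neighbourhood of the target
    tau_s = ctype[s]
    tau_t = ctype[t]
    for k in range(8):
        nr = tr + MOORE[k, 0]
        nc = tc + MOORE[k, 1]
        if nr < 0 or nr >= H or nc < 0 or nc >= W:
            nb = 0  # closed boundary: the outside is medium
            tau_n = 0
        else:
            nb = sigma[nr, nc]
            tau_n = ctype[nb]
        if nb != s:
            dH += J[tau_s, tau_n]
        if nb != t:
            dH -= J[tau_t, tau_n]

    # --- elastic terms for both affected cells
    if s != 0:
        v = vol[s]
        tv = cellf[s, PF_TVOL]
        dH += cellf[s, PF_LAM] * ((v + 1 - tv) ** 2 - (v - tv) ** 2)
    if t != 0:
        v = vol[t]
        tv = cellf[t, PF_TVOL]
        dH += cellf[t, PF_LAM] * ((v - 1 - tv) ** 2 - (v - tv) ** 2)

    destroyed = adh_grid[tr, tc] != 0 and t != 0
    # a copy whose source subcell is one of its cell's focal adhesions
    # moves that adhesion outward with the protrusion tip
    moved = s != 0 and adh_grid[sr, sc] != 0

    # --- protrusion term: the 1/rho potential is a field sourced at the
    # (quasi-static) centre of mass acting on the attachment sites; only
    # a moved site does work in it.  A destroyed adhesion vanishes
    # without releasing its stored potential (non-conservative event,
    # charged P_detach below).
    if moved:
        v = vol[s]
        cm_r0 = sum_r[s] / v
        cm_c0 = sum_c[s] / v
        G = cellf[s, PF_G]
        dH += _protr_term(tr, tc, cm_r0, cm_c0, G,
                          fibre_on[tr, tc], fibre_ang[tr, tc],
                          cos_floor, rho_floor)
        dH -= _protr_term(sr, sc, cm_r0, cm_c0, G,
                          fibre_on[sr, sc], fibre_ang[sr, sc],
                          cos_floor, rho_floor)

    # --- stiff-nucleus penalty: invading (medium or foreign cell) a
    # subcell within the nucleus radius of the invaded cell's centre of
    # mass is penalised with P_N = 2 P_detach of that cell
    if t != 0:
        pn = cellf[t, PF_PN]
        if pn > 0.0:
            v = vol[t]
            dr_n = tr - sum_r[t] / v
            dc_n = tc - sum_c[t] / v
            if dr_n * dr_n + dc_n * dc_n < nuc_r2:
                dH += pn

    # --- transition penalties (not part of the state energy)
    if destroyed:
        dH += cellf[t, PF_PDET]
    if moved and fibre_on[sr, sc] != 0 and fibre_on[tr, tc] == 0:
        dH += cellf[s, PF_PUNL]

    return dH


# Moore ring in cyclic order (consecutive entries are 4-adjacent)
RING = np.array([(-1, 0), (-1, 1), (0, 1), (1, 1),
                 (1, 0), (1, -1), (0, -1), (-1, -1)], dtype=np.int64)


@njit(cache=True)
def _connectivity_ok(tr, tc, sigma, vol, bbox, visited, gen, stack):
    """Connectivity rule: local Moore-ring arc test as a sufficient fast
    path, full bounded flood fill when inconclusive."""
    cell = sigma[tr, tc]
    H, W = sigma.shape
    n4 = 0
    seed_r = -1
    seed_c = -1
    for k in range(4):
        nr = tr + VON_NEUMANN[k, 0]
        nc = tc + VON_NEUMANN[k, 1]
        if 0 <= nr < H and 0 <= nc < W and sigma[nr, nc] == cell:
            n4 += 1
            seed_r = nr
            seed_c = nc
    if n4 <= 1:
        return True
    # fast path: if the cell's sites on the 8-ring around t form exactly
    # one cyclically contiguous arc, the remainder stays connected and no
    # flood fill is needed (sufficient, not necessary)
    ring_in = np.zeros(8, dtype=np.uint8)
    for k in range(8):
        nr = tr + RING[k, 0]
        nc = tc + RING[k, 1]
        if 0 <= nr < H and 0 <= nc < W and sigma[nr, nc] == cell:
            ring_in[k] = 1
    arcs = 0
    total = 0
    for k in range(8):
        total += ring_in[k]
        if ring_in[k] == 1 and ring_in[(k + 7) % 8] == 0:
            arcs += 1
    if arcs == 1 or total == 8:
        return True
    rmin = bbox[cell, 0]
    rmax = bbox[cell, 1]
    cmin = bbox[cell, 2]
    cmax = bbox[cell, 3]
    gen[0] += 1
    g = gen[0]
    visited[tr, tc] = g
    visited[seed_r, seed_c] = g
    stack[0, 0] = seed_r
    stack[0, 1] = seed_c
    top = 1
    reached = 1
    while top > 0:
        top -= 1
        r = stack[top, 0]
        c = stack[top, 1]
        for k in range(4):
            nr = r + VON_NEUMANN[k, 0]
            nc = c + VON_NEUMANN[k, 1]
            if nr < rmin or nr > rmax or nc < cmin or nc > cmax:
                continue
            if visited[nr, nc] == g or sigma[nr, nc] != cell:
                continue
            visited[nr, nc] = g
            stack[top, 0] = nr
            stack[top, 1] = nc
            top += 1
            reached += 1
    return reached == vol[cell] - 1


@njit(cache=True)
def _apply_copy(tr, tc, sr, sc, sigma, vol, sum_r, sum_c,
                celli, adh_r, adh_c, adh_n, adh_grid, bbox):
    """Commit an accepted copy: sigma, volumes, cm sums, bounding boxes and
    focal-adhesion bookkeeping."""
    s = sigma[sr, sc]
    t = sigma[tr, tc]
    if t != 0 and adh_grid[tr, tc] != 0:
        # destroyed adhesion: swap-remove from the owner's list
        n = adh_n[t]
        for k in range(n):
            if adh_r[t, k] == tr and adh_c[t, k] == tc:
                adh_r[t, k] = adh_r[t, n - 1]
                adh_c[t, k] = adh_c[t, n - 1]
                adh_n[t] = n - 1
                break
        adh_grid[tr, tc] = 0
    moved = s != 0 and adh_grid[sr, sc] != 0
    sigma[tr, tc] = s
    if t != 0:
        vol[t] -= 1
        sum_r[t] -= tr
        sum_c[t] -= tc
    if s != 0:
        vol[s] += 1
        sum_r[s] += tr
        sum_c[s] += tc
        if tr < bbox[s, 0]:
            bbox[s, 0] = tr
        if tr > bbox[s, 1]:
            bbox[s, 1] = tr
        if tc < bbox[s, 2]:
            bbox[s, 2] = tc
        if tc > bbox[s, 3]:
            bbox[s, 3] = tc
        if moved:
            # the protruding attachment site relocates to the new tip
            for k in range(adh_n[s]):
                if adh_r[s, k] == sr and adh_c[s, k] == sc:
                    adh_r[s, k] = tr
                    adh_c[s, k] = tc
                    break
            adh_grid[sr, sc] = 0
            adh_grid[tr, tc] = 1
        elif adh_n[s] < celli[s, 0]:
            # a successful border expansion below quota seeds a new adhesion
            k = adh_n[s]
            adh_r[s, k] = tr
            adh_c[s, k] = tc
            adh_n[s] = k + 1
            adh_grid[tr, tc] = 1


@njit(cache=True)
def _attachment_hop(rng, tr, tc, sr, sc, sigma, vol, sum_r, sum_c, cellf,
                    adh_r, adh_c, adh_n, adh_grid, fibre_on, fibre_ang,
                    T, cos_floor, rho_floor, out):
    """Move an attachment site to a neighbouring subcell of its cell.

    Driven by the 1/rho protrusion field (frozen centre of mass), with
    P_unleash for fibre -> substrate moves and P_detach when the target
    subcell already holds another attachment (which is destroyed)."""
    cell = sigma[sr, sc]
    v = vol[cell]
    cm_r = sum_r[cell] / v
    cm_c = sum_c[cell] / v
    # the protrusion may not spread farther than L_MAX from the cm
    dr = tr - cm_r
    dc = tc - cm_c
    if dr * dr + dc * dc > cellf[cell, PF_LMAX2]:
        return FORBIDDEN
    G = cellf[cell, PF_G]
    dH = _protr_term(tr, tc, cm_r, cm_c, G, fibre_on[tr, tc],
                     fibre_ang[tr, tc], cos_floor, rho_floor) \
        - _protr_term(sr, sc, cm_r, cm_c, G, fibre_on[sr, sc],
                      fibre_ang[sr, sc], cos_floor, rho_floor)
    if fibre_on[sr, sc] != 0 and fibre_on[tr, tc] == 0:
        dH += cellf[cell, PF_PUNL]
    destroyed = adh_grid[tr, tc] != 0
    if destroyed:
        dH += cellf[cell, PF_PDET]
    out[4] = dH
    if dH > 0.0:
        if rng.random() >= np.exp(-dH / T):
            return REJECTED
    if destroyed:
        n = adh_n[cell]
        for k in range(n):
            if adh_r[cell, k] == tr and adh_c[cell, k] == tc:
                adh_r[cell, k] = adh_r[cell, n - 1]
                adh_c[cell, k] = adh_c[cell, n - 1]
                adh_n[cell] = n - 1
                break
    for k in range(adh_n[cell]):
        if adh_r[cell, k] == sr and adh_c[cell, k] == sc:
            adh_r[cell, k] = tr
            adh_c[cell, k] = tc
            break
    adh_grid[sr, sc] = 0
    adh_grid[tr, tc] = 1
    return ACCEPTED


@njit(cache=True)
def _attempt(rng, sigma, mask, ctype, vol, sum_r, sum_c, cellf, celli,
             adh_r, adh_c, adh_n, adh_grid, bbox,
             fibre_on, fibre_ang, J, T, cos_floor, rho_floor, nuc_r2,
             visited, gen, stack, out):
    """One copy attempt.  Returns the outcome code; fills ``out`` with
    (tr, tc, sr, sc, dH)."""
    H, W = sigma.shape
    tr = int(rng.random() * H)
    tc = int(rng.random() * W)
    k = int(rng.random() * 8)
    sr = tr + MOORE[k, 0]
    sc = tc + MOORE[k, 1]
    out[0] = tr
    out[1] = tc
    out[2] = sr
    out[3] = sc
    out[4] = 0.0
    if sr < 0 or sr >= H or sc < 0 or sc >= W:
        return REJECTED
    if mask[tr, tc] == 0 or mask[sr, sc] == 0:
        return REJECTED
    s = sigma[sr, sc]
    t = sigma[tr, tc]
    if s == t:
        # same-index pair: no lattice copy, but an attachment site may
        # hop to a neighbouring subcell of its own cell (protrusion-tip
        # migration in the 1/rho field)
        if s != 0 and adh_grid[sr, sc] != 0 and (sr != tr or sc != tc):
            return _attachment_hop(rng, tr, tc, sr, sc, sigma, vol,
                                   sum_r, sum_c, cellf, adh_r, adh_c,
                                   adh_n, adh_grid, fibre_on, fibre_ang,
                                   T, cos_floor, rho_floor, out)
        return REJECTED
    # forbidden rules, checked before any energy evaluation
    if t != 0 and vol[t] == 1:
        return FORBIDDEN
    if s != 0:
        v = vol[s]
        dr = tr - sum_r[s] / v
        dc = tc - sum_c[s] / v
        if dr * dr + dc * dc > cellf[s, PF_LMAX2]:
            return FORBIDDEN
    if t != 0 and not _connectivity_ok(tr, tc, sigma, vol, bbox,
                                       visited, gen, stack):
        return FORBIDDEN
    dH = _delta_h(tr, tc, sr, sc, sigma, ctype, vol, sum_r, sum_c,
                  cellf, adh_r, adh_c, adh_n, adh_grid,
                  fibre_on, fibre_ang, J, cos_floor, rho_floor, nuc_r2)
    out[4] = dH
    if dH > 0.0:
        if rng.random() >= np.exp(-dH / T):
            return REJECTED
    _apply_copy(tr, tc, sr, sc, sigma, vol, sum_r, sum_c,
                celli, adh_r, adh_c, adh_n, adh_grid, bbox)
    return ACCEPTED


@njit(cache=True)
def _tighten_bboxes(sigma, vol, bbox):
    """Recompute tight bounding boxes in one pass (boxes only ever expand
    during a Monte-Carlo step)."""
    H, W = sigma.shape
    n = bbox.shape[0]
    for cell in range(1, n):
        if vol[cell] > 0:
            bbox[cell, 0] = H
            bbox[cell, 1] = -1
            bbox[cell, 2] = W
            bbox[cell, 3] = -1
    for r in range(H):
        for c in range(W):
            cell = sigma[r, c]
            if cell != 0:
                if r < bbox[cell, 0]:
                    bbox[cell, 0] = r
                if r > bbox[cell, 1]:
                    bbox[cell, 1] = r
                if c < bbox[cell, 2]:
                    bbox[cell, 2] = c
                if c > bbox[cell, 3]:
                    bbox[cell, 3] = c


@njit(cache=True)
def _run_mcs(n_mcs, rng, sigma, mask, ctype, vol, sum_r, sum_c, cellf, celli,
             adh_r, adh_c, adh_n, adh_grid, bbox,
             fibre_on, fibre_ang, J, T, cos_floor, rho_floor, nuc_r2,
             visited, gen, stack):
    """Run ``n_mcs`` Monte-Carlo steps (rows*cols attempts each).
    Returns (accepted, rejected, forbidden) attempt counts."""
    H, W = sigma.shape
    N = H * W
    out = np.empty(5, dtype=np.float64)
    n_acc = 0
    n_rej = 0
    n_forb = 0
    for _ in range(n_mcs):
        for _ in range(N):
            code = _attempt(rng, sigma, mask, ctype, vol, sum_r, sum_c,
                            cellf, celli, adh_r, adh_c, adh_n, adh_grid,
                            bbox, fibre_on, fibre_ang, J, T,
                            cos_floor, rho_floor, nuc_r2,
                            visited, gen, stack, out)
            if code == ACCEPTED:
                n_acc += 1
            elif code == FORBIDDEN:
                n_forb += 1
            else:
                n_rej += 1
        _tighten_bboxes(sigma, vol, bbox)
    return n_acc, n_rej, n_forb


# ---------------------------------------------------------------------------
# gap-junction label dynamics (secondary Potts-like model on a frozen mesh)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _gj_site_pair_energy(lp, lq, same_cell, JB, JH):
    """Pair energy of the label model: more-GJ pairs within one cell cost
    J_B (labels disperse along the border), more-GJ pairs across a
    cell-cell contact are free (end-to-end connections), a more-GJ label
    facing another cell's less-GJ subcell costs J_H (labels prefer to pair
    up across contacts); everything else is neutral."""
    if lp == 1 and lq == 1:
        return JB if same_cell else 0.0
    if lp != lq and not same_cell:
        return JH
    return 0.0


@njit(cache=True)
def _gj_g_term(r, c, cell, cm_r, cm_c, G, rho_floor):
    dr = r - cm_r[cell]
    dc = c - cm_c[cell]
    rho = np.sqrt(dr * dr + dc * dc)
    if rho < rho_floor:
        rho = rho_floor
    return G / rho


@njit(cache=True)
def _gj_delta_h(pr, pc, qr, qc, sigma, labels, cm_r, cm_c, G, JB, JH,
                rho_floor):
    """Energy change for swapping the labels at p and q (same cell)."""
    H, W = sigma.shape
    lp = np.int64(labels[pr, pc])
    lq = np.int64(labels[qr, qc])
    cell = sigma[pr, pc]
    dH = 0.0
    for k in range(8):
        nr = pr + MOORE[k, 0]
        nc = pc + MOORE[k, 1]
        if nr < 0 or nr >= H or nc < 0 or nc >= W:
            continue
        if nr == qr and nc == qc:
            continue
        nb = sigma[nr, nc]
        if nb == 0:
            continue
        ln = labels[nr, nc]
        same = nb == cell
        dH += _gj_site_pair_energy(lq, ln, same, JB, JH)
        dH -= _gj_site_pair_energy(lp, ln, same, JB, JH)
    for k in range(8):
        nr = qr + MOORE[k, 0]
        nc = qc + MOORE[k, 1]
        if nr < 0 or nr >= H or nc < 0 or nc >= W:
            continue
        if nr == pr and nc == pc:
            continue
        nb = sigma[nr, nc]
        if nb == 0:
            continue
        ln = labels[nr, nc]
        same = nb == cell
        dH += _gj_site_pair_energy(lp, ln, same, JB, JH)
        dH -= _gj_site_pair_energy(lq, ln, same, JB, JH)
    # the p-q pair itself is label-swap invariant; the 1/rho spreading term
    # moves with the more-GJ label
    gp = _gj_g_term(pr, pc, cell, cm_r, cm_c, G, rho_floor)
    gq = _gj_g_term(qr, qc, cell, cm_r, cm_c, G, rho_floor)
    dH += (lq - lp) * gp + (lp - lq) * gq
    return dH


@njit(cache=True)
def _gj_run(n_mcs, n_attempts, rng, sigma, labels, cm_r, cm_c,
            G, JB, JH, T, rho_floor):
    """Label-swap Metropolis dynamics with the cell-index grid frozen."""
    H, W = sigma.shape
    n_acc = 0
    for _ in range(n_mcs):
        for _ in range(n_attempts):
            pr = int(rng.random() * H)
            pc = int(rng.random() * W)
            k = int(rng.random() * 8)
            qr = pr + MOORE[k, 0]
            qc = pc + MOORE[k, 1]
            if qr < 0 or qr >= H or qc < 0 or qc >= W:
                continue
            cell = sigma[pr, pc]
            if cell == 0 or sigma[qr, qc] != cell:
                continue
            if labels[pr, pc] == labels[qr, qc]:
                continue
            dH = _gj_delta_h(pr, pc, qr, qc, sigma, labels, cm_r, cm_c,
                             G, JB, JH, rho_floor)
            if dH > 0.0:
                if rng.random() >= np.exp(-dH / T):
                    continue
            lp = labels[pr, pc]
            labels[pr, pc] = labels[qr, qc]
            labels[qr, qc] = lp
            n_acc += 1
    return n_acc


# ---------------------------------------------------------------------------
# monodomain ADI diffusion half-steps (Thomas tridiagonal solves)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _thomas(a, b, c, d, x, n):
    """Solve one tridiagonal system in place (scratch arrays c, d)."""
    # forward sweep
    c[0] = c[0] / b[0]
    d[0] = d[0] / b[0]
    for i in range(1, n):
        m = b[i] - a[i] * c[i - 1]
        c[i] = c[i] / m
        d[i] = (d[i] - a[i] * d[i - 1]) / m
    x[n - 1] = d[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = d[i] - c[i] * x[i + 1]


@njit(cache=True)
def _adi_half_x(V, R, Dh, Dv, beta, half_dt, Vout):
    """Half-step implicit along rows (x), explicit along columns (y).

    ``beta`` = dt / (2 h^2) with D already in the face arrays' units;
    ``half_dt`` = dt / 2 multiplies the reaction rate R.
    """
    H, W = V.shape
    a = np.empty(W)
    b = np.empty(W)
    c = np.empty(W)
    d = np.empty(W)
    x = np.empty(W)
    for i in range(H):
        for j in range(W):
            bl = beta * Dh[i, j - 1] if j > 0 else 0.0
            br = beta * Dh[i, j] if j < W - 1 else 0.0
            bu = beta * Dv[i - 1, j] if i > 0 else 0.0
            bd = beta * Dv[i, j] if i < H - 1 else 0.0
            a[j] = -bl
            b[j] = 1.0 + bl + br
            c[j] = -br
            rhs = V[i, j] + half_dt * R[i, j]
            if i > 0:
                rhs += bu * (V[i - 1, j] - V[i, j])
            if i < H - 1:
                rhs += bd * (V[i + 1, j] - V[i, j])
            d[j] = rhs
        _thomas(a, b, c, d, x, W)
        for j in range(W):
            Vout[i, j] = x[j]


@njit(cache=True)
def _adi_half_y(V, R, Dh, Dv, beta, half_dt, Vout):
    """Half-step implicit along columns (y), explicit along rows (x)."""
    H, W = V.shape
    a = np.empty(H)
    b = np.empty(H)
    c = np.empty(H)
    d = np.empty(H)
    x = np.empty(H)
    for j in range(W):
        for i in range(H):
            bl = beta * Dh[i, j - 1] if j > 0 else 0.0
            br = beta * Dh[i, j] if j < W - 1 else 0.0
            bu = beta * Dv[i - 1, j] if i > 0 else 0.0
            bd = beta * Dv[i, j] if i < H - 1 else 0.0
            a[i] = -bu
            b[i] = 1.0 + bu + bd
            c[i] = -bd
            rhs = V[i, j] + half_dt * R[i, j]
            if j > 0:
                rhs += bl * (V[i, j - 1] - V[i, j])
            if j < W - 1:
                rhs += br * (V[i, j + 1] - V[i, j])
            d[i] = rhs
        _thomas(a, b, c, d, x, H)
        for i in range(H):
            Vout[i, j] = x[i]
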