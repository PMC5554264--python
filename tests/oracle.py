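"""Independent from-scratch evaluators used as oracles in the tests.

Deliberately naive / vectorised differently from the package's kernels so
they share no code path with what they check.

Energy semantics mirrored here: the adhesive and elastic terms are
conserved state energy (recomputable from the configuration); the 1/rho
protrusion potential is a field sourced at the quasi-static centre of
mass in which only a *moved* attachment site does work; P_detach,
P_unleash and the stiff-nucleus P_N are per-event transition penalties;
adhesion destruction/creation are non-conservative events.
"""

import numpy as np

MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def conserved_energy(state) -> float:
    """Adhesive + elastic state energy, from scratch."""
    sigma = state.sigma
    H, W = sigma.shape
    p = state.params
    ctype = state.ctype
    J = p.j_matrix()

    # adhesive energy: each unordered neighbour pair once, via the four
    # forward shift directions; out-of-bounds neighbours are medium
    tau = ctype[sigma]
    e_adh = 0.0
    for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        a = (slice(max(0, -dr), H - max(0, dr)),
             slice(max(0, -dc), W - max(0, dc)))
        b = (slice(max(0, dr), H + min(0, dr) if dr <= 0 else H),
             slice(max(0, dc), W + min(0, dc) if dc <= 0 else W))
        sa, sb = sigma[a], sigma[b]
        e_adh += float(np.sum(J[tau[a], tau[b]] * (sa != sb)))
    # virtual medium pairs across the closed boundary: 8 minus the number
    # of in-bounds Moore neighbours, once per boundary site
    fr = np.where((np.arange(H) > 0) & (np.arange(H) < H - 1), 3, 2)
    fc = np.where((np.arange(W) > 0) & (np.arange(W) < W - 1), 3, 2)
    n_oob = 8 - (np.outer(fr, fc) - 1)
    e_adh += float(np.sum(n_oob * J[tau, 0] * (sigma != 0)))

    e_el = 0.0
    for cell in range(1, state.n_cells + 1):
        v = int(state.vol[cell])
        if v == 0:
            continue
        tp = p.by_type(int(ctype[cell]))
        e_el += tp.lam_lattice * (v - tp.target_area_subcells) ** 2
    return e_adh + e_el


def protrusion_term(state, cell, site, cm=None) -> float:
    """G/rho field value at one site, with the fibre projection."""
    p = state.params
    tp = p.by_type(int(state.ctype[cell]))
    if cm is None:
        rr, cc = np.nonzero(state.sigma == cell)
        cm = (rr.mean(), cc.mean())
    cm_r, cm_c = cm
    ar, ac = site
    rho = max(np.hypot(ar - cm_r, ac - cm_c), p.rho_floor)
    if state.fibre_field.occupied[ar, ac]:
        ca = abs(np.cos(state.fibre_field.orientation[ar, ac]
                        - np.arctan2(ar - cm_r, ac - cm_c)))
        ca = max(ca, p.cos_alpha_floor)
        return tp.G_lattice / (rho * ca)
    return tp.G_lattice / rho


def relocation_work(pre, target, source) -> float:
    """Work done in the protrusion field by a moved attachment site,
    evaluated with the pre-copy centre of mass (quasi-static field)."""
    sr, sc = source
    s = pre.sigma[sr, sc]
    if s == 0 or not pre.adh_grid[sr, sc]:
        return 0.0
    rr, cc = np.nonzero(pre.sigma == s)
    cm = (rr.mean(), cc.mean())
    return (protrusion_term(pre, int(s), target, cm)
            - protrusion_term(pre, int(s), source, cm))


def transition_penalties(state, target, source) -> float:
    """P_detach / P_unleash for the copy source -> target, from the rules."""
    tr, tc = target
    sr, sc = source
    p = state.params
    pen = 0.0
    t = state.sigma[tr, tc]
    s = state.sigma[sr, sc]
    if t != 0 and state.adh_grid[tr, tc]:
        pen += p.by_type(int(state.ctype[t])).p_detach_lattice
    if t != 0 and t != s:
        # stiff nucleus: only an invading copy (foreign index onto the
        # cell) pays P_N; same-cell attachment hops never invade
        rr, cc = np.nonzero(state.sigma == t)
        cm_r, cm_c = rr.mean(), cc.mean()
        if np.hypot(tr - cm_r, tc - cm_c) < p.nucleus_radius_subcells:
            pen += p.by_type(int(state.ctype[t])).p_nucleus_lattice
    if (s != 0 and state.adh_grid[sr, sc]
            and state.fibre_field.occupied[sr, sc]
            and not state.fibre_field.occupied[tr, tc]):
        pen += p.by_type(int(state.ctype[s])).p_unleash_lattice
    return pen


def expected_delta_h(pre, post, target, source) -> float:
    """Expected incremental dH for an accepted copy, from scratch."""
    return (conserved_energy(post) - conserved_energy(pre)
            + relocation_work(pre, target, source)
            + transition_penalties(pre, target, source))
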