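"""Public operations of the extended cellular-Potts (GGH) engine.

The Hamiltonian has four state terms -- type-dependent adhesion, area
elasticity ``lambda (v - V_t)^2``, the ``G / rho`` protrusion potential of
the focal-adhesion sites (fibre-projected ``G / (rho |cos a|)`` on
nanofibres) and the stiff-nucleus penalty ``P_N`` per foreign subcell within
7 um of a cell's centre of mass -- plus two transition penalties,
``P_detach`` for destroying an existing focal adhesion and ``P_unleash``
for pulling a fibre-anchored adhesion off its fibre.

Dynamics: Metropolis copy attempts.  One Monte-Carlo step (MCS) performs
``rows * cols`` attempts.  A copy is *forbidden* (no energy evaluated) if it
would make a cell disappear, break a cell's 4-connectivity, or extend a
cell farther than ``L_MAX`` from its centre of mass.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from . import _kernels
from ._kernels import ACCEPTED, FORBIDDEN, REJECTED
from .lattice import LatticeState

__all__ = [
    "delta_hamiltonian", "metropolis_accept", "copy_attempt",
    "connectivity_preserved", "monte_carlo_step", "run_mcs",
    "ACCEPTED", "FORBIDDEN", "REJECTED",
]

Site = Tuple[int, int]


def delta_hamiltonian(state: LatticeState, target: Site, source: Site) -> float:
    """Exact energy change for copying the index at ``source`` onto
    ``target`` (lattice neighbours with different indices), including the
    detachment / unleash transition penalties.
    """
    tr, tc = target
    sr, sc = source
    if abs(tr - sr) > 1 or abs(tc - sc) > 1 or target == source:
        raise ValueError("target and source must be distinct neighbours")
    if state.sigma[tr, tc] == state.sigma[sr, sc]:
        raise ValueError("target and source hold the same cell index")
    p = state.params
    return float(_kernels._delta_h(
        tr, tc, sr, sc, state.sigma, state.ctype, state.vol,
        state.sum_r, state.sum_c, state.cellf,
        state.adh_r, state.adh_c, state.adh_n, state.adh_grid,
        state.fibre_field.occupied, state.fibre_field.orientation,
        state.J, p.cos_alpha_floor, p.rho_floor,
        p.nucleus_radius_subcells ** 2))


def metropolis_accept(delta_h: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability ``min(1, exp(-dH/T))``.

    Consumes exactly one uniform draw when ``delta_h > 0`` and none
    otherwise (reproducibility contract).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_h <= 0:
        return True
    return rng.random() < np.exp(-delta_h / temperature)


def connectivity_preserved(state: LatticeState, cell: int,
                           removed_site: Site) -> bool:
    """True iff ``cell`` stays 4-connected after losing ``removed_site``.

    Flood fill restricted to the cell's bounding box (cost O(box)).
    """
    r, c = removed_site
    if state.sigma[r, c] != cell:
        raise ValueError(f"site {removed_site} is not owned by cell {cell}")
    return bool(_kernels._connectivity_ok(
        r, c, state.sigma, state.vol, state.bbox,
        state._visited, state._gen, state._stack))


def copy_attempt(state: LatticeState, rng: np.random.Generator) -> dict:
    """One random copy attempt (target site, Moore-neighbour source).

    Mutates ``state`` in place on acceptance.  Returns a dict with keys
    ``outcome`` ("accepted" | "rejected" | "forbidden"), ``target``,
    ``source`` and ``delta_h`` (0.0 when no energy was evaluated).
    """
    p = state.params
    out = np.empty(5, dtype=np.float64)
    code = _kernels._attempt(
        rng, state.sigma, state.mask, state.ctype, state.vol,
        state.sum_r, state.sum_c, state.cellf, state.celli,
        state.adh_r, state.adh_c, state.adh_n, state.adh_grid, state.bbox,
        state.fibre_field.occupied, state.fibre_field.orientation,
        state.J, p.temperature, p.cos_alpha_floor, p.rho_floor,
        p.nucleus_radius_subcells ** 2,
        state._visited, state._gen, state._stack, out)
    name = {ACCEPTED: "accepted", REJECTED: "rejected",
            FORBIDDEN: "forbidden"}[code]
    return {
        "outcome": name,
        "target": (int(out[0]), int(out[1])),
        "source": (int(out[2]), int(out[3])),
        "delta_h": float(out[4]),
    }


def run_mcs(state: LatticeState, n_mcs: int,
            rng: np.random.Generator) -> Tuple[int, int, int]:
    """Run ``n_mcs`` Monte-Carlo steps in the compiled kernel.

    Returns cumulative (accepted, rejected, forbidden) attempt counts.
    """
    if n_mcs <= 0:
        return (0, 0, 0)
    p = state.params
    counts = _kernels._run_mcs(
        n_mcs, rng, state.sigma, state.mask, state.ctype, state.vol,
        state.sum_r, state.sum_c, state.cellf, state.celli,
        state.adh_r, state.adh_c, state.adh_n, state.adh_grid, state.bbox,
        state.fibre_field.occupied, state.fibre_field.orientation,
        state.J, p.temperature, p.cos_alpha_floor, p.rho_floor,
        p.nucleus_radius_subcells ** 2,
        state._visited, state._gen, state._stack)
    state.mcs_counter += n_mcs
    return tuple(int(x) for x in counts)


def monte_carlo_step(state: LatticeState,
                     rng: np.random.Generator) -> LatticeState:
    """Perform one MCS (rows*cols copy attempts) in place; returns state."""
    run_mcs(state, 1, rng)
    return state
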