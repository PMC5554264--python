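"""Gap-junction label distribution and the per-face conductance map.

A secondary Potts-like model distributes "more-GJ" membrane labels over
each cell's subcells with the cell-index grid frozen: labels start as a
one-subcell dilation ring around each focal-adhesion site and then evolve
by label-swap Metropolis dynamics under

    H = sum_pairs J(labels) + sum_{more-GJ} G / rho(i, cm),

with J_B = 10 for mismatched pairs within one cell (labels cluster),
J_H = 2 for mismatched pairs across a cell-cell contact (matched more-GJ
contacts across cells are free, so labels on both sides of a contact
stabilise each other), and the 1/rho term pushing labels away from the
centre of mass.  Swaps conserve the per-cell more-GJ count.

The conductance map then assigns the monodomain coupling coefficient to
every lattice face: D_in within a cardiomyocyte, D_end across CM-CM faces
labelled more-GJ on both sides, D_side across other CM-CM faces, and zero
for every face touching medium, a fibroblast (unexcited obstacles here) or
a CM-FB contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from . import _kernels
from .lattice import LatticeState
from .params import CM

__all__ = ["GJParams", "GJLabelField", "ConductanceMap",
           "distribute_gap_junctions", "build_conductance_map"]


@dataclass(frozen=True)
class GJParams:
    """Parameters of the label-distribution Hamiltonian."""

    G: float = 25.0          # spreading constant (1/rho term, rho in subcells)
    J_H: float = 2.0         # mismatched side-to-side (cross-cell) pairs
    J_B: float = 10.0        # mismatched pairs within one cell
    temperature: float = 1.0
    mcs: int = 100           # default label-dynamics budget
    dilate: int = 2          # initial label ring around each adhesion site

    def __post_init__(self):
        if min(self.G, self.J_H, self.J_B) < 0:
            raise ValueError("GJ parameters must be non-negative")


@dataclass
class GJLabelField:
    """More-GJ (1) / less-GJ (0) label per cell subcell; sigma is frozen."""

    labels: np.ndarray       # uint8 (rows, cols); 0 outside cells
    sigma: np.ndarray        # frozen copy of the cell-index grid

    def counts_per_cell(self) -> np.ndarray:
        """Total more-GJ subcells per cell index."""
        n = int(self.sigma.max())
        out = np.zeros(n + 1, dtype=np.int64)
        np.add.at(out, self.sigma.ravel(), self.labels.ravel().astype(np.int64))
        return out


@dataclass
class ConductanceMap:
    """Diffusion coefficient per lattice face, cm^2/s.

    ``horizontal[i, j]`` couples (i, j) and (i, j+1);
    ``vertical[i, j]`` couples (i, j) and (i+1, j).
    """

    horizontal: np.ndarray   # (rows, cols-1)
    vertical: np.ndarray     # (rows-1, cols)

    @property
    def max_d(self) -> float:
        return float(max(self.horizontal.max(initial=0.0),
                         self.vertical.max(initial=0.0)))


def initial_labels(state: LatticeState, dilate: int = 1) -> np.ndarray:
    """Seed labels: each cell's adhesion sites dilated by ``dilate``
    subcells, clipped to the owning cell."""
    labels = np.zeros(state.dims, dtype=np.uint8)
    adh = np.zeros(state.dims, dtype=bool)
    for cell in range(1, state.n_cells + 1):
        for k in range(state.adh_n[cell]):
            adh[state.adh_r[cell, k], state.adh_c[cell, k]] = True
    if dilate > 0:
        footprint = np.ones((2 * dilate + 1, 2 * dilate + 1), dtype=bool)
        # owner-aware dilation: grow each adhesion only into its own cell
        grown = ndimage.grey_dilation(
            np.where(adh, state.sigma, 0), footprint=footprint)
        labels[(grown == state.sigma) & (state.sigma > 0) & (grown > 0)] = 1
    labels[adh] = 1
    labels[state.sigma == 0] = 0
    return labels


def distribute_gap_junctions(state: LatticeState, params: GJParams,
                             rng: np.random.Generator,
                             n_mcs: int | None = None) -> GJLabelField:
    """Run the label-swap Metropolis dynamics on the frozen mesh.

    A cell with zero focal adhesions simply gets zero more-GJ labels.
    One Monte-Carlo step performs as many swap attempts as there are
    cell subcells; per-cell label counts are conserved exactly.
    """
    if n_mcs is None:
        n_mcs = params.mcs
    labels = initial_labels(state, params.dilate)
    sigma = state.sigma.copy()
    n = state.n_cells
    cm_r = np.zeros(n + 1)
    cm_c = np.zeros(n + 1)
    alive = state.vol[:n + 1] > 0
    cm_r[alive] = state.sum_r[:n + 1][alive] / state.vol[:n + 1][alive]
    cm_c[alive] = state.sum_c[:n + 1][alive] / state.vol[:n + 1][alive]
    n_attempts = int(np.count_nonzero(sigma))
    if n_mcs > 0 and n_attempts > 0:
        _kernels._gj_run(n_mcs, n_attempts, rng, sigma, labels, cm_r, cm_c,
                         params.G, params.J_B, params.J_H,
                         params.temperature, state.params.rho_floor)
    return GJLabelField(labels=labels, sigma=sigma)


def build_conductance_map(state: LatticeState, gj: GJLabelField,
                          d_in: float, d_end: float,
                          d_side: float,
                          patch_radius: int = 2) -> ConductanceMap:
    """Assign the coupling coefficient of every lattice face.

    A CM-CM border face becomes an end-to-end coupling when a more-GJ
    subcell exists on both sides of the border within ``patch_radius``
    subcells along it: paired labels mark a gap-junction plaque whose
    conducting patch spans a few subcells of the shared membrane, not a
    single lattice face.  ``patch_radius=0`` reduces to the strict
    per-face rule (both subcells of the face itself labelled).

    Requires ``d_in >= d_end >= d_side >= 0`` (the published ordering is
    D_in >> D_end > D_side).
    """
    if not (d_in >= d_end >= d_side >= 0.0):
        raise ValueError("conductance levels must satisfy "
                         "d_in >= d_end >= d_side >= 0")
    sigma = gj.sigma
    is_cm = state.ctype[sigma] == CM
    more = gj.labels.astype(bool)

    def face(a, b):
        """a, b: index slices of the two sides of the face set."""
        sa, sb = sigma[a], sigma[b]
        cm_a, cm_b = is_cm[a], is_cm[b]
        d = np.zeros(sa.shape, dtype=np.float64)
        within = (sa == sb) & (sa > 0) & cm_a
        d[within] = d_in
        between = (sa != sb) & (sa > 0) & (sb > 0) & cm_a & cm_b
        end = between & more[a] & more[b]
        d[end] = d_end
        d[between & ~end] = d_side
        return d, between, end, sa, sb

    dh, bh, eh, sah, sbh = face(np.s_[:, :-1], np.s_[:, 1:])
    dv, bv, ev, sav, sbv = face(np.s_[:-1, :], np.s_[1:, :])

    if patch_radius > 0 and d_end > d_side:
        # grow each paired-label face into a junction patch: border faces
        # of the same cell pair within the Chebyshev patch radius
        # (face midpoints in doubled coordinates)
        from collections import defaultdict

        strong = defaultdict(list)
        weak = defaultdict(list)
        for grid, (bet, end, sa, sb, dr, dc) in enumerate(
                [(bh, eh, sah, sbh, 0, 1), (bv, ev, sav, sbv, 1, 0)]):
            ii, jj = np.nonzero(bet)
            for i, j in zip(ii, jj):
                pair = (int(min(sa[i, j], sb[i, j])),
                        int(max(sa[i, j], sb[i, j])))
                rec = (grid, i, j, 2 * i + dr, 2 * j + dc)
                if end[i, j]:
                    strong[pair].append(rec)
                else:
                    weak[pair].append(rec)
        reach = 2 * patch_radius
        for pair, faces in weak.items():
            anchors = strong.get(pair)
            if not anchors:
                continue
            for grid, i, j, fr, fc in faces:
                for _, _, _, ar, ac in anchors:
                    if max(abs(fr - ar), abs(fc - ac)) <= reach:
                        if grid == 0:
                            dh[i, j] = d_end
                        else:
                            dv[i, j] = d_end
                        break

    return ConductanceMap(horizontal=dh, vertical=dv)
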