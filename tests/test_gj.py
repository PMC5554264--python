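"""Gap-junction label dynamics and the conductance map."""

import numpy as np
import pytest

from cardiolattice import gj
from cardiolattice.lattice import LatticeState
from cardiolattice.params import CM, FB

from conftest import simple_params


def square_cell_state(side=9, dims=(15, 15), cell_type=CM, n_adh=4):
    sigma = np.zeros(dims, dtype=np.int32)
    r0 = (dims[0] - side) // 2
    sigma[r0:r0 + side, r0:r0 + side] = 1
    state = LatticeState(sigma, np.array([0, cell_type], np.uint8),
                         simple_params(n_protr=max(n_adh, 1)))
    # plant adhesions at the cell corners
    corners = [(r0, r0), (r0, r0 + side - 1),
               (r0 + side - 1, r0), (r0 + side - 1, r0 + side - 1)]
    for k, (r, c) in enumerate(corners[:n_adh]):
        state.adh_r[1, k] = r
        state.adh_c[1, k] = c
        state.adh_grid[r, c] = 1
        state.adh_n[1] = k + 1
    return state


def test_default_parameters():
    p = gj.GJParams()
    assert (p.G, p.J_H, p.J_B) == (25.0, 2.0, 10.0)
    with pytest.raises(ValueError):
        gj.GJParams(G=-1.0)


def test_label_counts_conserved(rng):
    state = square_cell_state()
    field0 = gj.distribute_gap_junctions(state, gj.GJParams(), rng,
                                         n_mcs=0)
    field = gj.distribute_gap_junctions(state, gj.GJParams(),
                                        np.random.default_rng(5),
                                        n_mcs=200)
    assert np.array_equal(field0.counts_per_cell(),
                          field.counts_per_cell())
    # labels only on cell subcells; sigma untouched
    assert not field.labels[field.sigma == 0].any()
    assert np.array_equal(field.sigma, state.sigma)


def test_null_hamiltonian_is_pure_random_walk(rng):
    """G = J = 0: swaps still conserve counts (pure plumbing check)."""
    state = square_cell_state()
    params = gj.GJParams(G=0.0, J_H=0.0, J_B=0.0)
    field = gj.distribute_gap_junctions(state, params, rng, n_mcs=50)
    assert int(field.labels.sum()) \
        == int(gj.initial_labels(state, params.dilate).sum())


def test_cell_without_adhesions_gets_no_labels(rng):
    state = square_cell_state(n_adh=0)
    field = gj.distribute_gap_junctions(state, gj.GJParams(), rng)
    assert int(field.labels.sum()) == 0


def test_labels_drift_away_from_centre(rng):
    """With the 1/rho spreading term, the mean label distance to the cm
    strictly increases in expectation (many replicates, central seed)."""
    side, dims = 11, (15, 15)
    sigma = np.zeros(dims, dtype=np.int32)
    sigma[2:2 + side, 2:2 + side] = 1
    state = LatticeState(sigma, np.array([0, CM], np.uint8),
                         simple_params(n_protr=1))
    cm_r, cm_c = state.centre_of_mass(1)
    # one label at the centre subcell
    state.adh_r[1, 0] = int(round(cm_r))
    state.adh_c[1, 0] = int(round(cm_c))
    state.adh_grid[int(round(cm_r)), int(round(cm_c))] = 1
    state.adh_n[1] = 1
    params = gj.GJParams(dilate=0)
    d0, d1 = [], []
    for rep in range(100):
        field = gj.distribute_gap_junctions(
            state, params, np.random.default_rng(rep), n_mcs=30)
        rr, cc = np.nonzero(field.labels)
        d1.append(np.hypot(rr - cm_r, cc - cm_c).mean())
        d0.append(0.0)
    assert np.mean(d1) > np.mean(d0) + 1.0


def test_conductance_levels_and_zero_couplings(rng):
    """CM-FB faces are zero, CM interiors D_in, FB interiors zero, and
    CM-CM faces split into end-end / side-side by the labels."""
    sigma = np.zeros((6, 9), dtype=np.int32)
    sigma[1:5, 1:4] = 1   # CM
    sigma[1:5, 4:8] = 2   # FB
    state = LatticeState(sigma, np.array([0, CM, FB], np.uint8),
                         simple_params())
    labels = np.ones_like(sigma, dtype=np.uint8)
    labels[sigma == 0] = 0
    field = gj.GJLabelField(labels=labels, sigma=sigma.copy())
    dmap = gj.build_conductance_map(state, field, d_in=1.0, d_end=0.02,
                                    d_side=0.001, patch_radius=0)
    # CM-FB interface column (between cols 3 and 4): zero
    assert (dmap.horizontal[1:5, 3] == 0).all()
    # within-CM faces: D_in; within-FB: 0
    assert (dmap.horizontal[1:5, 1:3] == 1.0).all()
    assert (dmap.horizontal[1:5, 4:7] == 0.0).all()
    # faces to medium: zero
    assert (dmap.horizontal[0, :] == 0).all()
    assert dmap.max_d == 1.0


def test_end_end_requires_labels_on_both_sides():
    sigma = np.zeros((4, 8), dtype=np.int32)
    sigma[1:3, 1:4] = 1
    sigma[1:3, 4:7] = 2
    state = LatticeState(sigma, np.array([0, CM, CM], np.uint8),
                         simple_params())
    labels = np.zeros_like(sigma, dtype=np.uint8)
    labels[1, 3] = 1  # one side of the (1,3)-(1,4) face
    field = gj.GJLabelField(labels=labels, sigma=sigma.copy())
    dmap = gj.build_conductance_map(state, field, 1.0, 0.02, 0.001,
                                    patch_radius=0)
    assert dmap.horizontal[1, 3] == pytest.approx(0.001)  # side-side
    labels[1, 4] = 1
    dmap = gj.build_conductance_map(state, field, 1.0, 0.02, 0.001,
                                    patch_radius=0)
    assert dmap.horizontal[1, 3] == pytest.approx(0.02)   # end-end
    assert dmap.horizontal[2, 3] == pytest.approx(0.001)
    # with the default junction patch the paired-label plaque extends to
    # neighbouring faces of the same border
    dmap = gj.build_conductance_map(state, field, 1.0, 0.02, 0.001)
    assert dmap.horizontal[2, 3] == pytest.approx(0.02)


def test_equal_levels_recover_homogeneous_cm_map(rng):
    """D_side = D_end = D_in: every CM-CM and CM-interior face carries
    the same coefficient (the minimal-anisotropy control)."""
    sigma = np.zeros((4, 8), dtype=np.int32)
    sigma[1:3, 1:4] = 1
    sigma[1:3, 4:7] = 2
    state = LatticeState(sigma, np.array([0, CM, CM], np.uint8),
                         simple_params())
    field = gj.GJLabelField(
        labels=np.zeros_like(sigma, np.uint8), sigma=sigma.copy())
    dmap = gj.build_conductance_map(state, field, 1.0, 1.0, 1.0)
    inside = np.zeros_like(dmap.horizontal, dtype=bool)
    inside[1:3, 1:6] = True
    assert (dmap.horizontal[inside] == 1.0).all()
    assert (dmap.horizontal[~inside] == 0.0).all()


def test_level_ordering_enforced():
    sigma = np.zeros((3, 3), dtype=np.int32)
    sigma[1, 1] = 1
    state = LatticeState(sigma, np.array([0, CM], np.uint8),
                         simple_params())
    field = gj.GJLabelField(labels=np.zeros_like(sigma, np.uint8),
                            sigma=sigma.copy())
    with pytest.raises(ValueError):
        gj.build_conductance_map(state, field, 1.0, 0.001, 0.02)


def test_map_is_deterministic(rng):
    state = square_cell_state()
    f1 = gj.distribute_gap_junctions(state, gj.GJParams(),
                                     np.random.default_rng(3), n_mcs=50)
    f2 = gj.distribute_gap_junctions(state, gj.GJParams(),
                                     np.random.default_rng(3), n_mcs=50)
    assert np.array_equal(f1.labels, f2.labels)
    d1 = gj.build_conductance_map(state, f1, 1.0, 0.01, 0.0)
    d2 = gj.build_conductance_map(state, f2, 1.0, 0.01, 0.0)
    assert np.array_equal(d1.horizontal, d2.horizontal)
    assert np.array_equal(d1.vertical, d2.vertical)
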