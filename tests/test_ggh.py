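"""Unit and property tests for the cellular-Potts engine."""

import numpy as np
import pytest

from cardiolattice import ggh
from cardiolattice.lattice import FibreField, LatticeState
from cardiolattice.params import CM, FB

from conftest import simple_params
from oracle import conserved_energy, expected_delta_h


def make_state(sigma, params, types=None, fibres=None):
    sigma = np.asarray(sigma, dtype=np.int32)
    n = int(sigma.max())
    if types is None:
        types = [CM] * n
    return LatticeState(sigma, np.array([0, *types], np.uint8), params,
                        fibre_field=fibres)


# ---------------------------------------------------------------------------
# delta-H examples
# ---------------------------------------------------------------------------

def test_elastic_contribution_at_target_volume():
    """Removing one subcell from a cell at its target volume costs
    exactly +lambda (quadratic at its minimum)."""
    lam = 7.0
    params = simple_params(lam=lam, target_area_um2=4 * 6.25,
                           j_cell_md=0.0)
    sigma = np.zeros((6, 6), dtype=np.int32)
    sigma[2:4, 2:4] = 1  # volume 4 == target
    state = make_state(sigma, params)
    # medium (3,4) copies onto (3,3): cell shrinks 4 -> 3
    dh = ggh.delta_hamiltonian(state, target=(3, 3), source=(3, 4))
    assert dh == pytest.approx(lam * 1.0)


def test_adhesive_and_elastic_on_2x2_to_tromino():
    """Medium copied into a corner of an isolated 2x2 cell.

    Hand count of cell-medium contact pairs: 8 with the von-Neumann
    neighbourhood on both shapes (no adhesive change), 20 -> 18 with the
    Moore neighbourhood used here, so the adhesive part is exactly -2 J
    and the elastic part lambda((3-Vt)^2 - (4-Vt)^2).
    """
    lam, vt, j = 3.0, 9.0, 11.0
    params = simple_params(lam=lam, target_area_um2=vt * 6.25,
                           j_cell_md=j)
    sigma = np.zeros((6, 6), dtype=np.int32)
    sigma[2:4, 2:4] = 1
    state = make_state(sigma, params)
    h0 = conserved_energy(state)
    dh = ggh.delta_hamiltonian(state, target=(2, 2), source=(2, 1))
    expected_elastic = lam * ((3 - vt) ** 2 - (4 - vt) ** 2)
    # the local recount must agree with the full-lattice difference
    sigma2 = sigma.copy()
    sigma2[2, 2] = 0
    state2 = make_state(sigma2, params)
    assert dh == pytest.approx(conserved_energy(state2) - h0, abs=1e-9)
    assert dh - expected_elastic == pytest.approx(-2.0 * j, abs=1e-9)


def test_fibre_term_reduces_to_isotropic_when_aligned():
    """A focal contact on a fibre with alpha = 0 contributes exactly the
    isotropic G/rho (cos 0 = 1)."""
    G_lat = 400.0  # after the x400 unit scale with G=1.0
    params = simple_params(G=G_lat, j_cell_md=0.0, lam=0.0)
    dims = (9, 9)
    occ = np.zeros(dims, np.uint8)
    occ[4, :] = 1  # horizontal fibre through the cell row
    fibres = FibreField(occ, np.zeros(dims))
    sigma = np.zeros(dims, dtype=np.int32)
    sigma[4, 2:7] = 1  # horizontal bar on the fibre
    state = make_state(sigma, params, fibres=fibres)
    # plant an adhesion at the right tip (on the fibre, alpha = 0)
    state.adh_r[1, 0] = 4
    state.adh_c[1, 0] = 6
    state.adh_n[1] = 1
    state.adh_grid[4, 6] = 1

    state_iso = make_state(sigma, params)  # same geometry, no fibres
    state_iso.adh_r[1, 0] = 4
    state_iso.adh_c[1, 0] = 6
    state_iso.adh_n[1] = 1
    state_iso.adh_grid[4, 6] = 1

    dh_fib = ggh.delta_hamiltonian(state, target=(4, 7), source=(4, 6))
    dh_iso = ggh.delta_hamiltonian(state_iso, target=(4, 7), source=(4, 6))
    assert dh_fib == pytest.approx(dh_iso, rel=1e-12)


# ---------------------------------------------------------------------------
# Metropolis rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dh", [-3.0, 0.0])
def test_metropolis_always_accepts_nonpositive(dh, rng):
    before = rng.bit_generator.state
    assert ggh.metropolis_accept(dh, 1.0, rng)
    # no uniform consumed for dH <= 0
    assert rng.bit_generator.state == before


def test_metropolis_rate_matches_boltzmann(rng):
    """Empirical acceptance for dH = T within 3 SE of exp(-1)."""
    n = 200_000
    acc = sum(ggh.metropolis_accept(2.5, 2.5, rng) for _ in range(n))
    p = np.exp(-1.0)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(acc / n - p) < 3 * se


def test_metropolis_consumes_one_draw_for_positive(rng):
    rng2 = np.random.default_rng(777)
    ggh.metropolis_accept(5.0, 1.0, rng2)
    # exactly one draw consumed: next value equals the second draw of a
    # fresh generator with the same seed
    fresh = np.random.default_rng(777)
    fresh.random()
    assert rng2.random() == fresh.random()


# ---------------------------------------------------------------------------
# copy attempts, forbidden rules, connectivity
# ---------------------------------------------------------------------------

def test_volume_one_cell_is_protected():
    """A cell may not disappear: invading its last subcell is forbidden."""
    # volumes pinned at 1 (target one subcell, stiff elasticity)
    params = simple_params(target_area_um2=6.25, lam=50.0, j_cell_md=0.0)
    sigma = np.zeros((5, 5), dtype=np.int32)
    sigma[2, 2] = 1
    sigma[2, 3] = 2
    state = make_state(sigma, params, types=[CM, CM])
    # drive attempts until the (2,2) target with a foreign source occurs
    rng = np.random.default_rng(0)
    saw_forbidden = False
    for _ in range(2000):
        out = ggh.copy_attempt(state, rng)
        if out["target"] == (2, 2) and out["outcome"] != "rejected":
            assert out["outcome"] == "forbidden"
            saw_forbidden = True
    assert saw_forbidden
    assert state.vol[1] >= 1


def test_l_max_blocks_distant_expansion():
    """Expansion beyond L_MAX from the cm is forbidden before any energy
    evaluation."""
    params = simple_params(l_max_um=2.5 * 3.0)  # 3 subcells
    sigma = np.zeros((9, 9), dtype=np.int32)
    sigma[4, 1:5] = 1  # bar, cm at col 2.5
    state = make_state(sigma, params)
    rng = np.random.default_rng(1)
    for _ in range(4000):
        out = ggh.copy_attempt(state, rng)
        if out["outcome"] == "accepted":
            cm = state.centre_of_mass(1)
            tr, tc = out["target"]
            d = np.hypot(tr - cm[0], tc - cm[1])
            # distance measured against the pre-copy cm; allow the O(1/v)
            # post-copy shift
            assert d <= 3.0 + 1.0


@pytest.mark.parametrize("sigma,remove,expected", [
    # 1x3 bar, remove the middle -> splits
    ([[1, 1, 1]], (0, 1), False),
    # 2x2 block, remove any -> L-tromino stays connected
    ([[1, 1], [1, 1]], (0, 0), True),
])
def test_connectivity_simple_cases(sigma, remove, expected):
    params = simple_params()
    state = make_state(np.array(sigma), params)
    assert ggh.connectivity_preserved(state, 1, remove) is expected


def test_connectivity_ring():
    """Ring of 8 subcells: one removal keeps it connected, two opposite
    removals disconnect it."""
    params = simple_params()
    ring = np.array([[1, 1, 1],
                     [1, 0, 1],
                     [1, 1, 1]], dtype=np.int32)
    state = make_state(ring, params)
    assert ggh.connectivity_preserved(state, 1, (0, 1))
    ring2 = ring.copy()
    ring2[0, 1] = 0
    state2 = make_state(ring2, params)
    assert not ggh.connectivity_preserved(state2, 1, (2, 1))


def test_connectivity_requires_ownership():
    params = simple_params()
    state = make_state(np.array([[1, 1, 0]]), params)
    with pytest.raises(ValueError):
        ggh.connectivity_preserved(state, 1, (0, 2))


# ---------------------------------------------------------------------------
# Monte-Carlo steps
# ---------------------------------------------------------------------------

def test_empty_lattice_is_invariant(rng):
    params = simple_params()
    sigma = np.zeros((8, 8), dtype=np.int32)
    state = LatticeState(sigma, np.zeros(1, np.uint8), params)
    acc, rej, forb = ggh.run_mcs(state, 5, rng)
    assert acc == 0 and forb == 0
    assert rej == 5 * 64
    assert not state.sigma.any()
    assert state.mcs_counter == 5


def test_mcs_performs_n_attempts(rng):
    params = simple_params()
    sigma = np.zeros((7, 9), dtype=np.int32)
    sigma[3, 4] = 1
    sigma[3, 5] = 1
    state = make_state(sigma, params)
    counts = ggh.run_mcs(state, 2, rng)
    assert sum(counts) == 2 * 7 * 9


def test_greedy_volume_descent(rng):
    """T -> 0, only the elastic term: an oversized cell shrinks
    monotonically toward its target volume."""
    params = simple_params(lam=5.0, target_area_um2=9 * 6.25,
                           j_cell_md=0.0, temperature=1e-6)
    sigma = np.zeros((12, 12), dtype=np.int32)
    sigma[3:9, 3:9] = 1  # volume 36, target 9
    state = make_state(sigma, params)
    vols = [int(state.vol[1])]
    for _ in range(30):
        ggh.monte_carlo_step(state, rng)
        vols.append(int(state.vol[1]))
    assert all(b <= a for a, b in zip(vols, vols[1:]))
    assert vols[-1] == 9


def test_bookkeeping_audit_after_run(rng):
    """Volumes, centres of mass and adhesion ownership recomputed from
    sigma agree with the incremental records after a long mixed run."""
    params = simple_params(G=800.0, p_detach=40.0, lam=2.0,
                           target_area_um2=20 * 6.25, n_protr=6)
    sigma = np.zeros((20, 20), dtype=np.int32)
    sigma[4:8, 4:8] = 1
    sigma[12:16, 12:16] = 2
    sigma[4:8, 12:16] = 3
    state = make_state(sigma, params, types=[CM, FB, CM])
    ggh.run_mcs(state, 60, rng)
    state.validate()  # raises on any inconsistency
    assert all(state.vol[1:] >= 1)


def test_seed_determinism():
    params = simple_params(G=400.0, lam=2.0, target_area_um2=25 * 6.25)
    sigma = np.zeros((15, 15), dtype=np.int32)
    sigma[5:9, 5:9] = 1
    runs = []
    for _ in range(2):
        state = make_state(sigma.copy(), params)
        ggh.run_mcs(state, 20, np.random.default_rng(42))
        runs.append(state.sigma.copy())
    assert np.array_equal(runs[0], runs[1])


# ---------------------------------------------------------------------------
# oracle equivalence: incremental dH == full-lattice H difference
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("with_fibres", [False, True])
def test_delta_h_matches_full_hamiltonian(with_fibres, rng):
    """On small lattices every accepted copy's incremental dH equals the
    from-scratch H(after) - H(before) plus the transition penalties, to
    1e-9."""
    params = simple_params(G=2000.0, p_detach=30.0, p_unleash=12.0,
                           lam=1.0, target_area_um2=48 * 6.25, n_protr=6,
                           j_cell_md=9.0, j_cell_cell=4.0, j_cm_fb=6.0)
    dims = (26, 26)
    fibres = None
    if with_fibres:
        occ = np.zeros(dims, np.uint8)
        occ[::3, :] = 1
        fibres = FibreField(occ, np.zeros(dims))
    sigma = np.zeros(dims, dtype=np.int32)
    sigma[3:11, 3:11] = 1
    sigma[14:22, 14:22] = 2
    sigma[3:11, 14:22] = 3
    state = make_state(sigma, params, types=[CM, FB, CM], fibres=fibres)

    checked = 0
    for _ in range(6000):
        pre = state.copy()
        out = ggh.copy_attempt(state, rng)
        if out["outcome"] != "accepted":
            continue
        assert out["delta_h"] == pytest.approx(
            expected_delta_h(pre, state, out["target"], out["source"]),
            abs=1e-9), f"dH mismatch at {out}"
        checked += 1
    assert checked > 100
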