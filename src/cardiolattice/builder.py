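"""Initial conditions and tissue formation for the four experimental
conditions (isolated / monolayer, with / without aligned nanofibres).

Seeding follows the published protocol: the sample is divided into a grid
of ``n_x x n_y`` areas and one square seed of side ``sqrt(V_t / 10)`` is
placed at a uniform-random admissible offset within each area.  Cells start
with no focal adhesions; adhesions appear during the first successful
border expansions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import ggh
from .lattice import FibreField, LatticeState
from .params import CM, FB, Preset, get_preset

DEFAULT_FIBRE_PITCH = 4  # subcells (10 um) between parallel fibre rows


@dataclass(frozen=True)
class SeedingPlan:
    """Grid of seeding areas with per-type cell counts."""

    dims: Tuple[int, int]         # lattice (rows, cols)
    grid: Tuple[int, int]         # (n_x, n_y) seeding areas
    fb_fraction: float = 0.5

    @property
    def n_cells(self) -> int:
        return self.grid[0] * self.grid[1]

    def type_counts(self) -> Tuple[int, int]:
        """(n_cm, n_fb) honouring the FB fraction exactly
        (largest-remainder rounding)."""
        n = self.n_cells
        n_fb = int(np.floor(self.fb_fraction * n))
        if self.fb_fraction * n - n_fb >= 0.5:
            n_fb += 1
        return n - n_fb, n_fb


def seed_side(target_area_subcells: float) -> int:
    """Side of the initial square seed, subcells: sqrt(V_t / 10)."""
    return max(1, int(round(np.sqrt(target_area_subcells / 10.0))))


def seed_cells(plan: SeedingPlan, preset: Preset,
               rng: np.random.Generator,
               mask: Optional[np.ndarray] = None,
               fibre_field: Optional[FibreField] = None) -> LatticeState:
    """Seed one square per grid area at a uniform-random offset.

    Cell types are assigned by a seeded random permutation matching the
    requested CM/FB fraction; all adhesion sets start empty.  Areas that
    fall entirely outside ``mask`` (e.g. the cut corner of an L-shaped
    domain) are skipped.
    """
    rows, cols = plan.dims
    n_x, n_y = plan.grid
    n_cm, n_fb = plan.type_counts()
    types = np.array([CM] * n_cm + [FB] * n_fb, dtype=np.uint8)
    rng.shuffle(types)

    sigma = np.zeros((rows, cols), dtype=np.int32)
    cell_types: List[int] = [0]
    # area edges (areas tile the lattice as evenly as integer division allows)
    x_edges = np.linspace(0, cols, n_x + 1).astype(int)
    y_edges = np.linspace(0, rows, n_y + 1).astype(int)

    index = 0
    for iy in range(n_y):
        for ix in range(n_x):
            t = int(types[iy * n_x + ix])
            tp = preset.params.by_type(t)
            side = seed_side(tp.target_area_subcells)
            r0, r1 = y_edges[iy], y_edges[iy + 1]
            c0, c1 = x_edges[ix], x_edges[ix + 1]
            if r1 - r0 < side or c1 - c0 < side:
                raise ValueError(
                    f"seed of side {side} does not fit in a "
                    f"{r1 - r0}x{c1 - c0} seeding area")
            # uniform-random admissible offset; two draws per seed
            rr = r0 + int(rng.random() * (r1 - r0 - side + 1))
            cc = c0 + int(rng.random() * (c1 - c0 - side + 1))
            if mask is not None and not mask[rr:rr + side, cc:cc + side].all():
                continue  # seed would straddle the forbidden region
            index += 1
            sigma[rr:rr + side, cc:cc + side] = index
            cell_types.append(t)

    return LatticeState(sigma, np.array(cell_types, dtype=np.uint8),
                        preset.params, fibre_field=fibre_field, mask=mask)


def generate_fibre_field(dims: Tuple[int, int], orientation: float = 0.0,
                         pitch: int = DEFAULT_FIBRE_PITCH) -> FibreField:
    """Parallel one-subcell-wide fibres at the given pitch.

    ``orientation`` is the fibre angle in radians ([0, pi)); fibres are laid
    out as rows for orientation 0 (the aligned-nanofibre configuration) --
    arbitrary orientations keep the same row layout but store the requested
    angle, which is what the protrusion projection uses.
    """
    if pitch < 1:
        raise ValueError("pitch must be >= 1")
    occ = np.zeros(dims, dtype=np.uint8)
    occ[::pitch, :] = 1
    ang = np.zeros(dims, dtype=np.float64)
    ang[occ == 1] = orientation % np.pi
    return FibreField(occ, ang)


def build_l_shape_mask(dims: Tuple[int, int], arm_width: int) -> np.ndarray:
    """Boolean admissible-region mask shaped as an L.

    The horizontal arm spans the top ``arm_width`` rows, the vertical arm
    the left ``arm_width`` columns; the stimulation point at the
    intersection of the arm middle lines, ``(arm_width // 2,
    arm_width // 2)``, lies inside the mask.
    """
    rows, cols = dims
    if arm_width > rows or arm_width > cols:
        raise ValueError("arm_width exceeds the domain")
    mask = np.zeros(dims, dtype=bool)
    mask[:arm_width, :] = True
    mask[:, :arm_width] = True
    return mask


def l_shape_stimulus_site(arm_width: int) -> Tuple[int, int]:
    """Electrode site at the intersection of the arm middle lines."""
    return (arm_width // 2, arm_width // 2)


def run_formation(state: LatticeState, preset: Preset,
                  rng: np.random.Generator,
                  n_mcs: Optional[int] = None,
                  log_every: int = 100) -> Tuple[LatticeState, pd.DataFrame]:
    """Run tissue formation for ``n_mcs`` Monte-Carlo steps (preset default).

    Returns the evolved state (mutated in place) and a time-series log with
    per-cell volume and adhesion count every ``log_every`` MCS.
    """
    if n_mcs is None:
        n_mcs = preset.mcs
    records = []

    def _log():
        alive = np.nonzero(state.vol[1:])[0] + 1
        records.append(pd.DataFrame({
            "mcs": state.mcs_counter,
            "cell": alive,
            "type": state.ctype[alive],
            "volume": state.vol[alive],
            "n_adhesions": state.adh_n[alive],
        }))

    _log()
    done = 0
    while done < n_mcs:
        chunk = min(log_every, n_mcs - done)
        ggh.run_mcs(state, chunk, rng)
        done += chunk
        _log()
    log = pd.concat(records, ignore_index=True)
    return state, log


def grow(preset_name: str, seed: int, n_mcs: Optional[int] = None,
         fb_fraction: float = 0.5,
         dims: Optional[Tuple[int, int]] = None,
         grid: Optional[Tuple[int, int]] = None,
         l_shape_arm: Optional[int] = None,
         fibre_pitch: int = DEFAULT_FIBRE_PITCH,
         log_every: int = 500) -> Tuple[LatticeState, pd.DataFrame]:
    """High-level entry point: seed and grow one virtual tissue.

    ``dims``/``grid`` override the preset for reduced-scale runs (the grid
    is rescaled proportionally if only ``dims`` is given).
    """
    preset = get_preset(preset_name)
    full_dims = preset.dims
    if dims is None:
        dims = full_dims
    if grid is None:
        gx, gy = preset.grid
        grid = (max(1, int(round(gx * dims[1] / full_dims[1]))),
                max(1, int(round(gy * dims[0] / full_dims[0]))))
    rng = np.random.default_rng(seed)
    mask = None
    if l_shape_arm is not None:
        mask = build_l_shape_mask(dims, l_shape_arm)
    fibres = None
    if preset.fibres:
        fibres = generate_fibre_field(dims, orientation=0.0,
                                      pitch=fibre_pitch)
    plan = SeedingPlan(dims=dims, grid=grid, fb_fraction=fb_fraction)
    state = seed_cells(plan, preset, rng, mask=mask, fibre_field=fibres)
    return run_formation(state, preset, rng, n_mcs=n_mcs,
                         log_every=log_every)
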