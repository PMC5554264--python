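"""Deterministic toy inputs for examples and tests.

Generation is seed-free and exact: tiny lattices (single cell, touching
cell pairs), analytic masks with hand-derivable morphometrics (rectangle,
plus-pentomino, cross, five-armed star) and synthetic activation maps with
known plane-wave speeds.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .ep import ActivationMap
from .lattice import LatticeState
from .params import CM, FB, ModelParams, get_preset


def default_params() -> ModelParams:
    """Parameters used by the toy lattices (isolated no-fibre preset)."""
    return get_preset("isolated_iso").params


def single_cell_lattice(side: int = 6, dims: Tuple[int, int] = (12, 12),
                        cell_type: int = CM) -> LatticeState:
    """One square cell centred in medium."""
    sigma = np.zeros(dims, dtype=np.int32)
    r0 = (dims[0] - side) // 2
    c0 = (dims[1] - side) // 2
    sigma[r0:r0 + side, c0:c0 + side] = 1
    return LatticeState(sigma, np.array([0, cell_type], np.uint8),
                        default_params())


def touching_pair_lattice(types: Tuple[int, int] = (CM, CM),
                          side: int = 5) -> LatticeState:
    """Two square cells sharing a vertical border."""
    dims = (side + 4, 2 * side + 4)
    sigma = np.zeros(dims, dtype=np.int32)
    sigma[2:2 + side, 2:2 + side] = 1
    sigma[2:2 + side, 2 + side:2 + 2 * side] = 2
    return LatticeState(sigma, np.array([0, *types], np.uint8),
                        default_params())


def rectangle_mask(shape: Tuple[int, int] = (10, 20)) -> np.ndarray:
    """Filled rectangle: convex coverage 1, elongation = aspect ratio."""
    return np.ones(shape, dtype=bool)


def plus_pentomino_mask() -> np.ndarray:
    """Five unit squares in a plus: coverage exactly 5/7."""
    m = np.zeros((3, 3), dtype=bool)
    m[1, :] = True
    m[:, 1] = True
    return m


def cross_mask(arm: int = 9, width: int = 3) -> np.ndarray:
    """Symmetric four-armed cross; arms longer than the 7 um nucleus
    radius, so the protrusion count is 4."""
    n = 2 * arm + width
    m = np.zeros((n, n), dtype=bool)
    m[arm:arm + width, :] = True
    m[:, arm:arm + width] = True
    return m


def star_mask(n_arms: int = 5, arm: int = 18) -> np.ndarray:
    """Star with ``n_arms`` thick arms; one skeleton tip per arm."""
    n = 2 * arm + 5
    c = n // 2
    m = np.zeros((n, n), dtype=bool)
    for a in np.linspace(0.0, 2 * np.pi, n_arms, endpoint=False):
        for t in np.linspace(0.0, arm, 4 * arm):
            r = int(round(c + t * np.sin(a)))
            q = int(round(c + t * np.cos(a)))
            m[r - 1:r + 2, q - 1:q + 2] = True
    return m


def linear_activation_map(dims: Tuple[int, int] = (40, 60),
                          speed_px_per_ms: float = 20.0) -> ActivationMap:
    """Plane wave along +x: t = x / c."""
    _, xx = np.indices(dims)
    return ActivationMap(times=xx / speed_px_per_ms)


def anisotropic_activation_map(dims: Tuple[int, int] = (61, 61),
                               speed_x: float = 20.0,
                               speed_y: float = 10.0) -> ActivationMap:
    """Elliptic spread from the domain centre with a 2:1 axis speed
    ratio by default: t = hypot(x/cx, y/cy)."""
    yy, xx = np.indices(dims)
    cy, cx = (dims[0] - 1) / 2, (dims[1] - 1) / 2
    return ActivationMap(times=np.hypot((xx - cx) / speed_x,
                                        (yy - cy) / speed_y))


ALL_MASKS = {
    "rectangle": rectangle_mask,
    "plus_pentomino": plus_pentomino_mask,
    "cross": cross_mask,
    "star": star_mask,
}


def generate_fixtures(outdir) -> Dict[str, object]:
    """Write every fixture in standard formats; idempotent.

    Masks as boolean TIFFs, activation maps as float TIFFs, lattices as
    mesh directories.  Returns the in-memory objects keyed by name.
    """
    from pathlib import Path

    import tifffile

    from .io import write_activation_map, write_mesh

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    objects: Dict[str, object] = {}
    for name, fn in ALL_MASKS.items():
        mask = fn()
        tifffile.imwrite(outdir / f"mask_{name}.tiff",
                         mask.astype(np.uint8))
        objects[name] = mask
    amap = linear_activation_map()
    write_activation_map(amap.times, outdir / "amap_linear.tiff")
    objects["amap_linear"] = amap
    amap2 = anisotropic_activation_map()
    write_activation_map(amap2.times, outdir / "amap_2to1.tiff")
    objects["amap_2to1"] = amap2
    for name, state in [("single_cell", single_cell_lattice()),
                        ("cm_pair", touching_pair_lattice((CM, CM))),
                        ("cm_fb_pair", touching_pair_lattice((CM, FB)))]:
        write_mesh(state, outdir / name, preset="isolated_iso")
        objects[name] = state
    return objects
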