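"""Lattice state containers for the cellular-Potts tissue model.

A :class:`LatticeState` owns the integer cell-index grid ``sigma`` (0 =
medium) together with incrementally maintained per-cell bookkeeping
(volume, centre-of-mass sums, focal adhesions, bounding boxes).  The
bookkeeping lives in flat numpy arrays so that the Monte-Carlo kernels can
run without touching Python objects; :class:`CellRecord` views are built on
demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Set, Tuple

import numpy as np

from . import _kernels
from .params import CM, FB, SPACING_UM, ModelParams


@dataclass(frozen=True)
class CellRecord:
    """Read-only snapshot of one biological cell."""

    index: int
    type: int                      # CM or FB
    volume: int
    target_volume: float
    centre_of_mass: Tuple[float, float]
    adhesions: Set[Tuple[int, int]]
    bbox: Tuple[int, int, int, int]  # rmin, rmax, cmin, cmax (inclusive)

    @property
    def type_name(self) -> str:
        return {CM: "CM", FB: "FB"}[self.type]


@dataclass
class FibreField:
    """Nanofibre occupancy and per-subcell orientation (radians, [0, pi))."""

    occupied: np.ndarray            # uint8 (rows, cols)
    orientation: np.ndarray         # float64 (rows, cols); defined iff occupied

    def __post_init__(self):
        self.occupied = np.ascontiguousarray(self.occupied, dtype=np.uint8)
        self.orientation = np.ascontiguousarray(self.orientation,
                                                dtype=np.float64)
        if self.occupied.shape != self.orientation.shape:
            raise ValueError("occupied and orientation shapes differ")

    @classmethod
    def empty(cls, dims: Tuple[int, int]) -> "FibreField":
        return cls(np.zeros(dims, np.uint8), np.zeros(dims, np.float64))


class LatticeState:
    """Cell-index grid plus per-cell bookkeeping.

    Parameters
    ----------
    sigma : integer array (rows, cols), 0 = medium
    cell_types : array mapping cell index -> type code (entry 0 unused)
    params : ModelParams used to resolve per-type coefficients
    fibre_field : optional FibreField
    mask : optional boolean array of admissible sites (e.g. an L-shaped
        domain); sites outside the mask are frozen medium
    """

    spacing: float = SPACING_UM

    def __init__(self, sigma: np.ndarray, cell_types: np.ndarray,
                 params: ModelParams,
                 fibre_field: Optional[FibreField] = None,
                 mask: Optional[np.ndarray] = None):
        sigma = np.ascontiguousarray(sigma, dtype=np.int32)
        self.sigma = sigma
        self.dims = sigma.shape
        self.params = params
        self.n_cells = int(sigma.max())
        self.mcs_counter = 0

        cell_types = np.asarray(cell_types, dtype=np.uint8)
        if len(cell_types) < self.n_cells + 1:
            raise ValueError("cell_types shorter than the number of cells")
        ct = np.zeros(self.n_cells + 1, dtype=np.uint8)
        ct[1:] = cell_types[1:self.n_cells + 1]
        self.ctype = ct

        self.fibre_field = fibre_field if fibre_field is not None \
            else FibreField.empty(self.dims)
        if self.fibre_field.occupied.shape != self.dims:
            raise ValueError("fibre field dims do not match the lattice")
        self.mask = (np.ones(self.dims, np.uint8) if mask is None
                     else np.ascontiguousarray(mask, dtype=np.uint8))

        self._build_bookkeeping()
        self._build_param_tables()
        # scratch buffers for the connectivity flood fill
        self._visited = np.zeros(self.dims, dtype=np.int64)
        self._gen = np.zeros(1, dtype=np.int64)
        self._stack = np.empty((sigma.size, 2), dtype=np.int64)

    # ------------------------------------------------------------------
    def _build_bookkeeping(self) -> None:
        n = self.n_cells
        self.vol = np.zeros(n + 1, dtype=np.int64)
        self.sum_r = np.zeros(n + 1, dtype=np.int64)
        self.sum_c = np.zeros(n + 1, dtype=np.int64)
        self.bbox = np.zeros((n + 1, 4), dtype=np.int64)
        self.bbox[:, 0] = self.dims[0]
        self.bbox[:, 1] = -1
        self.bbox[:, 2] = self.dims[1]
        self.bbox[:, 3] = -1
        rr, cc = np.nonzero(self.sigma)
        for r, c in zip(rr, cc):
            cell = self.sigma[r, c]
            self.vol[cell] += 1
            self.sum_r[cell] += r
            self.sum_c[cell] += c
        _kernels._tighten_bboxes(self.sigma, self.vol, self.bbox)
        max_p = max(int(self.params.cm.n_protr), int(self.params.fb.n_protr), 1)
        self.adh_r = np.full((n + 1, max_p), -1, dtype=np.int64)
        self.adh_c = np.full((n + 1, max_p), -1, dtype=np.int64)
        self.adh_n = np.zeros(n + 1, dtype=np.int64)
        self.adh_grid = np.zeros(self.dims, dtype=np.uint8)

    def _build_param_tables(self) -> None:
        """Per-cell coefficient tables in lattice units for the kernels."""
        n = self.n_cells
        self.cellf = np.zeros((n + 1, 7), dtype=np.float64)
        self.celli = np.zeros((n + 1, 2), dtype=np.int64)
        for cell in range(1, n + 1):
            tp = self.params.by_type(int(self.ctype[cell]))
            self.cellf[cell, _kernels.PF_LAM] = tp.lam_lattice
            self.cellf[cell, _kernels.PF_TVOL] = tp.target_area_subcells
            self.cellf[cell, _kernels.PF_G] = tp.G_lattice
            self.cellf[cell, _kernels.PF_PDET] = tp.p_detach_lattice
            self.cellf[cell, _kernels.PF_PUNL] = tp.p_unleash_lattice
            self.cellf[cell, _kernels.PF_LMAX2] = tp.l_max_subcells ** 2
            self.cellf[cell, _kernels.PF_PN] = tp.p_nucleus_lattice
            self.celli[cell, 0] = tp.n_protr
            self.celli[cell, 1] = self.ctype[cell]
        self.J = self.params.j_matrix()

    # ------------------------------------------------------------------
    def centre_of_mass(self, cell: int) -> Tuple[float, float]:
        v = self.vol[cell]
        if v == 0:
            raise ValueError(f"cell {cell} has zero volume")
        return self.sum_r[cell] / v, self.sum_c[cell] / v

    def cell(self, index: int) -> CellRecord:
        if not (1 <= index <= self.n_cells) or self.vol[index] == 0:
            raise KeyError(f"no cell with index {index}")
        adh = {(int(self.adh_r[index, k]), int(self.adh_c[index, k]))
               for k in range(self.adh_n[index])}
        tp = self.params.by_type(int(self.ctype[index]))
        return CellRecord(
            index=index,
            type=int(self.ctype[index]),
            volume=int(self.vol[index]),
            target_volume=tp.target_area_subcells,
            centre_of_mass=self.centre_of_mass(index),
            adhesions=adh,
            bbox=tuple(int(x) for x in self.bbox[index]),
        )

    @property
    def cells(self) -> Dict[int, CellRecord]:
        return {i: self.cell(i) for i in range(1, self.n_cells + 1)
                if self.vol[i] > 0}

    def cell_mask(self, index: int) -> np.ndarray:
        """Binary mask of one cell cropped to its bounding box."""
        r0, r1, c0, c1 = self.bbox[index]
        return (self.sigma[r0:r1 + 1, c0:c1 + 1] == index)

    def type_grid(self) -> np.ndarray:
        """Per-pixel cell-type code grid (0 medium, 1 CM, 2 FB)."""
        return self.ctype[self.sigma]

    # ------------------------------------------------------------------
    def validate(self, tol: float = 1e-9) -> None:
        """Audit the incremental bookkeeping against ``sigma``.

        Raises ``ValueError`` on the first inconsistency; used by tests and
        by the mesh reader to detect corrupted inputs.
        """
        vol = np.bincount(self.sigma.ravel(), minlength=self.n_cells + 1)
        if not np.array_equal(vol[1:], self.vol[1:]):
            bad = int(np.nonzero(vol[1:] != self.vol[1:])[0][0]) + 1
            raise ValueError(
                f"volume bookkeeping mismatch for cell {bad}: "
                f"grid={vol[bad]} record={self.vol[bad]}")
        rr, cc = np.nonzero(self.sigma)
        sum_r = np.zeros(self.n_cells + 1, np.int64)
        sum_c = np.zeros(self.n_cells + 1, np.int64)
        np.add.at(sum_r, self.sigma[rr, cc], rr)
        np.add.at(sum_c, self.sigma[rr, cc], cc)
        for cell in range(1, self.n_cells + 1):
            if self.vol[cell] == 0:
                continue
            if (abs(sum_r[cell] - self.sum_r[cell]) > 0
                    or abs(sum_c[cell] - self.sum_c[cell]) > 0):
                raise ValueError(f"centre-of-mass sums wrong for cell {cell}")
            cm = self.centre_of_mass(cell)
            cm_ref = (sum_r[cell] / vol[cell], sum_c[cell] / vol[cell])
            if (abs(cm[0] - cm_ref[0]) > tol or abs(cm[1] - cm_ref[1]) > tol):
                raise ValueError(f"centre of mass drifted for cell {cell}")
            for k in range(self.adh_n[cell]):
                r, c = self.adh_r[cell, k], self.adh_c[cell, k]
                if self.sigma[r, c] != cell:
                    raise ValueError(
                        f"adhesion ({r},{c}) not owned by cell {cell}")
                if self.adh_grid[r, c] == 0:
                    raise ValueError(
                        f"adhesion grid out of sync at ({r},{c})")
            if self.adh_n[cell] > self.celli[cell, 0]:
                raise ValueError(f"adhesion quota exceeded for cell {cell}")
        if int(self.adh_grid.sum()) != int(self.adh_n.sum()):
            raise ValueError("adhesion grid count mismatch")

    def copy(self) -> "LatticeState":
        new = LatticeState.__new__(LatticeState)
        new.__dict__.update(self.__dict__)
        for name in ("sigma", "vol", "sum_r", "sum_c", "bbox", "adh_r",
                     "adh_c", "adh_n", "adh_grid", "_visited", "_gen",
                     "_stack", "mask", "ctype", "cellf", "celli", "J"):
            setattr(new, name, getattr(self, name).copy())
        return new
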