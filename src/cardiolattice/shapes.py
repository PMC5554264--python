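"""Cell-shape morphometrics on binary subcell masks.

The five descriptors used to validate the tissue model against stained
cell cultures:

* spreading area (um^2),
* convex coverage -- cell area over convex-hull area; discriminates
  cardiomyocytes (~80%) from fibroblasts (60-70%),
* caliper elongation l/w -- long over short side of the minimum-area
  bounding rectangle of the convex hull,
* protrusion count at 1.0 um resolution -- skeleton endpoints outside the
  nucleus region,
* convex count at 2.5 um resolution -- same algorithm at the native
  lattice resolution (coarse rasterisation averages some protrusions out).

The convex hull is taken over the subcell *corner* points, so any convex
raster shape scores a coverage of exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage.morphology import skeletonize

from .lattice import LatticeState
from .params import CM, FB, NUCLEUS_RADIUS_UM, SPACING_UM, TYPE_NAMES

__all__ = [
    "area_um2", "caliper_elongation", "convex_coverage",
    "count_protrusions", "shape_summary", "shape_fitness", "ShapeReport",
]

#: metric columns of a shape report
METRICS = ("area_um2", "convex_coverage", "elongation",
           "protrusions_1um", "convexes_2p5um")


def _corner_points(mask: np.ndarray) -> np.ndarray:
    """Outer corner points of all subcells in the mask (deduplicated)."""
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty mask")
    pts = np.concatenate([
        np.stack([rr, cc], 1),
        np.stack([rr + 1, cc], 1),
        np.stack([rr, cc + 1], 1),
        np.stack([rr + 1, cc + 1], 1),
    ])
    return np.unique(pts, axis=0)


def area_um2(mask: np.ndarray, spacing: float = SPACING_UM) -> float:
    """Spreading area: subcell count times the subcell area."""
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty mask")
    return n * spacing * spacing


def convex_coverage(mask: np.ndarray) -> float:
    """Mask area divided by its convex-hull area (hull over subcell
    corners); equals 1 for convex raster shapes."""
    pts = _corner_points(mask)
    hull = MultiPoint(pts).convex_hull
    n = float(np.count_nonzero(mask))
    if hull.area == 0.0:  # degenerate 1-pixel-wide shapes: hull is a segment
        return 1.0
    return min(1.0, n / hull.area)


def caliper_elongation(mask: np.ndarray) -> float:
    """Long over short side of the minimum-area bounding rectangle of the
    convex hull (rotating-calipers extremes); >= 1."""
    if np.count_nonzero(mask) < 2:
        raise ValueError("elongation undefined for a single-subcell mask")
    pts = _corner_points(mask)
    rect = MultiPoint(pts).convex_hull.minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    e1 = np.hypot(*(xy[1] - xy[0]))
    e2 = np.hypot(*(xy[2] - xy[1]))
    lo, hi = sorted((e1, e2))
    if lo == 0.0:
        lo = 1.0  # degenerate collinear mask: width is one subcell
    return hi / lo


def _endpoint_pixels(skel: np.ndarray) -> np.ndarray:
    """Boolean map of skeleton pixels with exactly one 8-connected
    skeleton neighbour (isolated pixels do not count)."""
    k = np.ones((3, 3), dtype=int)
    neigh = ndimage.convolve(skel.astype(int), k, mode="constant") - skel
    return skel & (neigh == 1)


def count_protrusions(mask: np.ndarray, resolution: float = 1.0,
                      spacing: float = SPACING_UM,
                      central_radius_um: float = NUCLEUS_RADIUS_UM) -> int:
    """Protrusion count: skeleton endpoints outside the central disk.

    The mask is resampled from the lattice resolution to ``resolution`` um
    per pixel (nearest neighbour, crisp boundaries), skeletonised, the part
    of the skeleton within ``central_radius_um`` of the mask centroid is
    removed, and the remaining endpoints are counted.  Endpoints sitting on
    the cut boundary itself (created by the removal, not by a protrusion)
    are excluded.
    """
    if resolution not in (1.0, 2.5):
        raise ValueError("resolution must be 1.0 or 2.5 um")
    if np.count_nonzero(mask) == 0:
        raise ValueError("empty mask")
    zoom = spacing / resolution
    m = mask.astype(np.uint8)
    if zoom != 1.0:
        m = ndimage.zoom(m, zoom, order=0)
    if np.count_nonzero(m) == 0:
        warnings.warn("mask vanished at the requested resolution")
        return 0
    skel = skeletonize(m.astype(bool), method="lee").astype(bool)
    r_px = central_radius_um / resolution
    rr, cc = np.nonzero(m)
    cen_r, cen_c = rr.mean(), cc.mean()
    yy, xx = np.indices(m.shape)
    d2 = (yy - cen_r) ** 2 + (xx - cen_c) ** 2
    skel = skel & (d2 >= r_px ** 2)
    if not skel.any():
        if np.count_nonzero(m) <= np.pi * r_px ** 2:
            warnings.warn("mask smaller than the central disk; count is 0")
        return 0
    tips = _endpoint_pixels(skel)
    # drop endpoints adjacent to the removed centre: those are cut ends,
    # not protrusion tips
    tips = tips & (d2 >= (r_px + 2.0) ** 2)
    return int(np.count_nonzero(tips))


@dataclass
class ShapeReport:
    """Per-cell metric table plus per-type mean +/- SD summary."""

    per_cell: pd.DataFrame
    summary: pd.DataFrame  # index: type name; columns: metric mean/sd

    def mean(self, type_name: str, metric: str) -> float:
        return float(self.summary.loc[type_name, f"{metric}_mean"])

    def sd(self, type_name: str, metric: str) -> float:
        return float(self.summary.loc[type_name, f"{metric}_sd"])


def _summarise(per_cell: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for tname, grp in per_cell.groupby("type"):
        row = {}
        for m in METRICS:
            row[f"{m}_mean"] = grp[m].mean()
            row[f"{m}_sd"] = grp[m].std(ddof=1) if len(grp) > 1 else 0.0
        row["n"] = len(grp)
        rows[tname] = row
    return pd.DataFrame(rows).T


def shape_summary(state: LatticeState,
                  min_volume: int = 4) -> ShapeReport:
    """All five metrics per cell and mean +/- SD per type.

    Convex counts use the native 2.5 um resolution, protrusion counts the
    1.0 um resampling.  Cells smaller than ``min_volume`` subcells are
    skipped (no meaningful shape).
    """
    if state.n_cells == 0:
        raise ValueError("state has no cells")
    records = []
    for idx in range(1, state.n_cells + 1):
        if state.vol[idx] < min_volume:
            continue
        mask = state.cell_mask(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records.append({
                "cell": idx,
                "type": TYPE_NAMES[int(state.ctype[idx])],
                "area_um2": area_um2(mask, state.spacing),
                "convex_coverage": convex_coverage(mask),
                "elongation": caliper_elongation(mask),
                "protrusions_1um": count_protrusions(mask, 1.0,
                                                     state.spacing),
                "convexes_2p5um": count_protrusions(mask, 2.5,
                                                    state.spacing),
            })
    per_cell = pd.DataFrame.from_records(records)
    return ShapeReport(per_cell=per_cell, summary=_summarise(per_cell))


def report_from_masks(masks: Dict[int, np.ndarray],
                      types: Dict[int, str],
                      spacing: float = SPACING_UM) -> ShapeReport:
    """Build a report from user-supplied per-cell masks (label images)."""
    records = []
    for idx, mask in masks.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records.append({
                "cell": idx, "type": types[idx],
                "area_um2": area_um2(mask, spacing),
                "convex_coverage": convex_coverage(mask),
                "elongation": caliper_elongation(mask),
                "protrusions_1um": count_protrusions(mask, 1.0, spacing),
                "convexes_2p5um": count_protrusions(mask, 2.5, spacing),
            })
    per_cell = pd.DataFrame.from_records(records)
    return ShapeReport(per_cell=per_cell, summary=_summarise(per_cell))


def shape_fitness(report: ShapeReport, reference: ShapeReport) -> float:
    """Sum over (type, metric) of squared z-distances
    ``((mean_sim - mean_ref) / sd_ref)^2``; 0 iff all means coincide.

    This is the objective a parameter search would minimise when fitting
    the growth model to measured cell shapes.
    """
    total = 0.0
    for tname in reference.summary.index:
        if tname not in report.summary.index:
            raise ValueError(f"report is missing cell type {tname}")
        for m in METRICS:
            sd = reference.sd(tname, m)
            if sd == 0.0:
                sd = 1.0
            total += ((report.mean(tname, m) - reference.mean(tname, m))
                      / sd) ** 2
    return float(total)
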