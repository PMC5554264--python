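"""Mesh and result serialisation, run manifests, pipeline orchestration.

Mesh layout (one directory per tissue):

* ``sigma.tiff``      -- 16-bit cell-index label image (0 = medium)
* ``cells.csv``       -- per-cell table: index, type, volume, cm_row,
  cm_col, adhesion sites encoded ``"r:c;r:c;..."``
* ``fibres.tiff``     -- boolean fibre occupancy (only when fibres exist);
  the constant fibre orientation is stored in the manifest
* ``manifest.json``   -- preset name, resolved parameters, seed, MCS
  count, lattice dims, file inventory with sha256 checksums

Coordinates are row/column, 0-based, origin top-left; the physical scale
is 2.5 um per subcell throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .gj import ConductanceMap, GJLabelField
from .lattice import FibreField, LatticeState
from .params import ModelParams, Preset, get_preset

__all__ = ["write_mesh", "read_mesh", "write_manifest", "MeshLoadError",
           "write_conductance", "read_conductance",
           "write_activation_map", "read_activation_map"]


class MeshLoadError(ValueError):
    """Inconsistent or truncated mesh input."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, stage: str, *, preset: Optional[str],
                   seed: Optional[int], params: dict,
                   files: Dict[str, Path]) -> Path:
    outdir = Path(outdir)
    manifest = {
        "tool_version": __version__,
        "stage": stage,
        "preset": preset,
        "seed": seed,
        "parameters": params,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {name: {"path": p.name, "sha256": _sha256(p)}
                  for name, p in files.items()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def _encode_adhesions(state: LatticeState, cell: int) -> str:
    return ";".join(f"{state.adh_r[cell, k]}:{state.adh_c[cell, k]}"
                    for k in range(state.adh_n[cell]))


def write_mesh(state: LatticeState, outdir, *, preset: Optional[str] = None,
               seed: Optional[int] = None,
               extra_params: Optional[dict] = None) -> Path:
    """Write a tissue mesh directory; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if state.n_cells >= 2 ** 16:
        raise ValueError("too many cells for a 16-bit label image")
    files: Dict[str, Path] = {}
    sigma_path = outdir / "sigma.tiff"
    tifffile.imwrite(sigma_path, state.sigma.astype(np.uint16))
    files["sigma"] = sigma_path

    rows = []
    for cell in range(1, state.n_cells + 1):
        if state.vol[cell] == 0:
            continue
        cm_r, cm_c = state.centre_of_mass(cell)
        rows.append({
            "index": cell,
            "type": int(state.ctype[cell]),
            "volume": int(state.vol[cell]),
            "cm_row": cm_r,
            "cm_col": cm_c,
            "adhesions": _encode_adhesions(state, cell),
        })
    cells_path = outdir / "cells.csv"
    pd.DataFrame(rows).to_csv(cells_path, index=False)
    files["cells"] = cells_path

    fibre_orientation = None
    if state.fibre_field.occupied.any():
        fibre_path = outdir / "fibres.tiff"
        tifffile.imwrite(fibre_path, state.fibre_field.occupied)
        files["fibres"] = fibre_path
        occ = state.fibre_field.occupied.astype(bool)
        fibre_orientation = float(state.fibre_field.orientation[occ][0])
    if not state.mask.all():
        mask_path = outdir / "mask.tiff"
        tifffile.imwrite(mask_path, state.mask)
        files["mask"] = mask_path

    params = {
        "dims": list(state.dims),
        "mcs": state.mcs_counter,
        "spacing_um": state.spacing,
        "fibre_orientation": fibre_orientation,
        "model_params": dataclasses.asdict(state.params),
    }
    if extra_params:
        params.update(extra_params)
    return write_manifest(outdir, "grow", preset=preset, seed=seed,
                          params=params, files=files)


def read_mesh(indir, params: Optional[ModelParams] = None) -> LatticeState:
    """Load a mesh directory back into a consistent LatticeState.

    Verifies file checksums against the manifest and the cell table
    against the label image; inconsistencies raise :class:`MeshLoadError`
    naming the offending cell index.
    """
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    for name, entry in manifest["files"].items():
        p = indir / entry["path"]
        if not p.exists():
            raise MeshLoadError(f"missing file {entry['path']}")
        if _sha256(p) != entry["sha256"]:
            raise MeshLoadError(f"checksum mismatch for {entry['path']}")

    sigma = tifffile.imread(indir / "sigma.tiff").astype(np.int32)
    cells = pd.read_csv(indir / "cells.csv",
                        dtype={"adhesions": str}, keep_default_na=False)
    n_cells = int(sigma.max())
    present = set(cells["index"].astype(int))
    for cell in range(1, n_cells + 1):
        if np.any(sigma == cell) and cell not in present:
            raise MeshLoadError(f"cell {cell} present in the label image "
                                "but missing from the cell table")

    if params is None:
        preset_name = manifest.get("preset")
        if preset_name:
            params = get_preset(preset_name).params
        else:
            raise MeshLoadError("no preset in manifest; pass params "
                                "explicitly")
    cell_types = np.zeros(n_cells + 1, dtype=np.uint8)
    for _, row in cells.iterrows():
        cell_types[int(row["index"])] = int(row["type"])

    fibre_field = None
    if "fibres" in manifest["files"]:
        occ = tifffile.imread(indir / "fibres.tiff").astype(np.uint8)
        ang = np.zeros(occ.shape)
        orientation = manifest["parameters"].get("fibre_orientation") or 0.0
        ang[occ > 0] = orientation
        fibre_field = FibreField(occ, ang)
    mask = None
    if "mask" in manifest["files"]:
        mask = tifffile.imread(indir / "mask.tiff").astype(np.uint8)

    state = LatticeState(sigma, cell_types, params,
                         fibre_field=fibre_field, mask=mask)
    state.mcs_counter = int(manifest["parameters"].get("mcs", 0))

    # restore adhesions and cross-check the table
    for _, row in cells.iterrows():
        cell = int(row["index"])
        if int(row["volume"]) != int(state.vol[cell]):
            raise MeshLoadError(
                f"cell {cell}: table volume {row['volume']} != "
                f"{int(state.vol[cell])} in the label image")
        adh = str(row["adhesions"])
        if adh:
            for tok in adh.split(";"):
                r_s, c_s = tok.split(":")
                r, c = int(r_s), int(c_s)
                if sigma[r, c] != cell:
                    raise MeshLoadError(
                        f"cell {cell}: adhesion ({r},{c}) not owned by it")
                k = state.adh_n[cell]
                if k >= state.adh_r.shape[1]:
                    raise MeshLoadError(
                        f"cell {cell}: more adhesions than the quota")
                state.adh_r[cell, k] = r
                state.adh_c[cell, k] = c
                state.adh_n[cell] = k + 1
                state.adh_grid[r, c] = 1
    state.validate()
    return state


# ---------------------------------------------------------------------------

def write_conductance(dmap: ConductanceMap, path) -> Path:
    """Face-coefficient arrays in a compressed NPZ container."""
    path = Path(path)
    np.savez_compressed(path, horizontal=dmap.horizontal,
                        vertical=dmap.vertical)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix
                                                               + ".npz")


def read_conductance(path) -> ConductanceMap:
    with np.load(path) as z:
        return ConductanceMap(horizontal=z["horizontal"],
                              vertical=z["vertical"])


def write_gj_labels(gjf: GJLabelField, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, gjf.labels)
    return path


def write_activation_map(times: np.ndarray, path_tiff, path_csv=None):
    tifffile.imwrite(path_tiff, times.astype(np.float32))
    if path_csv is not None:
        pd.DataFrame(times).to_csv(path_csv, index=False, header=False)


def read_activation_map(path_tiff) -> np.ndarray:
    return tifffile.imread(path_tiff).astype(np.float64)


def write_frames(frames: np.ndarray, times: np.ndarray, path) -> Path:
    """Voltage movie in an HDF5 container."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=frames, compression="gzip")
        f.create_dataset("times_ms", data=times)
    return path
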