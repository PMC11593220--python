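"""Readers and writers for the on-disk exchange formats.

Label maps travel as single-channel 8-bit PNG (or TIFF for wide maps) with
a JSON sidecar documenting class codes and pixel size; nuclei as CSV point
tables; cohorts, feature matrices, scores and patch grids as CSV; fitted
models as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
import tifffile

from .preprocess import CellPointSet, LabelMap, PatchGrid

__all__ = [
    "write_label_map", "read_label_map",
    "write_points", "read_points",
    "write_cohort", "read_cohort",
    "write_feature_matrix", "read_feature_matrix",
    "write_patch_grid",
]


def write_label_map(path, label_map: LabelMap) -> None:
    """Write a label map as 8-bit PNG/TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    grid = np.asarray(label_map.grid)
    if grid.max(initial=0) > 255:
        raise ValueError("label codes above 255 are not supported")
    arr = grid.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)
    sidecar = {
        "pixel_size_um": label_map.pixel_size_um,
        "class_codes": {str(k): v for k, v in label_map.class_codes.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_label_map(path) -> LabelMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path)
    else:
        grid = np.asarray(Image.open(path))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return LabelMap(
        grid=grid,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        class_codes={int(k): v for k, v in sidecar["class_codes"].items()},
    )


def write_points(path, cells: CellPointSet, patient_id: str = "") -> None:
    pd.DataFrame({
        "patient_id": patient_id,
        "x_px": cells.x_px,
        "y_px": cells.y_px,
        "class": cells.classes,
    }).to_csv(path, index=False)


def read_points(path, frame_shape: tuple[int, int],
                frame_pixel_size_um: float) -> CellPointSet:
    df = pd.read_csv(path)
    return CellPointSet(
        x_px=df["x_px"].to_numpy(float),
        y_px=df["y_px"].to_numpy(float),
        classes=df["class"].to_numpy(object),
        frame_shape=frame_shape,
        frame_pixel_size_um=frame_pixel_size_um,
    )


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_matrix(path, fm: pd.DataFrame) -> None:
    fm.to_csv(path, index_label="patient_id")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")


def write_patch_grid(path, grid: PatchGrid) -> None:
    """Patch grid as tidy CSV: one row per patch with layer fractions,
    graded dominant levels and validity."""
    nr, nc = grid.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    data = {
        "row": rows.ravel(),
        "col": cols.ravel(),
        "valid": grid.valid.ravel().astype(int),
        "tissue_fraction": grid.tissue_fraction.ravel(),
    }
    for name, f in grid.fractions.items():
        data[f"frac_{name}"] = f.ravel()
    for group, lev in grid.levels.items():
        data[f"level_{group}"] = lev.ravel()
    pd.DataFrame(data).to_csv(path, index=False)
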