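"""Reading and writing the package's exchange formats.

Measurement series travel as delimited text (CSV) with columns
``stone_id, direction, level_index, x_mm, y_mm, component_id`` (an
equivalent JSON layout is accepted); Q results are written as JSON records;
masks are NIfTI volumes or raw arrays with a JSON spacing sidecar.

NIfTI stores data (x, y, z); the in-memory convention here is (z, y, x)
with slice 0 most superior, so volumes are transposed on the way in and
out and the zooms reversed accordingly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .ct_measure import LevelMeasurement, MaskQResult, StoneSeries, VoxelMask

__all__ = [
    "series_to_frame",
    "frame_to_series",
    "read_series_csv",
    "write_series_csv",
    "read_series_json",
    "write_q_json",
    "load_mask",
    "save_mask_nifti",
]

_SERIES_COLS = ["stone_id", "direction", "level_index", "x_mm", "y_mm",
                "component_id"]


def series_to_frame(series_list: Sequence[StoneSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for m in s.levels:
            rows.append(
                {
                    "stone_id": s.stone_id,
                    "direction": s.direction,
                    "level_index": m.level_index,
                    "x_mm": m.x_mm,
                    "y_mm": m.y_mm,
                    "component_id": m.component_id,
                    "level_step_mm": s.level_step_mm,
                }
            )
    return pd.DataFrame(rows)


def frame_to_series(df: pd.DataFrame, default_step_mm: float = 4.9) -> list[StoneSeries]:
    missing = [c for c in _SERIES_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"series table missing columns: {missing}")
    out = []
    for (sid, direction), sub in df.groupby(["stone_id", "direction"], sort=False):
        sub = sub.sort_values(["level_index", "component_id"])
        step = float(sub["level_step_mm"].iloc[0]) if "level_step_mm" in sub \
            else default_step_mm
        levels = [
            LevelMeasurement(
                level_index=int(r.level_index),
                component_id=int(r.component_id),
                x_mm=float(r.x_mm),
                y_mm=float(r.y_mm),
            )
            for r in sub.itertuples()
        ]
        out.append(StoneSeries(sid, direction, levels, step))
    return out


def read_series_csv(path: str | Path) -> list[StoneSeries]:
    return frame_to_series(pd.read_csv(path))


def write_series_csv(series_list: Sequence[StoneSeries], path: str | Path) -> None:
    series_to_frame(series_list).to_csv(path, index=False)


def read_series_json(path: str | Path) -> list[StoneSeries]:
    with open(path) as fh:
        payload = json.load(fh)
    return frame_to_series(pd.DataFrame(payload))


def write_q_json(result: MaskQResult, path: str | Path) -> None:
    payload = {
        "stones": [s.to_record() for s in result.stones],
        "n_ignored": result.n_ignored,
        "total_topdown": result.total_topdown,
        "total_bottomup": result.total_bottomup,
        "total_average": result.total_average,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_mask(path: str | Path, spacing: tuple[float, float, float] | None = None
              ) -> VoxelMask:
    """Load a binary mask from NIfTI or a raw ``.npy`` array + JSON sidecar.

    For raw arrays the sidecar ``<name>.json`` must hold
    ``{"spacing_mm": [dz, dy, dx]}`` unless ``spacing`` is given.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj) > 0
        zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
        grid = np.transpose(data, (2, 1, 0))
        return VoxelMask(grid, (float(zooms[2]), float(zooms[1]), float(zooms[0])))
    if path.suffix == ".npy":
        grid = np.load(path)
        if spacing is None:
            sidecar = path.with_suffix(".json")
            if not sidecar.exists():
                raise ValueError(f"raw mask {path} needs a spacing sidecar or spacing=")
            spacing = tuple(json.loads(sidecar.read_text())["spacing_mm"])
        return VoxelMask(grid, spacing)
    raise ValueError(f"unsupported mask format: {path}")


def save_mask_nifti(mask: VoxelMask, path: str | Path) -> None:
    dz, dy, dx = mask.spacing
    data = np.transpose(mask.grid.astype(np.uint8), (2, 1, 0))
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
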