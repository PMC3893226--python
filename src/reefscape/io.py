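"""Point-table I/O: fish-target and density-bin CSV schemas.

Targets: x, y, depth_m, ts_db [, length_cm, size_class]
Bins:    x, y, area_m2, track_len_m, count_* and dens_* per size class

Schema violations are reported with the 1-based file line number
(header = line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics
from .acoustics import DensityBin, FishTarget
from .grids import read_ascii_grid, read_raster, write_ascii_grid, write_raster  # noqa: F401

TARGET_COLUMNS = ("x", "y", "depth_m", "ts_db")
BIN_COLUMNS = ("x", "y", "area_m2", "track_len_m")


def _read_checked(path: str | Path, required: tuple[str, ...],
                  numeric: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = coerced
    return df


def read_targets(path: str | Path) -> list[FishTarget]:
    df = _read_checked(path, TARGET_COLUMNS, TARGET_COLUMNS + ("length_cm",))
    return acoustics.targets_from_frame(df)


def write_targets(targets: list[FishTarget], path: str | Path) -> None:
    # %.17g guarantees a lossless double round trip through text
    acoustics.targets_to_frame(targets).to_csv(path, index=False, float_format="%.17g")


def read_bins(path: str | Path) -> list[DensityBin]:
    count_cols = tuple(f"count_{c}" for c in acoustics.SIZE_CLASSES)
    df = _read_checked(path, BIN_COLUMNS + count_cols, BIN_COLUMNS + count_cols)
    bins = []
    for rec in df.itertuples(index=False):
        b = DensityBin(x=float(rec.x), y=float(rec.y), area_m2=float(rec.area_m2),
                       track_len_m=float(rec.track_len_m))
        for c in acoustics.SIZE_CLASSES:
            b.counts[c] = int(getattr(rec, f"count_{c}"))
        bins.append(b)
    return bins


def write_bins(bins: list[DensityBin], path: str | Path) -> None:
    acoustics.bins_to_frame(bins).to_csv(path, index=False, float_format="%.17g")


def write_stack(stack, out_dir: str | Path) -> dict:
    """Write every predictor layer as an ESRI ASCII grid plus a JSON manifest."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = stack.grid
    entries = []
    for name, layer in stack.layers.items():
        fname = name.replace("@", "_at_") + ".asc"
        write_ascii_grid(layer, grid.cell_size, grid.origin, out / fname)
        surface, _, radius = name.partition("@")
        entries.append({"name": name, "surface": surface,
                        "radius_m": float(radius), "file": fname})
    manifest = {"cell_size": grid.cell_size, "origin": list(grid.origin),
                "layers": entries}
    with open(out / "stack_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
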