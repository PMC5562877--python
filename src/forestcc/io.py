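"""Raster and table I/O.

Rasters are written as multiband TIFF (one band per year for annual
stacks), with the grid geometry, year span and nodata sentinel carried in a
JSON document in the image description tag.  Integer data round-trips
bit-exactly; numeric data is stored as float32.  Nodata sentinels follow
the package convention: -9999 for numeric bands, 255 for categorical or
binary bands.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grid import AnnualCube, GridSpec, NODATA_FLOAT, NODATA_INT

_META_KEY = "forestcc"


def _grid_meta(grid: GridSpec, nodata: float) -> str:
    return json.dumps(
        {
            _META_KEY: {
                "rows": grid.rows,
                "cols": grid.cols,
                "pixel_size_m": grid.pixel_size_m,
                "origin_x": grid.origin_x,
                "origin_y": grid.origin_y,
                "year_start": grid.year_start,
                "year_end": grid.year_end,
                "nodata": nodata,
            }
        }
    )


def write_raster(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    nodata: float | None = None,
) -> None:
    """Write a 2-D raster or (year, row, col) stack as multiband TIFF."""
    values = np.asarray(values)
    if values.ndim == 2:
        stack = values[None]
    elif values.ndim == 3:
        stack = values
    else:
        raise ValueError("expected a 2-D raster or a 3-D annual stack")
    if stack.shape[-2:] != grid.shape:
        raise ValueError(f"raster shape {stack.shape} does not match grid {grid.shape}")
    if np.issubdtype(stack.dtype, np.floating):
        stack = stack.astype(np.float32)
        nodata = NODATA_FLOAT if nodata is None else nodata
    else:
        nodata = NODATA_INT if nodata is None else nodata
    tifffile.imwrite(
        Path(path),
        stack,
        photometric="minisblack",
        description=_grid_meta(grid, float(nodata)),
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read a raster written by :func:`write_raster`.

    Returns (values, grid, nodata); 2-D for single-band files, 3-D stacks
    otherwise.
    """
    with tifffile.TiffFile(Path(path)) as tif:
        values = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)[_META_KEY]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path} carries no grid metadata") from exc
    grid = GridSpec(
        rows=meta["rows"],
        cols=meta["cols"],
        pixel_size_m=meta["pixel_size_m"],
        origin_x=meta["origin_x"],
        origin_y=meta["origin_y"],
        year_start=meta["year_start"],
        year_end=meta["year_end"],
    )
    if values.ndim == 3 and values.shape[0] == 1:
        values = values[0]
    return values, grid, float(meta["nodata"])


def write_cube(path: str | Path, cube: AnnualCube) -> None:
    write_raster(path, cube.values, cube.grid, nodata=cube.nodata)


def read_cube(path: str | Path) -> AnnualCube:
    values, grid, nodata = read_raster(path)
    if values.ndim == 2:
        values = values[None]
    return AnnualCube(grid, values, nodata=nodata)
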