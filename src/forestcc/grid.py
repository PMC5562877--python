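"""Grid geometry and annual raster cubes.

All rasters in this package live on an abstract equal-area grid: square
pixels of known side length, row-major from the top-left corner, pixel-center
coordinate convention.  Because the grid is equal-area, area accounting
reduces to pixel counting (area = count x pixel_area_km2), which is the
arithmetic every downstream statistic relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NODATA_FLOAT = -9999.0
NODATA_INT = 255


@dataclass(frozen=True)
class GridSpec:
    """Geometry and time span of an annual raster stack.

    Parameters
    ----------
    rows, cols
        Raster dimensions (>= 1).
    pixel_size_m
        Square pixel side length in metres (> 0).
    origin_x, origin_y
        Projected coordinates (m) of the top-left corner of the grid.
    year_start, year_end
        Inclusive calendar-year span of the stack.
    """

    rows: int
    cols: int
    pixel_size_m: float = 500.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    year_start: int = 2000
    year_end: int = 2013

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size_m / 1000.0) ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def refine(self, factor: int) -> "GridSpec":
        """Return the grid of a ``factor``-times finer product on the same extent."""
        if factor < 1:
            raise ValueError("refine factor must be >= 1")
        return replace(
            self,
            rows=self.rows * factor,
            cols=self.cols * factor,
            pixel_size_m=self.pixel_size_m / factor,
        )

    def coarsen(self, factor: int) -> "GridSpec":
        if factor < 1:
            raise ValueError("coarsen factor must be >= 1")
        if self.rows % factor or self.cols % factor:
            raise ValueError("grid dimensions must be divisible by the factor")
        return replace(
            self,
            rows=self.rows // factor,
            cols=self.cols // factor,
            pixel_size_m=self.pixel_size_m * factor,
        )


@dataclass
class AnnualCube:
    """A (year, row, col) stack of single-band annual rasters.

    ``values`` is float for numeric products (spectral index in [-1, 1],
    percent cover in [0, 100]) and int for categorical series.  Missing
    observations are encoded with ``nodata``.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float = NODATA_FLOAT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        expected = (self.grid.n_years, self.grid.rows, self.grid.cols)
        if self.values.shape != expected:
            raise ValueError(
                f"cube shape {self.values.shape} does not match grid {expected}"
            )

    @property
    def years(self) -> np.ndarray:
        return self.grid.years

    def year_index(self, year: int) -> int:
        if not (self.grid.year_start <= year <= self.grid.year_end):
            raise ValueError(f"year {year} outside cube span")
        return year - self.grid.year_start

    def layer(self, year: int) -> np.ndarray:
        return self.values[self.year_index(year)]

    def mask_valid(self) -> np.ndarray:
        """Boolean (year, row, col) array of valid observations."""
        if np.issubdtype(self.values.dtype, np.floating):
            return (self.values != self.nodata) & ~np.isnan(self.values)
        return self.values != self.nodata


def check_same_grid(a: GridSpec, b: GridSpec) -> None:
    """Reject rasters whose spatial footprints disagree (years may differ)."""
    if (a.rows, a.cols, a.pixel_size_m) != (b.rows, b.cols, b.pixel_size_m):
        raise ValueError(
            f"grid mismatch: {a.rows}x{a.cols}@{a.pixel_size_m}m vs "
            f"{b.rows}x{b.cols}@{b.pixel_size_m}m"
        )
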