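"""Fine-to-coarse aggregation and block-aligned resampling.

All operations use integer scale factors and block alignment (a coarse cell
covers exactly factor x factor fine pixels), which is how the coarse and
fine products in this analysis nest; sub-pixel registration never arises.

Five resampling methods mirror the standard GDAL kernels for the scaling
sensitivity experiment: nearest neighbour, bilinear, average (block mean),
mode (block majority) and cubic (Catmull-Rom, a = -0.5, edge-clamped,
clipped to the input range).  Interpolating methods sample at coarse-cell
centres.  Bilinear, average and cubic are rejected for categorical data —
interpolating class codes is meaningless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import accounting, mapchange
from .grid import GridSpec
from .trajfit import LABEL_GAIN, LABEL_LOSS

RESAMPLE_METHODS = ("nearest", "bilinear", "average", "mode", "cubic")
CATEGORICAL_OK = ("nearest", "mode")


def _blocks(a: np.ndarray, factor: int) -> np.ndarray:
    r, c = a.shape
    if r % factor or c % factor:
        raise ValueError(
            f"dimensions {a.shape} not divisible by factor {factor}"
        )
    return a.reshape(r // factor, factor, c // factor, factor).swapaxes(1, 2)


def aggregate_average(
    fine: np.ndarray, factor: int, nodata: float | None = None
) -> np.ndarray:
    """Coarse cell = mean of its factor x factor children.

    Nodata-aware: the mean is over valid children only; a coarse cell is
    nodata (NaN) only when every child is missing.
    """
    fine = np.asarray(fine, dtype=float)
    blocks = _blocks(fine, factor)
    if nodata is None:
        return blocks.mean(axis=(2, 3))
    valid = (blocks != nodata) & ~np.isnan(blocks)
    with np.errstate(invalid="ignore"):
        out = np.where(valid, blocks, 0.0).sum(axis=(2, 3)) / valid.sum(axis=(2, 3))
    return out


def aggregate_fraction(fine_binary: np.ndarray, factor: int) -> np.ndarray:
    """Coarse percent map: 100 x (flagged children / children per cell)."""
    blocks = _blocks(np.asarray(fine_binary) > 0, factor)
    return 100.0 * blocks.mean(axis=(2, 3))


def _resample_nearest(a: np.ndarray, factor: int) -> np.ndarray:
    # coarse-cell centre in fine index space: (I + 0.5) * factor - 0.5
    n_r, n_c = a.shape[0] // factor, a.shape[1] // factor
    idx_r = np.floor((np.arange(n_r) + 0.5) * factor).astype(int)
    idx_c = np.floor((np.arange(n_c) + 0.5) * factor).astype(int)
    idx_r = np.clip(idx_r, 0, a.shape[0] - 1)
    idx_c = np.clip(idx_c, 0, a.shape[1] - 1)
    return a[np.ix_(idx_r, idx_c)]


def _centre_coords(n_coarse: int, factor: int) -> np.ndarray:
    return (np.arange(n_coarse) + 0.5) * factor - 0.5


def _resample_bilinear(a: np.ndarray, factor: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    out_r = _centre_coords(a.shape[0] // factor, factor)
    out_c = _centre_coords(a.shape[1] // factor, factor)

    def interp_axis(arr, coords, axis):
        n = arr.shape[axis]
        x0 = np.clip(np.floor(coords).astype(int), 0, n - 1)
        x1 = np.clip(x0 + 1, 0, n - 1)
        w = coords - np.floor(coords)
        lo = np.take(arr, x0, axis=axis)
        hi = np.take(arr, x1, axis=axis)
        shape = [1] * arr.ndim
        shape[axis] = len(coords)
        w = w.reshape(shape)
        return lo * (1 - w) + hi * w

    return interp_axis(interp_axis(a, out_r, 0), out_c, 1)


def _catmull_rom_weights(frac: np.ndarray) -> np.ndarray:
    """Weights for samples at offsets (-1, 0, 1, 2), Catmull-Rom a = -0.5."""
    t = frac
    w = np.empty((4,) + t.shape)
    w[0] = -0.5 * t**3 + t**2 - 0.5 * t
    w[1] = 1.5 * t**3 - 2.5 * t**2 + 1.0
    w[2] = -1.5 * t**3 + 2.0 * t**2 + 0.5 * t
    w[3] = 0.5 * t**3 - 0.5 * t**2
    return w


def _resample_cubic(a: np.ndarray, factor: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)

    def interp_axis(arr, coords, axis):
        n = arr.shape[axis]
        base = np.floor(coords).astype(int)
        frac = coords - base
        w = _catmull_rom_weights(frac)  # (4, m)
        acc = 0.0
        for k in range(4):
            idx = np.clip(base + k - 1, 0, n - 1)
            shape = [1] * arr.ndim
            shape[axis] = len(coords)
            acc = acc + np.take(arr, idx, axis=axis) * w[k].reshape(shape)
        return acc

    out_r = _centre_coords(a.shape[0] // factor, factor)
    out_c = _centre_coords(a.shape[1] // factor, factor)
    out = interp_axis(interp_axis(a, out_r, 0), out_c, 1)
    return np.clip(out, a.min(), a.max())


def _resample_mode(a: np.ndarray, factor: int) -> np.ndarray:
    blocks = _blocks(a, factor)  # (R, C, f, f)
    flat = blocks.reshape(blocks.shape[0], blocks.shape[1], -1)
    codes = np.unique(a)
    counts = np.stack([(flat == c).sum(axis=-1) for c in codes])
    # ties -> smallest code (argmax takes the first maximum)
    return codes[np.argmax(counts, axis=0)]


def resample(
    a: np.ndarray,
    factor: int,
    method: str,
    categorical: bool = False,
) -> np.ndarray:
    """Downsample a 2-D raster by an integer factor with a named kernel."""
    if method not in RESAMPLE_METHODS:
        raise ValueError(
            f"unknown method {method!r}; choose from {RESAMPLE_METHODS}"
        )
    if categorical and method not in CATEGORICAL_OK:
        raise ValueError(
            f"method {method!r} is not suitable for categorical data; "
            f"use one of {CATEGORICAL_OK}"
        )
    a = np.asarray(a)
    if factor == 1:
        return a.copy()
    if a.shape[0] % factor or a.shape[1] % factor:
        raise ValueError(f"dimensions {a.shape} not divisible by factor {factor}")
    if method == "nearest":
        return _resample_nearest(a, factor)
    if method == "average":
        return aggregate_average(a, factor)
    if method == "mode":
        return _resample_mode(a, factor)
    if method == "bilinear":
        return _resample_bilinear(a, factor)
    return _resample_cubic(a, factor)


# ---------------------------------------------------------------------------
# scaling experiment
# ---------------------------------------------------------------------------

def run_scaling_experiment(
    *,
    strategy: str,
    factor: int,
    grid: GridSpec,
    methods: tuple[str, ...] = RESAMPLE_METHODS,
    label_map: np.ndarray | None = None,
    forest_t1: np.ndarray | None = None,
    forest_t2: np.ndarray | None = None,
    categorical: bool = False,
    definition: mapchange.ForestDefinition | None = None,
) -> pd.DataFrame:
    """Loss/gain areas per resampling method, at coarse scale, plus reference.

    ``change_then_scale`` (trajectory- and accumulation-style products that
    provide change at native resolution): the per-direction binary change
    map is resampled as a 0-1 fraction and accounted fractionally; nearest
    and mode stay binary by construction.

    ``scale_then_change`` (post-classification products): the two period
    forest maps are resampled first and change is extracted from the
    resampled maps — categorical maps via class comparison, numeric percent
    maps via the signed cover difference.  This mirrors how a resolution
    change would act on the source imagery.

    The returned table has one row per method plus a ``reference`` row with
    the original-resolution areas.
    """
    coarse_grid = grid.coarsen(factor)
    rows = []

    if strategy == "change_then_scale":
        if label_map is None:
            raise ValueError("change_then_scale needs label_map")
        ref = accounting.binary_change_area(label_map, grid)
        rows.append(("reference", ref["loss_km2"], ref["gain_km2"]))
        loss_b = (label_map == LABEL_LOSS).astype(float)
        gain_b = (label_map == LABEL_GAIN).astype(float)
        for m in methods:
            if categorical and m not in CATEGORICAL_OK:
                continue
            ls = resample(loss_b, factor, m)
            gs = resample(gain_b, factor, m)
            # resampled 0-1 fractions: account sub-pixel fractional area
            loss_km2 = float(np.clip(ls, 0, 1).sum() * coarse_grid.pixel_area_km2)
            gain_km2 = float(np.clip(gs, 0, 1).sum() * coarse_grid.pixel_area_km2)
            rows.append((m, loss_km2, gain_km2))
    elif strategy == "scale_then_change":
        if forest_t1 is None or forest_t2 is None:
            raise ValueError("scale_then_change needs forest_t1 and forest_t2")
        if categorical:
            if definition is None:
                raise ValueError("categorical scale_then_change needs a definition")
            ref_map = mapchange.categorical_change(forest_t1, forest_t2, definition)
            ref = accounting.binary_change_area(ref_map, grid)
        else:
            delta = mapchange.fractional_change(forest_t1, forest_t2)
            ref = accounting.fractional_change_area(delta, grid)
        rows.append(("reference", ref["loss_km2"], ref["gain_km2"]))
        for m in methods:
            if categorical and m not in CATEGORICAL_OK:
                continue
            t1s = resample(forest_t1, factor, m, categorical=categorical)
            t2s = resample(forest_t2, factor, m, categorical=categorical)
            if categorical:
                cmap = mapchange.categorical_change(t1s, t2s, definition)
                areas = accounting.binary_change_area(cmap, coarse_grid)
            else:
                delta = mapchange.fractional_change(t1s, t2s)
                areas = accounting.fractional_change_area(delta, coarse_grid)
            rows.append((m, areas["loss_km2"], areas["gain_km2"]))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    return pd.DataFrame(rows, columns=["method", "loss_area_km2", "gain_area_km2"])
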