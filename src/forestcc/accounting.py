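"""Area accounting and provincial aggregation.

Two accounting conventions coexist in the analysis, matching the two kinds
of change product:

* **binary**: every changed pixel contributes its whole pixel area
  (label-map products at the analysis resolution);
* **sub-pixel fractional**: a changed pixel contributes |delta| percent of
  its pixel area (percent-cover products, and fine binary products
  aggregated to percent-of-change).

On an equal-area grid both reduce to sums over pixels, so provincial tables
conserve mass exactly: national totals are the same summands regrouped.
National *coverage* expresses an area as a percent of total land area
(default 9.6 million km2, the conventional land area of China).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import GridSpec
from .trajfit import LABEL_GAIN, LABEL_LOSS

#: Conventional land area of China used for national coverage percentages.
CHINA_LAND_AREA_KM2 = 9.6e6

UNASSIGNED_ID = -1

PROVINCE_COLUMNS = [
    "province_id",
    "land_area_km2",
    "loss_km2",
    "gain_km2",
    "net_km2",
    "loss_pct",
    "gain_pct",
    "net_pct",
]


def binary_change_area(label_map: np.ndarray, grid: GridSpec) -> dict[str, float]:
    """Whole-pixel areas of loss and gain labels (km2)."""
    label_map = np.asarray(label_map)
    return {
        "loss_km2": float((label_map == LABEL_LOSS).sum() * grid.pixel_area_km2),
        "gain_km2": float((label_map == LABEL_GAIN).sum() * grid.pixel_area_km2),
    }


def fractional_change_area(delta: np.ndarray, grid: GridSpec) -> dict[str, float]:
    """Sub-pixel fractional areas from a signed percent-change map (km2).

    Loss is the sum of |delta|/100 x pixel area over negative-delta pixels;
    gain the analogue over positive deltas.  NaN pixels contribute nothing.
    """
    d = np.asarray(delta, dtype=float)
    neg = np.nansum(np.where(d < 0, -d, 0.0))
    pos = np.nansum(np.where(d > 0, d, 0.0))
    return {
        "loss_km2": float(neg / 100.0 * grid.pixel_area_km2),
        "gain_km2": float(pos / 100.0 * grid.pixel_area_km2),
    }


def coverage_percent(area_km2: float, land_area_km2: float = CHINA_LAND_AREA_KM2) -> float:
    """Area as a percent of total land area."""
    if land_area_km2 <= 0:
        raise ValueError("land_area_km2 must be positive")
    return 100.0 * area_km2 / land_area_km2


def provincial_aggregate(
    *,
    province_ids: np.ndarray,
    land_areas: pd.DataFrame,
    grid: GridSpec,
    label_map: np.ndarray | None = None,
    delta_map: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-province change areas and coverage percentages.

    Exactly one of ``label_map`` (binary accounting) or ``delta_map``
    (fractional accounting) must be given.  ``land_areas`` must have
    ``province_id`` and ``land_area_km2`` columns.  Pixels whose ID is
    absent from the table are gathered into an ``unassigned`` row (ID -1)
    rather than silently dropped.
    """
    if (label_map is None) == (delta_map is None):
        raise ValueError("give exactly one of label_map or delta_map")
    ids = np.asarray(province_ids)
    if ids.shape != grid.shape:
        raise ValueError("province raster does not match grid")

    known = set(int(p) for p in land_areas["province_id"])
    area_by_id = dict(
        zip(land_areas["province_id"].astype(int), land_areas["land_area_km2"])
    )

    flat_ids = ids.ravel()
    assigned = np.isin(flat_ids, sorted(known))
    eff_ids = np.where(assigned, flat_ids, UNASSIGNED_ID)

    if label_map is not None:
        lab = np.asarray(label_map).ravel()
        loss_w = (lab == LABEL_LOSS).astype(float) * grid.pixel_area_km2
        gain_w = (lab == LABEL_GAIN).astype(float) * grid.pixel_area_km2
    else:
        d = np.asarray(delta_map, dtype=float).ravel()
        d = np.where(np.isnan(d), 0.0, d)
        loss_w = np.where(d < 0, -d, 0.0) / 100.0 * grid.pixel_area_km2
        gain_w = np.where(d > 0, d, 0.0) / 100.0 * grid.pixel_area_km2

    out_ids = sorted(known)
    if (eff_ids == UNASSIGNED_ID).any():
        out_ids = out_ids + [UNASSIGNED_ID]

    rows = []
    for pid in out_ids:
        sel = eff_ids == pid
        loss = float(loss_w[sel].sum())
        gain = float(gain_w[sel].sum())
        if pid == UNASSIGNED_ID:
            land = float(sel.sum() * grid.pixel_area_km2)
        else:
            land = float(area_by_id[pid])
        rows.append(
            {
                "province_id": pid,
                "land_area_km2": land,
                "loss_km2": loss,
                "gain_km2": gain,
                "net_km2": gain - loss,
                "loss_pct": coverage_percent(loss, land) if land > 0 else np.nan,
                "gain_pct": coverage_percent(gain, land) if land > 0 else np.nan,
                "net_pct": coverage_percent(gain - loss, land) if land > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=PROVINCE_COLUMNS)


def national_totals(table: pd.DataFrame) -> dict[str, float]:
    """Sum the provincial rows back to national loss/gain/net areas."""
    return {
        "loss_km2": float(table["loss_km2"].sum()),
        "gain_km2": float(table["gain_km2"].sum()),
        "net_km2": float(table["net_km2"].sum()),
    }
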