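"""Non-trajectory change extraction: categorical, fractional and annual-loss.

Three alternative recipes for turning annual raster series into a single
change map:

* **categorical** (land-cover style): build per-period *stable* maps as the
  per-pixel modal class over a multi-year window, then compare the two
  stable maps under a forest definition (forest -> non-forest is loss, the
  reverse is gain);
* **fractional** (tree-cover style): difference of period-mean percent
  cover, a signed sub-pixel change;
* **annual-loss accumulation** (fine-resolution binary style): logical OR
  of per-year binary loss layers over the whole span.

A :class:`ForestDefinition` states the rule declaring a pixel forest — a
class set, a cover-percent threshold, or raw fractional cover — which is
the main lever of the baseline-area sensitivity experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AnnualCube
from .trajfit import LABEL_GAIN, LABEL_LOSS, LABEL_NONE

# IGBP class codes: 1-5 are the five forest classes (evergreen/deciduous
# needleleaf and broadleaf, mixed); 8 is woody savanna (30-60% canopy).
IGBP_FOREST = frozenset({1, 2, 3, 4, 5})
IGBP_WOODY_SAVANNA = 8


@dataclass(frozen=True)
class ForestDefinition:
    """The rule declaring a pixel forest.

    kind = "class_set":        forest iff the class code is in class_codes.
    kind = "cover_threshold":  forest iff percent cover >= threshold_pct.
    kind = "fractional":       no binarisation; cover itself is the quantity.
    """

    kind: str
    class_codes: frozenset[int] = frozenset()
    threshold_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"class_set", "cover_threshold", "fractional"}:
            raise ValueError(f"unknown forest definition kind {self.kind!r}")
        if self.kind == "class_set" and not self.class_codes:
            raise ValueError("class_set definition needs a non-empty class set")
        if self.kind == "cover_threshold" and not (0 < self.threshold_pct <= 100):
            raise ValueError("threshold_pct must be in (0, 100]")

    @classmethod
    def igbp5(cls) -> "ForestDefinition":
        return cls("class_set", class_codes=IGBP_FOREST)

    @classmethod
    def igbp5_plus_ws(cls) -> "ForestDefinition":
        return cls("class_set", class_codes=IGBP_FOREST | {IGBP_WOODY_SAVANNA})

    @classmethod
    def cover(cls, threshold_pct: float) -> "ForestDefinition":
        return cls("cover_threshold", threshold_pct=threshold_pct)

    def is_forest(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "class_set":
            return np.isin(values, sorted(self.class_codes))
        if self.kind == "cover_threshold":
            return np.asarray(values) >= self.threshold_pct
        raise ValueError("fractional definition does not binarise")


def stable_class_map(
    series: AnnualCube,
    window: tuple[int, int],
    tie_rule: str = "latest",
) -> np.ndarray:
    """Per-pixel modal class over a year window (a *stable* land-cover map).

    Suppresses spurious year-to-year label flicker before change extraction.
    Ties are broken by ``tie_rule``: "latest" (default) keeps the tied class
    observed latest in the window, "lowest" the smallest code.
    """
    y0, y1 = window
    years = [y for y in range(y0, y1 + 1)
             if series.grid.year_start <= y <= series.grid.year_end]
    if not years:
        raise ValueError(f"window {window} contains no year of the series")
    stack = np.stack([series.layer(y) for y in years])  # (w, rows, cols)
    w = stack.shape[0]
    out = np.empty(series.grid.shape, dtype=stack.dtype)
    codes = np.unique(stack)
    counts = np.stack([(stack == c).sum(axis=0) for c in codes])  # (k, r, c)
    if tie_rule == "lowest":
        best = np.argmax(counts, axis=0)  # first max = smallest code
    elif tie_rule == "latest":
        # index of each code's last occurrence in the window (-1 if absent)
        last_seen = np.stack(
            [np.where((stack == c).any(axis=0),
                      w - 1 - (stack[::-1] == c).argmax(axis=0), -1)
             for c in codes])
        # lexicographic: maximise count, then recency
        key = counts * (w + 1) + (last_seen + 1)
        best = np.argmax(key, axis=0)
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    out[...] = codes[best]
    return out


def categorical_change(
    map_t1: np.ndarray,
    map_t2: np.ndarray,
    definition: ForestDefinition,
) -> np.ndarray:
    """Post-classification change: forest -> non-forest is loss, reverse is gain."""
    f1 = definition.is_forest(map_t1)
    f2 = definition.is_forest(map_t2)
    out = np.full(np.shape(map_t1), LABEL_NONE, dtype=np.int16)
    out[f1 & ~f2] = LABEL_LOSS
    out[~f1 & f2] = LABEL_GAIN
    return out


def period_mean_cover(cube: AnnualCube, window: tuple[int, int]) -> np.ndarray:
    """Per-pixel mean percent cover over the window, skipping nodata years.

    Returns NaN where every year in the window is missing.
    """
    y0, y1 = window
    years = [y for y in range(y0, y1 + 1)
             if cube.grid.year_start <= y <= cube.grid.year_end]
    if not years:
        raise ValueError(f"window {window} contains no year of the cube")
    idx = [cube.year_index(y) for y in years]
    vals = cube.values[idx].astype(float)
    valid = cube.mask_valid()[idx]
    vals[~valid] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(vals, axis=0)


def fractional_change(mean_t1: np.ndarray, mean_t2: np.ndarray) -> np.ndarray:
    """Signed percent change in cover between two period means (t2 - t1)."""
    return np.asarray(mean_t2, dtype=float) - np.asarray(mean_t1, dtype=float)


def binarize_cover(percent_map: np.ndarray, definition: ForestDefinition) -> np.ndarray:
    """Forest/non-forest map from percent cover under a threshold definition."""
    if definition.kind != "cover_threshold":
        raise ValueError("binarize_cover needs a cover_threshold definition")
    return definition.is_forest(percent_map)


def accumulate_annual_loss(loss_layers: np.ndarray | AnnualCube) -> np.ndarray:
    """Whole-period binary loss: a pixel is loss if it lost in any year."""
    if isinstance(loss_layers, AnnualCube):
        layers = loss_layers.values
    else:
        layers = np.asarray(loss_layers)
    if layers.ndim != 3:
        raise ValueError("expected a (year, row, col) stack of binary layers")
    return (layers > 0).any(axis=0)


def fractional_to_labels(delta: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """Label map from signed fractional change: any non-zero delta counts.

    ``epsilon`` (percent) guards against float noise; the default treats any
    strictly non-zero change as change.
    """
    out = np.full(np.shape(delta), LABEL_NONE, dtype=np.int16)
    d = np.asarray(delta, dtype=float)
    out[d < -epsilon] = LABEL_LOSS
    out[d > epsilon] = LABEL_GAIN
    return out
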