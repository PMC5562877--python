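"""Synthetic landscape generator with known ground truth.

The generator builds a per-pixel *truth* — a fractional tree-cover trajectory
over the study years — and then renders the four "sensor" products used in
the analysis from that shared truth:

* an NBR-like annual spectral-index cube (affine in cover, Gaussian noise),
* an annual categorical land-cover series (forest / non-forest codes with
  label-flip noise emulating spurious interannual class flicker),
* an annual percent-tree-cover cube on a finer grid (VCF-like),
* fine-resolution annual binary loss layers plus one aggregated gain layer
  and a baseline cover layer (GFC-like),

together with a rectangular province partition.  Because every product is a
deterministic (seeded) function of the same truth, downstream detectors,
area accounting, agreement maps and correlations can all be tested against
exactly known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import AnnualCube, GridSpec, NODATA_INT

EVENT_KINDS = (
    "stable_forest",
    "stable_nonforest",
    "abrupt_loss",
    "gradual_gain",
    "loss_then_recovery",
)

FOREST_CODE = 1
NONFOREST_CODE = 10


@dataclass
class TruthScene:
    """Ground-truth cover trajectories for every pixel.

    ``kind`` holds the event-class index into :data:`EVENT_KINDS`;
    ``event_year``, ``magnitude`` and ``ramp_rate`` parameterise the event.
    ``cover(year)`` / ``cover_cube()`` evaluate the implied true cover
    fraction in [0, 1].
    """

    grid: GridSpec
    kind: np.ndarray          # (rows, cols) int index into EVENT_KINDS
    event_year: np.ndarray    # (rows, cols) int
    magnitude: np.ndarray     # (rows, cols) float, cover fraction lost/gained
    ramp_rate: np.ndarray     # (rows, cols) float, cover fraction per year
    base_cover: np.ndarray    # (rows, cols) float, cover before any event

    def kind_name(self) -> np.ndarray:
        return np.asarray(EVENT_KINDS, dtype=object)[self.kind]

    def cover(self, year: int) -> np.ndarray:
        """True cover fraction of every pixel in ``year``."""
        k = self.kind
        cov = self.base_cover.copy()

        after = year >= self.event_year

        is_loss = (k == EVENT_KINDS.index("abrupt_loss")) & after
        cov[is_loss] = self.base_cover[is_loss] - self.magnitude[is_loss]

        is_gain = k == EVENT_KINDS.index("gradual_gain")
        if is_gain.any():
            dt = np.maximum(year - self.event_year + 1, 0)
            ramp = np.minimum(self.ramp_rate * dt, self.magnitude)
            cov[is_gain] = self.base_cover[is_gain] + ramp[is_gain]

        is_lr = k == EVENT_KINDS.index("loss_then_recovery")
        if is_lr.any():
            dt = np.maximum(year - self.event_year, 0)
            recov = np.minimum(self.ramp_rate * dt, self.magnitude)
            dropped = self.base_cover - self.magnitude + recov
            cov[is_lr & after] = dropped[is_lr & after]

        return np.clip(cov, 0.0, 1.0)

    def cover_cube(self) -> np.ndarray:
        """(year, row, col) stack of true cover fractions."""
        return np.stack([self.cover(y) for y in self.grid.years])

    def to_table(self) -> pd.DataFrame:
        rows, cols = np.indices(self.grid.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "kind": self.kind_name().ravel(),
                "event_year": self.event_year.ravel(),
                "magnitude": self.magnitude.ravel(),
                "ramp_rate": self.ramp_rate.ravel(),
                "base_cover": self.base_cover.ravel(),
            }
        )


def make_truth(
    grid: GridSpec,
    mix: dict[str, float],
    seed: int,
    *,
    loss_magnitude: float = 0.8,
    gain_magnitude: float = 0.7,
    ramp_rate: float = 0.07,
    forest_base: float = 1.0,
    nonforest_base: float = 0.05,
    event_year: int | None = None,
) -> TruthScene:
    """Draw a random landscape whose pixels follow the given event mix.

    Event kinds are drawn i.i.d. per pixel with the probabilities in ``mix``
    (must sum to 1).  Event years are uniform on the interior of the study
    span — never at the endpoints, so a detector always has at least one
    observation on each side of the event.  ``event_year`` pins all events to
    one year (useful for exact-answer fixtures).
    """
    unknown = set(mix) - set(EVENT_KINDS)
    if unknown:
        raise ValueError(f"unknown event kinds in mix: {sorted(unknown)}")
    probs = np.array([mix.get(k, 0.0) for k in EVENT_KINDS], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mix proportions must sum to 1, got {probs.sum()!r}")
    if grid.n_pixels < 1:
        raise ValueError("grid has no pixels")
    if grid.n_years < 3:
        raise ValueError("need at least 3 years so events avoid the endpoints")

    rng = np.random.default_rng(seed)
    kind = rng.choice(len(EVENT_KINDS), size=grid.shape, p=probs)

    lo, hi = grid.year_start + 1, grid.year_end - 1
    if event_year is not None:
        if not (lo <= event_year <= hi):
            raise ValueError(f"event_year must lie in [{lo}, {hi}]")
        years = np.full(grid.shape, event_year, dtype=int)
    else:
        years = rng.integers(lo, hi + 1, size=grid.shape)

    magnitude = np.zeros(grid.shape)
    rate = np.zeros(grid.shape)
    base = np.full(grid.shape, nonforest_base)

    forest_start = (
        (kind == EVENT_KINDS.index("stable_forest"))
        | (kind == EVENT_KINDS.index("abrupt_loss"))
        | (kind == EVENT_KINDS.index("loss_then_recovery"))
    )
    base[forest_start] = forest_base

    losing = (kind == EVENT_KINDS.index("abrupt_loss")) | (
        kind == EVENT_KINDS.index("loss_then_recovery")
    )
    magnitude[losing] = loss_magnitude
    gaining = kind == EVENT_KINDS.index("gradual_gain")
    magnitude[gaining] = gain_magnitude
    rate[gaining | (kind == EVENT_KINDS.index("loss_then_recovery"))] = ramp_rate

    return TruthScene(
        grid=grid,
        kind=kind,
        event_year=years,
        magnitude=magnitude,
        ramp_rate=rate,
        base_cover=base,
    )


def render_nbr(
    truth: TruthScene,
    level_forest: float = 0.60,
    level_bare: float = 0.05,
    sigma: float = 0.0,
    seed: int = 0,
) -> AnnualCube:
    """Render an NBR-like index cube: affine in true cover plus Gaussian noise.

    ``NBR = level_bare + (level_forest - level_bare) * cover + N(0, sigma)``,
    clipped to the index's physical range [-1, 1].
    """
    if level_forest <= level_bare:
        raise ValueError("level_forest must exceed level_bare")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    cover = truth.cover_cube()
    vals = level_bare + (level_forest - level_bare) * cover
    if sigma > 0:
        vals = vals + rng.normal(0.0, sigma, size=vals.shape)
    return AnnualCube(truth.grid, np.clip(vals, -1.0, 1.0))


def render_lc(
    truth: TruthScene,
    cover_to_class_threshold: float = 0.6,
    flip_prob: float = 0.0,
    seed: int = 0,
) -> AnnualCube:
    """Render an annual forest/non-forest categorical series.

    A pixel-year is the forest code where true cover >= threshold (the 60%
    canopy-cover convention of the IGBP forest classes), else the non-forest
    code; each label is independently flipped with probability ``flip_prob``
    to emulate spurious interannual classification flicker.
    """
    if not (0.0 < cover_to_class_threshold < 1.0):
        raise ValueError("cover_to_class_threshold must be in (0, 1)")
    if not (0.0 <= flip_prob < 1.0):
        raise ValueError("flip_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cover = truth.cover_cube()
    labels = np.where(cover >= cover_to_class_threshold, FOREST_CODE, NONFOREST_CODE)
    if flip_prob > 0:
        flip = rng.random(labels.shape) < flip_prob
        flipped = np.where(labels == FOREST_CODE, NONFOREST_CODE, FOREST_CODE)
        labels = np.where(flip, flipped, labels)
    return AnnualCube(truth.grid, labels.astype(np.int16), nodata=NODATA_INT)


def render_vcf(
    truth: TruthScene,
    refine_factor: int = 2,
    sigma_pct: float = 0.0,
    seed: int = 0,
) -> AnnualCube:
    """Render a percent-tree-cover cube on a ``refine_factor`` x finer grid.

    Truth cover is replicated to the child pixels (the finer native product
    sees the same landscape), scaled to percent, plus Gaussian noise, clipped
    to [0, 100].
    """
    if refine_factor < 1:
        raise ValueError("refine_factor must be >= 1")
    if sigma_pct < 0:
        raise ValueError("sigma_pct must be non-negative")
    rng = np.random.default_rng(seed)
    cover = truth.cover_cube()
    fine = cover.repeat(refine_factor, axis=1).repeat(refine_factor, axis=2)
    vals = 100.0 * fine
    if sigma_pct > 0:
        vals = vals + rng.normal(0.0, sigma_pct, size=vals.shape)
    return AnnualCube(truth.grid.refine(refine_factor), np.clip(vals, 0.0, 100.0))


def render_gfc(
    truth: TruthScene,
    refine_factor: int = 16,
    forest_threshold: float = 0.5,
    seed: int = 0,
) -> dict[str, object]:
    """Render fine-resolution annual binary loss layers plus aggregated gain.

    A fine pixel is flagged *loss* in the year its parent's true cover first
    drops below ``forest_threshold``; the single *gain* layer flags fine
    pixels whose parent crossed the threshold upward at any point over the
    whole span (gain is only distributed aggregated over the period).
    ``baseline`` is first-year percent cover.

    Returns a dict with keys ``loss`` (AnnualCube of 0/1), ``gain`` (2-D 0/1
    array), ``baseline`` (2-D percent array) and ``grid`` (fine GridSpec).
    """
    if refine_factor < 1:
        raise ValueError("refine_factor must be >= 1")
    grid = truth.grid
    fine_grid = grid.refine(refine_factor)
    cover = truth.cover_cube()
    forest = cover >= forest_threshold

    n_years = grid.n_years
    loss = np.zeros((n_years, grid.rows, grid.cols), dtype=np.uint8)
    seen = np.zeros(grid.shape, dtype=bool)
    for t in range(1, n_years):
        newly_lost = forest[t - 1] & ~forest[t] & ~seen
        loss[t][newly_lost] = 1
        seen |= newly_lost

    gained = (~forest[0] & forest[-1]).astype(np.uint8)

    def _refine(a: np.ndarray) -> np.ndarray:
        return a.repeat(refine_factor, axis=-2).repeat(refine_factor, axis=-1)

    return {
        "loss": AnnualCube(fine_grid, _refine(loss), nodata=NODATA_INT),
        "gain": _refine(gained),
        "baseline": _refine(100.0 * cover[0]),
        "grid": fine_grid,
    }


def render_provinces(
    grid: GridSpec, k_rows: int, k_cols: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Partition the grid into a k_rows x k_cols block of "provinces".

    Returns the integer province-ID raster (IDs 0..k-1, row-major blocks)
    and a land-area table (block pixel count x pixel area).
    """
    if k_rows < 1 or k_cols < 1:
        raise ValueError("province partition factors must be >= 1")
    if grid.rows % k_rows or grid.cols % k_cols:
        raise ValueError("grid dimensions must be divisible by the partition")
    br, bc = grid.rows // k_rows, grid.cols // k_cols
    rows_idx = np.arange(grid.rows) // br
    cols_idx = np.arange(grid.cols) // bc
    ids = (rows_idx[:, None] * k_cols + cols_idx[None, :]).astype(np.int32)
    counts = np.bincount(ids.ravel(), minlength=k_rows * k_cols)
    table = pd.DataFrame(
        {
            "province_id": np.arange(k_rows * k_cols),
            "land_area_km2": counts * grid.pixel_area_km2,
        }
    )
    return ids, table
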