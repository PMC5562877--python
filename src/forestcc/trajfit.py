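"""Temporal segmentation of annual spectral-index trajectories.

A pixel's annual index series (e.g. NBR) is despiked, fitted with a small
number of connected linear segments, and classified as forest loss, gain or
no change from the fitted segment rises and drops.  The fitting model is a
continuous piecewise-linear least-squares fit with free vertex values at a
chosen set of vertex years: for fixed vertices the fit is a linear
regression on "hat" (tent) basis functions, and vertices are chosen by
greedy top-down splitting (add the vertex giving the largest residual
reduction) followed by a vertex-relocation refinement pass.

Classification: a segment is a change candidate when its fitted value drop
or rise is at least ``change_threshold``; the largest-magnitude candidate
decides the label.  A loss must start from forest (fitted start value at or
above ``forest_threshold``); a gain must end as forest.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .grid import AnnualCube, GridSpec, check_same_grid

LABEL_NONE = 0
LABEL_LOSS = 1
LABEL_GAIN = 2


@dataclass(frozen=True)
class DetectorParams:
    """User-facing knobs of the trajectory change detector.

    forest_threshold
        Index value separating forest from non-forest; gates loss (must
        start as forest) and gain (must end as forest) labels.
    change_threshold
        Minimum absolute fitted value change along a segment to count as a
        change candidate (index units).
    max_segments
        Upper bound on the number of linear segments in the fit.
    despike_threshold
        Fraction of the local range a point must deviate from its neighbour
        mean (while poking above or below both neighbours) to be treated as
        a one-year spike.
    mse_improvement_min
        Stop adding vertices when the relative SSE improvement falls below
        this fraction.
    """

    forest_threshold: float = 0.4
    change_threshold: float = 0.15
    max_segments: int = 4
    despike_threshold: float = 0.5
    mse_improvement_min: float = 0.01
    mask_filters_gain: bool = False

    def __post_init__(self) -> None:
        if self.change_threshold <= 0:
            raise ValueError("change_threshold must be positive")
        if self.max_segments < 1:
            raise ValueError("max_segments must be >= 1")


@dataclass
class SegmentFit:
    """A continuous piecewise-linear fit of one pixel's annual trajectory."""

    vertex_years: np.ndarray   # strictly increasing, endpoints included
    vertex_values: np.ndarray  # fitted index values at the vertices
    sse: float                 # residual sum of squares of the fit

    def __post_init__(self) -> None:
        self.vertex_years = np.asarray(self.vertex_years, dtype=float)
        self.vertex_values = np.asarray(self.vertex_values, dtype=float)
        if np.any(np.diff(self.vertex_years) <= 0):
            raise ValueError("vertex_years must be strictly increasing")
        if len(self.vertex_years) != len(self.vertex_values):
            raise ValueError("vertex_years and vertex_values lengths differ")

    @property
    def n_segments(self) -> int:
        return len(self.vertex_years) - 1

    @property
    def slopes(self) -> np.ndarray:
        """Index units per year, one per segment."""
        return np.diff(self.vertex_values) / np.diff(self.vertex_years)

    def predict(self, years: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(years, dtype=float),
                         self.vertex_years, self.vertex_values)


def despike(series: np.ndarray, despike_threshold: float = 0.5) -> np.ndarray:
    """Remove one-year spikes from an annual series.

    An interior point is a spike when it pokes above or below *both*
    neighbours, its deviation from their mean exceeds ``despike_threshold``
    times the local (3-point) range, and the neighbours roughly agree with
    each other (their difference stays below the same fraction of the local
    range) — a one-year excursion returns to its level, whereas at a real
    step edge the neighbours disagree and the point is preserved.  Spikes
    are replaced by the neighbour mean; a monotone step is never a spike.
    Endpoints are untouched; series shorter than 3 are returned unchanged.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 3:
        return s.copy()
    out = s.copy()
    left, mid, right = s[:-2], s[1:-1], s[2:]
    neigh_mean = 0.5 * (left + right)
    local_range = (np.maximum.reduce([left, mid, right])
                   - np.minimum.reduce([left, mid, right]))
    pokes = (mid - left) * (mid - right) > 0
    spike = (
        pokes
        & (np.abs(mid - neigh_mean) > despike_threshold * local_range)
        & (np.abs(left - right) < despike_threshold * local_range)
    )
    out[1:-1] = np.where(spike, neigh_mean, mid)
    return out


# ---------------------------------------------------------------------------
# continuous piecewise-linear least squares on hat bases
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _hat_operators(n: int, vertices: tuple[int, ...]):
    """Design matrix, projector and fitting operator for a vertex set.

    ``vertices`` are indices into the 0..n-1 time axis (endpoints included).
    Returns (Phi, coef_op) with ``values = coef_op @ y`` the least-squares
    vertex values and ``Phi @ values`` the fitted series.
    """
    t = np.arange(n, dtype=float)
    vx = np.asarray(vertices, dtype=float)
    k = len(vertices)
    phi = np.zeros((n, k))
    for j in range(k):
        left = vx[j - 1] if j > 0 else vx[j]
        right = vx[j + 1] if j < k - 1 else vx[j]
        up = np.zeros(n)
        if j > 0:
            seg = (t >= left) & (t <= vx[j])
            up[seg] = (t[seg] - left) / (vx[j] - left)
        else:
            up[t <= vx[j]] = 1.0
        down = np.zeros(n)
        if j < k - 1:
            seg = (t >= vx[j]) & (t <= right)
            down[seg] = (right - t[seg]) / (right - vx[j])
        else:
            down[t >= vx[j]] = 1.0
        phi[:, j] = np.where(t <= vx[j], up, down)
    coef_op = np.linalg.pinv(phi)
    return phi, coef_op


def _fit_for_vertices(y: np.ndarray, vertices: tuple[int, ...]):
    phi, coef_op = _hat_operators(len(y), vertices)
    coef = coef_op @ y
    resid = y - phi @ coef
    return coef, float(resid @ resid)


def fit_trajectory(
    series: np.ndarray,
    years: np.ndarray | None = None,
    max_segments: int = 4,
    mse_improvement_min: float = 0.01,
) -> SegmentFit:
    """Fit a continuous piecewise-linear model to an annual series.

    Vertices are added greedily: starting from the endpoints-only line, each
    step adds the interior year whose inclusion most reduces the residual
    sum of squares, stopping at ``max_segments`` segments or when the
    relative improvement drops below ``mse_improvement_min``.  A relocation
    pass then coordinate-descends each interior vertex to its best position,
    which recovers the optimum on noiseless piecewise-linear inputs.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("series must have at least 2 observations")
    if np.isnan(y).any():
        raise ValueError("series contains missing values; gap-fill first")
    if years is None:
        years = np.arange(n, dtype=float)
    else:
        years = np.asarray(years, dtype=float)
        if years.size != n:
            raise ValueError("years and series lengths differ")
    max_segments = min(max_segments, n - 1)

    vertices = [0, n - 1]
    coef, sse = _fit_for_vertices(y, tuple(vertices))

    while len(vertices) - 1 < max_segments:
        if sse <= 1e-24:
            break
        candidates = [i for i in range(1, n - 1) if i not in vertices]
        if not candidates:
            break
        best = None
        for c in candidates:
            vs = tuple(sorted(vertices + [c]))
            cf, s = _fit_for_vertices(y, vs)
            if best is None or s < best[0]:
                best = (s, vs, cf)
        new_sse, new_vs, new_cf = best
        improvement = (sse - new_sse) / sse if sse > 0 else 0.0
        if sse > 0 and improvement < mse_improvement_min:
            break
        vertices = list(new_vs)
        coef, sse = new_cf, new_sse
        if sse <= 1e-24:
            break

    vertices, coef, sse = _relocate_vertices(y, vertices, coef, sse)
    return SegmentFit(years[vertices], coef, sse)


def _relocate_vertices(y, vertices, coef, sse):
    """Refine greedy vertices by relocation and remove-and-reinsert moves.

    Relocation coordinate-descends each interior vertex within its
    neighbour span; remove-and-reinsert drops one interior vertex and
    re-adds the globally best one, which lets a vertex jump across its
    neighbours.  SSE strictly decreases, so the loop terminates.
    """
    n = y.size
    improved = True
    while improved and len(vertices) > 2:
        improved = False
        # relocation within neighbour spans
        for pos in range(1, len(vertices) - 1):
            lo, hi = vertices[pos - 1], vertices[pos + 1]
            best = (sse, vertices[pos], coef)
            for c in range(lo + 1, hi):
                if c == vertices[pos]:
                    continue
                vs = tuple(vertices[:pos] + [c] + vertices[pos + 1:])
                cf, s = _fit_for_vertices(y, vs)
                if s < best[0] - 1e-15:
                    best = (s, c, cf)
            if best[1] != vertices[pos]:
                sse, vertices[pos], coef = best
                improved = True
        # remove one vertex, reinsert the globally best replacement
        for pos in range(1, len(vertices) - 1):
            reduced = vertices[:pos] + vertices[pos + 1:]
            for c in range(1, n - 1):
                if c in reduced:
                    continue
                vs = tuple(sorted(reduced + [c]))
                cf, s = _fit_for_vertices(y, vs)
                if s < sse - 1e-15:
                    sse, vertices, coef = s, list(vs), cf
                    improved = True
                    break
            if improved:
                break
    return vertices, coef, sse


def fit_trajectory_exhaustive(
    series: np.ndarray,
    max_segments: int = 3,
) -> SegmentFit:
    """Globally optimal fit by enumerating every interior-vertex subset.

    Exponential in series length; intended as the desk-scale oracle the
    greedy fit is validated against (n <= ~16).
    """
    from itertools import combinations

    y = np.asarray(series, dtype=float)
    n = y.size
    max_segments = min(max_segments, n - 1)
    best = None
    interior = range(1, n - 1)
    for k in range(0, max_segments):
        for combo in combinations(interior, k):
            vs = (0, *combo, n - 1)
            cf, s = _fit_for_vertices(y, vs)
            if best is None or s < best[0] - 1e-15:
                best = (s, vs, cf)
    sse, vs, cf = best
    return SegmentFit(np.asarray(vs, dtype=float), cf, sse)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_trajectory(
    fit: SegmentFit, params: DetectorParams
) -> tuple[int, float | None, float]:
    """Label a fitted trajectory as loss, gain or none.

    Candidate segments are those whose |fitted value change| is at least
    ``change_threshold``.  The largest-magnitude candidate (earliest on
    ties) decides: a drop is loss only if the segment starts at or above
    ``forest_threshold`` (it was forest); a rise is gain only if it ends at
    or above ``forest_threshold`` (it became forest).  Returns
    ``(label, change_year, magnitude)``; year is the decisive segment's end
    for loss and start for gain, None when no change.
    """
    deltas = np.diff(fit.vertex_values)
    mags = np.abs(deltas)
    candidates = np.flatnonzero(mags >= params.change_threshold)
    if candidates.size == 0:
        return LABEL_NONE, None, 0.0
    # earliest wins on exact ties
    best = candidates[np.argmax(mags[candidates])]
    delta = deltas[best]
    magnitude = float(mags[best])
    if delta < 0:
        if fit.vertex_values[best] >= params.forest_threshold:
            return LABEL_LOSS, float(fit.vertex_years[best + 1]), magnitude
        return LABEL_NONE, None, 0.0
    if fit.vertex_values[best + 1] >= params.forest_threshold:
        return LABEL_GAIN, float(fit.vertex_years[best]), magnitude
    return LABEL_NONE, None, 0.0


# ---------------------------------------------------------------------------
# whole-cube detection
# ---------------------------------------------------------------------------

def fill_gaps(series: np.ndarray, valid: np.ndarray, max_gap: int = 2):
    """Linearly interpolate runs of <= ``max_gap`` missing interior years.

    Returns ``(filled, ok)``; ``ok`` is False when a gap is too long or an
    endpoint is missing, in which case the pixel is excluded from fitting.
    """
    s = np.asarray(series, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if valid.all():
        return s.copy(), True
    if not valid[0] or not valid[-1]:
        return s.copy(), False
    gaps = np.flatnonzero(~valid)
    # longest consecutive run of missing years
    run, longest = 1, 1
    for a, b in zip(gaps[:-1], gaps[1:]):
        run = run + 1 if b == a + 1 else 1
        longest = max(longest, run)
    if longest > max_gap:
        return s.copy(), False
    idx = np.arange(s.size)
    filled = s.copy()
    filled[~valid] = np.interp(idx[~valid], idx[valid], s[valid])
    return filled, True


def detect_changes(
    cube: AnnualCube,
    params: DetectorParams | None = None,
    mask: np.ndarray | None = None,
    max_gap: int = 2,
) -> dict[str, np.ndarray]:
    """Run despike -> fit -> classify on every pixel of an index cube.

    ``mask`` is the independent forest-domain raster: loss labels outside it
    are suppressed (a change signal in non-forest land cover is not forest
    loss).  Gain labels are kept regardless unless
    ``params.mask_filters_gain`` is set, since afforestation occurs on
    previously non-forest land.  Pixels with unfillable gaps are labelled
    none and flagged in the ``qa`` layer.

    Returns dict of 2-D arrays: ``label`` (0 none / 1 loss / 2 gain),
    ``year`` (NaN where none), ``magnitude``, ``qa`` (1 = excluded).
    """
    params = params or DetectorParams()
    grid = cube.grid
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match cube grid {grid.shape}"
            )

    label = np.zeros(grid.shape, dtype=np.int16)
    year = np.full(grid.shape, np.nan)
    magnitude = np.zeros(grid.shape)
    qa = np.zeros(grid.shape, dtype=np.uint8)

    valid = cube.mask_valid()
    years = grid.years.astype(float)
    vals = cube.values.astype(float)

    for r in range(grid.rows):
        for c in range(grid.cols):
            series, ok = fill_gaps(vals[:, r, c], valid[:, r, c], max_gap)
            if not ok:
                qa[r, c] = 1
                continue
            series = despike(series, params.despike_threshold)
            fit = fit_trajectory(
                series,
                years=years,
                max_segments=params.max_segments,
                mse_improvement_min=params.mse_improvement_min,
            )
            lab, yr, mag = classify_trajectory(fit, params)
            if mask is not None:
                if lab == LABEL_LOSS and not mask[r, c]:
                    lab, yr, mag = LABEL_NONE, None, 0.0
                if params.mask_filters_gain and lab == LABEL_GAIN and not mask[r, c]:
                    lab, yr, mag = LABEL_NONE, None, 0.0
            label[r, c] = lab
            magnitude[r, c] = mag
            if yr is not None:
                year[r, c] = yr

    return {"label": label, "year": year, "magnitude": magnitude, "qa": qa}
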