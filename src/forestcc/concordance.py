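"""Cross-dataset agreement maps and provincial correlation matrices.

Pixel level: the agreement level of a pixel is the count of datasets (0-4)
flagging it as changed in a given direction; levels 1-2 are "low"
agreement, 3-4 "high", and 4 alone "full".

Provincial level: pair-wise Pearson correlations between datasets'
provincial coverage percentages, plain or weighted by provincial forest
area, with a two-sided t-test significance flag at the 90% level.  The
weighted variant uses weighted means/covariance and takes its degrees of
freedom from the Kish effective sample size.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .trajfit import LABEL_GAIN, LABEL_LOSS

AGREEMENT_CATEGORIES = {"none": 0, "low": 1, "high": 2}


def to_binary_change(
    change_map: np.ndarray,
    direction: str,
    kind: str = "label",
    epsilon: float = 0.0,
) -> np.ndarray:
    """Boolean map of pixels changed in ``direction`` ("loss" or "gain").

    Label maps pass through; fractional (signed percent delta) maps flag any
    strictly non-zero delta of the requested sign.
    """
    if direction not in {"loss", "gain"}:
        raise ValueError("direction must be 'loss' or 'gain'")
    a = np.asarray(change_map)
    if kind == "label":
        target = LABEL_LOSS if direction == "loss" else LABEL_GAIN
        return a == target
    if kind == "fractional":
        d = a.astype(float)
        d = np.where(np.isnan(d), 0.0, d)
        return d < -epsilon if direction == "loss" else d > epsilon
    raise ValueError("kind must be 'label' or 'fractional'")


def agreement_count(binary_maps: list[np.ndarray]) -> dict[str, np.ndarray]:
    """Per-pixel count of datasets flagging change, with agreement banding.

    Returns ``level`` (integer 0..n) and ``category`` (0 none, 1 low = 1-2,
    2 high = 3-4); ``full`` marks unanimous pixels.
    """
    if not binary_maps:
        raise ValueError("need at least one binary map")
    stack = np.stack([np.asarray(m, dtype=bool) for m in binary_maps])
    n = stack.shape[0]
    level = stack.sum(axis=0).astype(np.int16)
    category = np.zeros_like(level)
    category[(level >= 1) & (level <= 2)] = AGREEMENT_CATEGORIES["low"]
    category[level >= 3] = AGREEMENT_CATEGORIES["high"]
    return {"level": level, "category": category, "full": level == n}


def agreement_composition(
    level: np.ndarray, binary_maps: dict[str, np.ndarray]
) -> pd.DataFrame:
    """For each dataset: percent of its flagged pixels at each agreement level.

    Rows are datasets; columns ``level_1..level_n`` sum to 100 for any
    dataset that flags at least one pixel.
    """
    level = np.asarray(level)
    n = len(binary_maps)
    rows = {}
    for name, m in binary_maps.items():
        m = np.asarray(m, dtype=bool)
        total = m.sum()
        comp = []
        for lv in range(1, n + 1):
            cnt = (m & (level == lv)).sum()
            comp.append(100.0 * cnt / total if total else np.nan)
        rows[name] = comp
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"level_{i}" for i in range(1, n + 1)]
    )


def pearson(x: np.ndarray, y: np.ndarray, alpha: float = 0.10):
    """Sample Pearson r with a two-sided t-test significance flag.

    The test statistic is t = r sqrt((n-2)/(1-r^2)) against Student-t with
    n-2 degrees of freedom; ``alpha`` = 0.10 is the 90% level.  Zero
    variance in either vector yields (nan, False).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), False
    res = stats.pearsonr(x, y)
    return float(res.statistic), bool(res.pvalue < alpha)


def weighted_pearson(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float = 0.10
):
    """Weighted Pearson r with significance from the Kish effective n.

    Weights (e.g. provincial forest areas) are normalised to sum 1;
    r_w is the weighted covariance over the weighted standard deviations.
    Degrees of freedom use n_eff = (sum w)^2 / sum w^2 computed on the raw
    weights, so the result is invariant to rescaling all weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.size == y.size == w.size):
        raise ValueError("x, y, w lengths differ")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    mx = float(wn @ x)
    my = float(wn @ y)
    cov = float(wn @ ((x - mx) * (y - my)))
    vx = float(wn @ ((x - mx) ** 2))
    vy = float(wn @ ((y - my) ** 2))
    if vx == 0 or vy == 0:
        return float("nan"), False
    r = cov / np.sqrt(vx * vy)
    n_eff = w.sum() ** 2 / (w**2).sum()
    df = n_eff - 2
    if df <= 0 or abs(r) >= 1:
        return float(r), bool(abs(r) >= 1 and df > 0)
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(r), bool(p < alpha)


def correlation_matrix(
    tables: dict[str, pd.DataFrame],
    metric: str = "net",
    weights: dict[str, np.ndarray] | np.ndarray | None = None,
    alpha: float = 0.10,
    net_only: set[str] = frozenset(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair-wise provincial correlation matrix across datasets.

    ``tables`` maps dataset name to a provincial table with ``province_id``
    and ``{metric}_pct`` columns; datasets in ``net_only`` (e.g. an
    inventory that reports only net change) are skipped unless
    ``metric == "net"``.  Provinces missing from either table, or with NaN
    coverage, are excluded pairwise.  Returns (r matrix, significance
    mask), both symmetric with unit/True diagonal.
    """
    col = f"{metric}_pct"
    names = [n for n in tables if metric == "net" or n not in net_only]
    r_mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    sig = pd.DataFrame(
        np.eye(len(names), dtype=bool), index=names, columns=names
    )
    series = {
        n: tables[n].set_index("province_id")[col].dropna() for n in names
    }
    if weights is not None and not isinstance(weights, dict):
        weights = {n: weights for n in names}
    for a, b in combinations(names, 2):
        common = series[a].index.intersection(series[b].index)
        xa = series[a].loc[common].to_numpy()
        xb = series[b].loc[common].to_numpy()
        if weights is None:
            r, s = pearson(xa, xb, alpha=alpha)
        else:
            wa = pd.Series(np.asarray(weights[a], dtype=float)).to_numpy()
            # weights are aligned with the full province list of table a
            w = (
                pd.Series(wa, index=tables[a]["province_id"])
                .loc[common]
                .to_numpy()
            )
            r, s = weighted_pearson(xa, xb, w, alpha=alpha)
        r_mat.loc[a, b] = r_mat.loc[b, a] = r
        sig.loc[a, b] = sig.loc[b, a] = s
    return r_mat, sig
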