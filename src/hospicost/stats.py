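"""Comparative analytics: median/IQR summaries, Kruskal–Wallis tests with
eta-squared effect sizes, Pearson cost–scale correlations, LOWESS smoothing,
and INR→USD presentation.

The Kruskal–Wallis H is the rank-based omnibus test for k independent groups
(tie-corrected, chi-square reference with k−1 df). Its effect size is

    eta² = (H − k + 1) / (n − k)

binned as small [0.01, 0.06), moderate [0.06, 0.14) and large ≥ 0.14; values
below 0.01 (including the negative values possible when H < k−1) are labelled
``below_small`` and reported as-is.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import DomainError
from .types import GroupComparison, GroupSummary, ScaleCorrelation

DEFAULT_USD_RATE = 76.21  # INR per USD, 2020


def median_iqr(values: Iterable[float]) -> dict[str, float]:
    """Median and quartiles (linear interpolation between order statistics)."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise DomainError("median_iqr requires at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> dict[str, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (k−1 df)."""
    if len(groups) < 2:
        raise DomainError("kruskal_wallis requires at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise DomainError("kruskal_wallis groups must be nonempty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.all(a == arrays[0][0]) for a in arrays):
        # scipy raises on all-identical data; the exchangeable identity is H=0.
        return {"H": 0.0, "p": 1.0}
    H, p = sps.kruskal(*arrays)
    return {"H": float(H), "p": float(p)}


_EFFECT_BINS = ((0.14, "large"), (0.06, "moderate"), (0.01, "small"))


def eta_squared(H: float, k: int, n: int) -> dict[str, object]:
    """Effect size eta² = (H − k + 1)/(n − k) with the printed label bins.

    Negative values (H below its null expectation k−1) are reported as-is
    and labelled below_small.
    """
    if n <= k:
        raise DomainError(f"eta_squared requires n > k, got n={n}, k={k}")
    eta2 = (H - k + 1) / (n - k)
    label = "below_small"
    for cut, name in _EFFECT_BINS:
        if eta2 >= cut:
            label = name
            break
    return {"eta2": float(eta2), "effect_label": label}


def pearson_r(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Product-moment correlation with two-sided t-based p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise DomainError("pearson_r requires equal-length inputs with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DomainError("pearson_r requires nonzero variance in both variables")
    res = sps.pearsonr(xa, ya)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": int(xa.size)}


def spearman_r(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Rank correlation, exposed as an option alongside the product-moment r."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise DomainError("spearman_r requires equal-length inputs with n >= 3")
    res = sps.spearmanr(xa, ya)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": int(xa.size)}


def lowess_curve(
    x: Sequence[float], y: Sequence[float], span: float = 2.0 / 3.0, iterations: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted scatterplot smoother (tricube weights, robustified).

    Returns the curve as (sorted unique x, fitted y). On exactly linear data
    the fit reproduces the line to numerical tolerance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 10:
        raise DomainError("lowess_curve requires n >= 10")
    if not 0 < span <= 1:
        raise DomainError(f"span must be in (0, 1], got {span}")
    if np.ptp(xa) == 0:
        raise DomainError("lowess_curve requires non-degenerate x")
    fitted = _sm_lowess(ya, xa, frac=span, it=iterations, return_sorted=True)
    cx, cy = fitted[:, 0], fitted[:, 1]
    keep = np.concatenate(([True], np.diff(cx) > 0))
    return cx[keep], cy[keep]


def inr_to_usd(inr: float, rate: float = DEFAULT_USD_RATE) -> float:
    """Convert 2020 INR to USD at the study exchange rate (default ₹76.21/$)."""
    if not np.isfinite(inr):
        raise DomainError("inr_to_usd requires finite input")
    if rate <= 0:
        raise DomainError("rate must be > 0")
    return inr / rate


def compare_groups(
    table: pd.DataFrame,
    grouping: str,
    outcome: str,
    min_group_size: int = 1,
) -> GroupComparison:
    """Median/IQR per group plus Kruskal–Wallis H, p and eta².

    Rows with undefined (non-finite) outcome values are filtered; groups left
    empty are dropped with a warning in the result (fewer than two remaining
    groups is a domain error).
    """
    if grouping not in table.columns or outcome not in table.columns:
        raise DomainError(f"columns {grouping!r}/{outcome!r} not in table")
    data = table[np.isfinite(table[outcome].astype(float))]
    names, groups = [], []
    for name, sub in data.groupby(grouping, sort=True):
        vals = sub[outcome].to_numpy(dtype=float)
        if vals.size >= max(1, min_group_size):
            names.append(str(name))
            groups.append(vals)
    if len(groups) < 2:
        raise DomainError("compare_groups requires >= 2 nonempty groups")
    kw = kruskal_wallis(groups)
    k = len(groups)
    n_total = int(sum(len(g) for g in groups))
    eff = eta_squared(kw["H"], k, n_total)
    summaries = tuple(
        GroupSummary(group=name, n=len(vals), **median_iqr(vals))
        for name, vals in zip(names, groups)
    )
    return GroupComparison(
        outcome=outcome,
        grouping=grouping,
        groups=summaries,
        H=kw["H"],
        p=kw["p"],
        k=k,
        n_total=n_total,
        eta2=eff["eta2"],
        effect_label=str(eff["effect_label"]),
    )


def pairwise_compare(
    table: pd.DataFrame, grouping: str, outcome: str
) -> dict[tuple[str, str], dict[str, float]]:
    """Two-group Kruskal–Wallis for every pair of groups (no multiplicity
    adjustment, matching the descriptive reporting style)."""
    data = table[np.isfinite(table[outcome].astype(float))]
    levels = sorted(data[grouping].astype(str).unique())
    out = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            ga = data.loc[data[grouping].astype(str) == a, outcome].to_numpy(dtype=float)
            gb = data.loc[data[grouping].astype(str) == b, outcome].to_numpy(dtype=float)
            out[(a, b)] = kruskal_wallis([ga, gb])
    return out


def scale_correlation(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str,
    y_name: str,
    span: float = 2.0 / 3.0,
) -> ScaleCorrelation:
    """Pearson r between a scale variable and a unit cost, with the LOWESS
    central-tendency curve for assessing nonlinearity."""
    pr = pearson_r(x, y)
    cx, cy = lowess_curve(x, y, span=span)
    return ScaleCorrelation(
        y=y_name,
        x=x_name,
        r=pr["r"],
        p=pr["p"],
        n=pr["n"],
        curve_x=tuple(float(v) for v in cx),
        curve_y=tuple(float(v) for v in cy),
        span=span,
    )
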