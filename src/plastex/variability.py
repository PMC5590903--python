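"""Per-gene variability statistics and nonparametric category
comparisons (coefficient of variation across a line panel, diversity
tables, Mann-Whitney U with exact small-sample enumeration)."""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from plastex.datatypes import PlastexError

EXACT_LIMIT = 10  # exact enumeration when n1 + n2 <= this


def gene_cv(panel: pd.DataFrame) -> pd.Series:
    """Coefficient of variation per gene across panel lines.

    Sample (n-1) standard deviation over the mean; genes with mean 0
    are returned missing.
    """
    if panel.shape[1] < 2:
        raise PlastexError("need at least 2 lines to compute a CV")
    values = panel.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.Series(cv, index=panel.index, name="cv")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x from midrank sums of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Enumerate all C(n1+n2, n1) group assignments of the pooled values
    and count arrangements at least as far from the null mean as
    observed (two-sided)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    n = pooled.size
    mid = n1 * (n - n1) / 2.0
    d_obs = abs(u_obs - mid)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for combo in combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mid) >= d_obs - 1e-12:
            count += 1
    return count / total


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for x) and two-sided p.

    Exact enumeration over rank arrangements when n1 + n2 <=
    ``EXACT_LIMIT``; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise PlastexError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all values identical across both samples",
                      stacklevel=2)
        return u, 1.0
    if x.size + y.size <= EXACT_LIMIT:
        return u, _exact_two_sided_p(x, y, u)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return u, float(min(1.0, res.pvalue))


def significance_code(p: float) -> str:
    """Starred code matching the figure convention: ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def compare_categories(
    stat: pd.Series,
    categories: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    statistic_name: str = "statistic",
) -> dict[str, pd.DataFrame]:
    """Category summaries and pairwise Mann-Whitney comparisons of a
    per-gene statistic.

    Missing statistic values are dropped; categories with fewer than 2
    genes skip their pairs with a warning. Returns ``{"summary": ...,
    "comparisons": ...}`` tables.
    """
    cat = categories.set_index(categories["gene_id"].astype(str))["category"]
    stat = stat.dropna()
    common = stat.index.intersection(cat.index)
    stat = stat.loc[common]
    cat = cat.loc[common]

    groups = {c: stat[cat == c].to_numpy() for c in sorted(cat.unique())}
    summary = pd.DataFrame(
        [
            {
                "category": c,
                "n": v.size,
                "median": float(np.median(v)) if v.size else np.nan,
                "iqr": float(np.subtract(*np.percentile(v, [75, 25])))
                if v.size
                else np.nan,
            }
            for c, v in groups.items()
        ],
        columns=["category", "n", "median", "iqr"],
    )

    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        va = groups.get(a, np.array([]))
        vb = groups.get(b, np.array([]))
        if va.size < 2 or vb.size < 2:
            warnings.warn(
                f"pair ({a}, {b}) skipped: a category has fewer than 2 "
                "genes",
                stacklevel=2,
            )
            continue
        u, p = mann_whitney_u(va, vb)
        rows.append(
            {
                "statistic": statistic_name,
                "category_a": a,
                "category_b": b,
                "n_a": va.size,
                "n_b": vb.size,
                "median_a": float(np.median(va)),
                "median_b": float(np.median(vb)),
                "u_statistic": u,
                "p_value": p,
                "code": significance_code(p),
            }
        )
    comparisons = pd.DataFrame(
        rows,
        columns=["statistic", "category_a", "category_b", "n_a", "n_b",
                 "median_a", "median_b", "u_statistic", "p_value", "code"],
    )
    return {"summary": summary, "comparisons": comparisons}
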