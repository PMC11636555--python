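"""Association battery: trend tests across preparedness levels and
Sidak-adjusted Spearman correlations with Fisher-z confidence intervals.

Binary outcomes are tested for a linear trend across the ordered levels with
the Cochran-Armitage test; continuous outcomes with a one-way ANOVA linear
contrast.  Correlations between the SCPI and numeric outcomes use Spearman's
rho with a Fisher-z interval (SE = 1/sqrt(n-3)); when a family of m related
comparisons is declared, the Sidak correction adjusts p-values as
1-(1-p)^m and widens each interval to the (1-alpha)^(1/m) per-comparison
confidence level so that family-wise coverage is 1-alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import LEVELS

__all__ = [
    "TrendTestResult",
    "CorrelationResult",
    "cochran_armitage_trend",
    "anova_linear_contrast",
    "fisher_z_ci",
    "spearman_ci",
    "sidak_adjust",
    "sidak_level",
    "tertile_summary",
]

#: Default ordinal scores for the (low, moderate, high) levels.  The trend
#: statistics are invariant to affine changes of these scores.
DEFAULT_GROUP_SCORES: tuple[float, ...] = (-1.0, 0.0, 1.0)


@dataclass(frozen=True)
class TrendTestResult:
    statistic: float
    p_value: float
    test_name: str
    group_scores: tuple[float, ...]
    df: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    level: float          # nominal family-wise confidence level
    level_per_comparison: float
    m: int                # family size used for the Sidak adjustment
    p_value: float = np.nan
    p_adjusted: float = np.nan
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not (
            -1.0 <= self.ci_low <= self.r <= self.ci_high <= 1.0
        ):
            raise ValueError("confidence interval must satisfy -1 <= lo <= r <= hi <= 1")


def cochran_armitage_trend(
    events: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
) -> TrendTestResult:
    """Cochran-Armitage test for trend in proportions across ordered groups.

    ``events[i]`` of ``totals[i]`` subjects in group i (with ordinal score
    ``scores[i]``) show the binary outcome.  The z statistic is

        z = sum_i s_i (x_i - n_i pbar) /
            sqrt( pbar qbar (sum n_i s_i^2 - (sum n_i s_i)^2 / N) )

    with a two-sided p-value from the standard normal reference.
    """
    x = np.asarray(events, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("events and totals must be 1-d sequences of equal length >= 2")
    if (x < 0).any() or (n < 0).any() or (x > n).any():
        raise ValueError("need 0 <= events <= totals in every group")
    if not (np.allclose(x, np.round(x)) and np.allclose(n, np.round(n))):
        raise ValueError("counts must be integers")
    s = np.asarray(scores if scores is not None else range(len(x)), dtype=float)
    if s.shape != x.shape:
        raise ValueError("scores must match the number of groups")

    N = n.sum()
    if N == 0:
        raise ValueError("empty table")
    pbar = x.sum() / N
    name = "cochran-armitage"
    if pbar in (0.0, 1.0) or (n > 0).sum() < 2:
        return TrendTestResult(0.0, 1.0, name, tuple(s), degenerate=True)
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        return TrendTestResult(0.0, 1.0, name, tuple(s), degenerate=True)
    z = float(np.sum(s * (x - n * pbar)) / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return TrendTestResult(z, p, name, tuple(s))


def anova_linear_contrast(
    groups: Sequence[np.ndarray],
    contrast: Sequence[float] | None = None,
) -> TrendTestResult:
    """Linear-contrast t test across ordered groups in a one-way ANOVA.

    t = sum_j c_j ybar_j / sqrt(MSE * sum_j c_j^2 / n_j) on N - k degrees of
    freedom, where MSE is the pooled within-group mean square.  The default
    contrast (-1, 0, +1) tests a linear trend over three ordered levels.
    """
    ys = [np.asarray(g, dtype=float) for g in groups]
    ys = [y[~np.isnan(y)] for y in ys]
    k = len(ys)
    if k < 2 or any(len(y) == 0 for y in ys):
        raise ValueError("need at least two non-empty groups")
    c = np.asarray(
        contrast if contrast is not None else DEFAULT_GROUP_SCORES[:k], dtype=float
    )
    if len(c) != k:
        raise ValueError("contrast length must equal the number of groups")
    nj = np.array([len(y) for y in ys], dtype=float)
    N = nj.sum()
    df = N - k
    name = "anova-linear-contrast"
    if df <= 0:
        return TrendTestResult(0.0, 1.0, name, tuple(c), df=max(df, 0.0), degenerate=True)
    means = np.array([y.mean() for y in ys])
    sse = sum(((y - y.mean()) ** 2).sum() for y in ys)
    mse = sse / df
    if mse <= 0:
        return TrendTestResult(0.0, 1.0, name, tuple(c), df=df, degenerate=True)
    t = float(np.dot(c, means) / np.sqrt(mse * np.sum(c**2 / nj)))
    p = float(2 * stats.t.sf(abs(t), df))
    return TrendTestResult(t, p, name, tuple(c), df=df)


def sidak_level(alpha: float, m: int) -> float:
    """Per-comparison confidence level giving family coverage 1 - alpha."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return (1.0 - alpha) ** (1.0 / m)


def sidak_adjust(p_values: Sequence[float] | float, m: int | None = None):
    """Sidak-adjusted p-values: 1 - (1-p)^m, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    fam = m if m is not None else p.size
    if fam < 1:
        raise ValueError("family size m must be >= 1")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = 1.0 - (1.0 - p) ** fam
    adj = np.minimum(adj, 1.0)
    return float(adj) if np.isscalar(p_values) else adj


def fisher_z_ci(r: float, n: int, level: float = 0.95, m: int = 1) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    ``z = atanh(r)`` with standard error ``1/sqrt(n-3)``, back-transformed;
    with a family of m comparisons the interval is computed at the Sidak
    per-comparison level."""
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    lvl = sidak_level(1.0 - level, m)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + lvl / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def spearman_ci(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    m: int = 1,
) -> CorrelationResult:
    """Spearman correlation with a Fisher-z confidence interval.

    Mid-ranks handle ties.  The interval uses SE = 1/sqrt(n-3) on the
    z = atanh(r) scale; with a declared family of m comparisons the interval
    is computed at the Sidak per-comparison level and the p-value adjusted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    lvl_pc = sidak_level(1.0 - level, m)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            np.nan, n, np.nan, np.nan, level, lvl_pc, m, undefined=True
        )
    r, p = stats.spearmanr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        lo, hi = (r, r)
    else:
        lo, hi = fisher_z_ci(r, n, level, m)
    return CorrelationResult(
        r, n, lo, hi, level, lvl_pc, m,
        p_value=float(p), p_adjusted=sidak_adjust(float(p), m),
    )


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def tertile_summary(
    scored: pd.DataFrame,
    outcomes: Sequence[str] | Mapping[str, str],
    level_col: str = "scpi_level",
    group_scores: Sequence[float] = DEFAULT_GROUP_SCORES,
) -> pd.DataFrame:
    """Per-level descriptive statistics plus trend p-values, one row per outcome.

    ``outcomes`` is a list of column names, or a mapping name -> 'binary' /
    'continuous' to override the automatic dispatch (binary columns go to
    Cochran-Armitage, continuous ones to the ANOVA linear contrast).
    """
    if level_col not in scored.columns:
        raise ValueError(f"missing level column {level_col!r}")
    if isinstance(outcomes, Mapping):
        typing_map = dict(outcomes)
    else:
        typing_map = {}
        for name in outcomes:
            if name not in scored.columns:
                raise ValueError(f"unknown outcome column {name!r}")
            typing_map[name] = "binary" if _is_binary(scored[name]) else "continuous"

    present_levels = [lv for lv in LEVELS if (scored[level_col] == lv).any()]
    rows = []
    for name, kind in typing_map.items():
        if name not in scored.columns:
            raise ValueError(f"unknown outcome column {name!r}")
        if kind not in ("binary", "continuous"):
            raise ValueError(f"outcome {name!r}: type must be binary or continuous")
        row: dict[str, object] = {"outcome": name, "type": kind}
        groups = [
            scored.loc[scored[level_col] == lv, name].dropna().to_numpy(dtype=float)
            for lv in LEVELS
        ]
        for lv, g in zip(LEVELS, groups):
            row[f"n_{lv}"] = len(g)
            if kind == "binary":
                row[f"stat_{lv}"] = g.sum() if len(g) else np.nan
                row[f"pct_{lv}"] = 100.0 * g.mean() if len(g) else np.nan
            else:
                row[f"mean_{lv}"] = g.mean() if len(g) else np.nan
                row[f"sd_{lv}"] = g.std(ddof=1) if len(g) > 1 else np.nan
        use = [i for i, lv in enumerate(LEVELS) if lv in present_levels and len(groups[i])]
        s = np.asarray(group_scores, dtype=float)[use]
        if len(use) < 2:
            row.update(trend_stat=np.nan, trend_p=np.nan, trend_test="degenerate",
                       degenerate=True)
        elif kind == "binary":
            res = cochran_armitage_trend(
                [groups[i].sum() for i in use], [len(groups[i]) for i in use], s
            )
            row.update(trend_stat=res.statistic, trend_p=res.p_value,
                       trend_test=res.test_name, degenerate=res.degenerate)
        else:
            res = anova_linear_contrast([groups[i] for i in use], s - s.mean())
            row.update(trend_stat=res.statistic, trend_p=res.p_value,
                       trend_test=res.test_name, degenerate=res.degenerate)
        rows.append(row)
    return pd.DataFrame(rows)
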