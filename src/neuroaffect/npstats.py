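"""Nonparametric test battery and percentile-bootstrap engine.

Small-sample, non-Gaussian data motivates this battery: a Shapiro-Wilk
normality gate routes analyses to Mann-Whitney U, Kruskal-Wallis H and
Spearman's rho; Cliff's delta supplies an ordinal effect size; percentile
bootstrap (case resampling, 1,000 resamples by default) supplies confidence
intervals for arbitrary statistics, including regression coefficients.

Standard tests are delegated to scipy; Cliff's delta and the bootstrap
engine are implemented here (the fast Cliff's delta path is checked against
its O(n^2) definition in the test suite).  Tie handling is midrank
throughout.  No multiple-testing correction is applied; callers receive raw
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .exceptions import EstimationError, InputError

__all__ = [
    "TestResult",
    "BootstrapResult",
    "shapiro_wilk_gate",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman_rho",
    "cliffs_delta",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_per_group: Tuple[int, ...]
    effect_size: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_resamples: int
    seed: int
    method: str = "percentile"
    n_failures: int = 0


def _clean(x, name: str = "sample") -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise InputError(f"{name} is empty")
    if not np.all(np.isfinite(x)):
        raise InputError(f"{name} contains non-finite values")
    return x


def shapiro_wilk_gate(x) -> Tuple[TestResult, bool]:
    """Shapiro-Wilk test with a normality flag (p >= 0.05).

    A False flag routes the pipeline to the nonparametric battery.
    """
    x = _clean(x)
    if not 3 <= x.size <= 5000:
        raise InputError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    stat, p = spstats.shapiro(x)
    result = TestResult(method="shapiro_wilk", statistic=float(stat),
                        p_value=float(p), n_per_group=(x.size,))
    return result, bool(p >= 0.05)


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U with midrank ties.

    Reports U = min(Ux, Uy).  The p-value is exact (full null distribution)
    when nx*ny <= 400 and the pooled sample is tie-free; otherwise the
    normal approximation with tie and continuity corrections is used.
    Cliff's delta is attached as the effect size.
    """
    x, y = _clean(x, "x"), _clean(y, "y")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = spstats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                               use_continuity=True)
    u_x = float(res.statistic)
    u_min = min(u_x, x.size * y.size - u_x)
    return TestResult(method="mann_whitney_u", statistic=u_min,
                      p_value=float(min(res.pvalue, 1.0)),
                      n_per_group=(x.size, y.size),
                      effect_size=cliffs_delta(x, y).effect_size)


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p with k-1 df."""
    if len(groups) < 2:
        raise InputError(f"need at least 2 groups, got {len(groups)}")
    cleaned = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if sum(g.size for g in cleaned) < 3:
        raise InputError("total sample size must be >= 3")
    stat, p = spstats.kruskal(*cleaned)
    return TestResult(method="kruskal_wallis", statistic=float(stat),
                      p_value=float(p),
                      n_per_group=tuple(g.size for g in cleaned))


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation (Pearson on midranks); t-approximation p."""
    x, y = _clean(x, "x"), _clean(y, "y")
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InputError(f"need paired length >= 3, got {x.size}")
    res = spstats.spearmanr(x, y)
    return TestResult(method="spearman", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n_per_group=(x.size,),
                      effect_size=float(res.statistic))


def cliffs_delta_brute(x, y) -> float:
    """O(n^2) definition of Cliff's delta; reference implementation."""
    x, y = _clean(x, "x"), _clean(y, "y")
    wins = sum(1 for xi in x for yj in y if xi > yj)
    losses = sum(1 for xi in x for yj in y if xi < yj)
    return (wins - losses) / (x.size * y.size)


def cliffs_delta(x, y) -> TestResult:
    """Cliff's delta ordinal dominance statistic in [-1, 1].

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (nx * ny), computed in
    O((nx+ny) log ny) via a sorted merge.
    """
    x, y = _clean(x, "x"), _clean(y, "y")
    ys = np.sort(y)
    wins = np.searchsorted(ys, x, side="left").sum()
    losses = (y.size - np.searchsorted(ys, x, side="right")).sum()
    delta = float(wins - losses) / (x.size * y.size)
    return TestResult(method="cliffs_delta", statistic=delta, p_value=1.0,
                      n_per_group=(x.size, y.size), effect_size=delta)


def bootstrap_ci(data: Union[np.ndarray, pd.DataFrame, Sequence[float]],
                 statistic: Callable, n_resamples: int = 1000,
                 level: float = 0.95, seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap CI by case (row) resampling with replacement.

    ``statistic`` maps a resampled dataset (same type as ``data``) to a
    scalar.  The point estimate is the statistic on the original data; the
    interval is the empirical (alpha/2, 1 - alpha/2) quantile pair of the
    resample distribution.  Statistic failures on individual resamples are
    counted and tolerated up to 1% of ``n_resamples``.
    """
    if n_resamples < 1:
        raise InputError("n_resamples must be >= 1")
    if not 0.0 < level < 1.0:
        raise InputError(f"level must be in (0, 1), got {level}")
    is_frame = isinstance(data, pd.DataFrame)
    if not is_frame:
        data = _clean(data, "data")
    n = len(data)
    if n == 0:
        raise InputError("data is empty")

    estimate = float(statistic(data))
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        resample = data.iloc[idx].reset_index(drop=True) if is_frame else data[idx]
        try:
            values.append(float(statistic(resample)))
        except Exception:
            failures += 1
    if failures > 0.01 * n_resamples:
        raise EstimationError(
            f"statistic failed on {failures}/{n_resamples} resamples (> 1%)")
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(estimate=estimate, ci_low=float(lo),
                           ci_high=float(hi), level=level,
                           n_resamples=n_resamples, seed=seed,
                           n_failures=failures)
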