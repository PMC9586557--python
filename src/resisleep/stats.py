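"""Statistical machinery for the analysis battery.

Holm-Sidak step-down adjustment maintains the family-wise error rate at
alpha across post-hoc comparisons; repeated-measures ANOVA delegates to
statsmodels (routine statistics, deliberately not reimplemented); the
sample-size calculation uses the two-sample normal approximation

    n = ceil( (z_{1-alpha/2} + z_{1-beta})^2 * 2 sigma^2 / delta^2 )

which, for sigma = 14.6 min and delta = 25 min at alpha = 0.05 and power
0.8, gives n = 6 per group. A noncentral-t iteration (which returns 7 for
the same inputs) is available via ``method="t"``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats


@dataclass
class ComparisonResult:
    statistic: float
    df: float | tuple
    p_value: float
    method: str
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if self.adjusted_p is not None:
            assert self.adjusted_p >= self.p_value - 1e-12


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    For ascending p_(1) <= ... <= p_(m), the adjusted value at rank k is
    ``max_{j<=k} 1 - (1 - p_(j))^(m - j + 1)``, capped at 1; adjusted
    values are monotone nondecreasing in rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def paired_t(x, y) -> ComparisonResult:
    """Student's paired t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired t requires matched lengths")
    if x.size < 2:
        raise ValueError("paired t requires n >= 2")
    res = spstats.ttest_rel(x, y)
    return ComparisonResult(statistic=float(res.statistic), df=float(x.size - 1),
                            p_value=float(res.pvalue), method="paired_t")


def independent_t(x, y) -> ComparisonResult:
    """Student's two-sample t-test (equal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("t-test requires n >= 2 per group")
    res = spstats.ttest_ind(x, y)
    return ComparisonResult(statistic=float(res.statistic),
                            df=float(x.size + y.size - 2),
                            p_value=float(res.pvalue), method="independent_t")


def oneway_anova(*groups) -> ComparisonResult:
    """One-way between-groups ANOVA."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    res = spstats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return ComparisonResult(statistic=float(res.statistic), df=(k - 1, n - k),
                            p_value=float(res.pvalue), method="oneway_anova")


def rm_anova(table: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> pd.DataFrame:
    """Repeated-measures ANOVA on a long-format table.

    Thin contract over statsmodels' AnovaRM (balanced designs). Returns
    the ANOVA table with F, num/den df and p per within factor.
    """
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(table, depvar=dv, subject=subject, within=within).fit()
    return res.anova_table


def sample_size_normal_approx(sd: float, mean_diff: float, alpha: float = 0.05,
                              power: float = 0.8, two_sided: bool = True,
                              method: str = "normal") -> int:
    """Per-group n for a two-sample comparison of means.

    ``method="normal"`` uses the closed-form normal approximation above;
    ``method="t"`` iterates with the noncentral t (slightly larger n).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if mean_diff == 0:
        raise ValueError("mean_diff must be nonzero")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_a = spstats.norm.ppf(1 - alpha / 2 if two_sided else 1 - alpha)
    z_b = spstats.norm.ppf(power)
    n = (z_a + z_b) ** 2 * 2.0 * sd ** 2 / mean_diff ** 2
    n_normal = int(math.ceil(n - 1e-9))
    if method == "normal":
        return n_normal
    if method != "t":
        raise ValueError("method must be 'normal' or 't'")
    from statsmodels.stats.power import TTestIndPower

    solved = TTestIndPower().solve_power(
        effect_size=abs(mean_diff) / sd, alpha=alpha, power=power,
        alternative="two-sided" if two_sided else "larger")
    return int(math.ceil(solved - 1e-9))
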