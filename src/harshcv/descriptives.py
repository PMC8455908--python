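"""Between-country descriptive comparisons and the design power check.

Continuous characteristics are compared across countries with one-way ANOVA
and the eta-squared effect size (between-group SS / total SS); categorical
characteristics with a chi-square test of independence and Cramer's V.
``power_pearson_r`` reproduces the design power computation for detecting a
population correlation with a two-sided test, via the Fisher z
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "ChiSquareResult",
    "eta_squared",
    "cramers_v",
    "power_pearson_r",
    "summarize_countries",
]


@dataclass(frozen=True)
class AnovaResult:
    eta_squared: float
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class ChiSquareResult:
    cramers_v: float
    chi2: float
    p_value: float
    dof: int
    n: int


def eta_squared(values: Sequence[float],
                groups: Sequence) -> AnovaResult:
    """One-way ANOVA with the eta-squared effect size.

    eta^2 = SS_between / SS_total, the proportion of outcome variance
    attributable to group membership.

    Raises ``ValueError`` for fewer than two groups, groups with fewer than
    two observations, or zero total variance.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.size != g.size:
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(g)
    samples = [y[g == lab] for lab in labels]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >=2 groups each with >=2 values")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total <= 0:
        raise ValueError("zero total variance; eta-squared undefined")
    ss_between = float(sum(s.size * (s.mean() - grand) ** 2 for s in samples))
    ss_within = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
    if ss_within == 0:  # groups are distinct constants
        f, p = np.inf, 0.0
    else:
        f, p = stats.f_oneway(*samples)
    return AnovaResult(eta_squared=ss_between / (ss_between + ss_within),
                       f_statistic=float(f), p_value=float(p),
                       df_between=len(samples) - 1,
                       df_within=y.size - len(samples))


def cramers_v(table: np.ndarray | Sequence[Sequence[int]]) -> ChiSquareResult:
    """Chi-square test of independence with Cramer's V.

    V = sqrt(chi2 / (N * (min(r, c) - 1))).  Rows or columns with a zero
    marginal are dropped with a warning before computation (they contribute
    no information and make expected counts degenerate).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D non-negative count matrix")
    if t.sum() <= 0:
        raise ValueError("contingency table has zero grand total")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not (row_ok.all() and col_ok.all()):
        warnings.warn("dropping zero-marginal rows/columns from "
                      "contingency table", UserWarning, stacklevel=2)
        t = t[np.ix_(row_ok, col_ok)]
    r, c = t.shape
    if min(r, c) < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    n = t.sum()
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return ChiSquareResult(cramers_v=v, chi2=float(chi2), p_value=float(p),
                           dof=int(dof), n=int(n))


def power_pearson_r(n: int, r: float, alpha: float = 0.05) -> float:
    """Power of the two-sided test of rho = 0 for a Pearson correlation.

    Uses the Fisher z approximation: z(r) = atanh(r) is approximately normal
    with SD 1/sqrt(n - 3), so power is
    Phi(|z(r)|*sqrt(n-3) - z_{1-a/2}) + Phi(-|z(r)|*sqrt(n-3) - z_{1-a/2}).
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    shift = abs(np.arctanh(r)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(shift - za) + stats.norm.cdf(-shift - za))


def summarize_countries(datasets: Mapping[str, pd.DataFrame],
                        continuous: Sequence[str] = (),
                        categorical: Sequence[str] = ()) -> pd.DataFrame:
    """Table-1-style between-country summary.

    For each continuous variable: per-country mean (SD), ANOVA p, eta^2.
    For each categorical variable: chi-square p and Cramer's V over the
    country x level contingency table.
    """
    names = list(datasets)
    rows = []
    for var in continuous:
        vals = np.concatenate([datasets[c][var].dropna().to_numpy()
                               for c in names])
        grp = np.concatenate([[c] * datasets[c][var].dropna().size
                              for c in names])
        res = eta_squared(vals, grp)
        row = {"characteristic": var, "test": "anova",
               "statistic": res.f_statistic, "p_value": res.p_value,
               "effect_size": res.eta_squared}
        for c in names:
            s = datasets[c][var].dropna()
            row[c] = f"{s.mean():.2f} ({s.std(ddof=1):.2f})"
        rows.append(row)
    for var in categorical:
        levels = sorted(set().union(*[datasets[c][var].dropna().unique()
                                      for c in names]))
        table = np.array([[int((datasets[c][var] == lev).sum())
                           for lev in levels] for c in names])
        res = cramers_v(table)
        row = {"characteristic": var, "test": "chi-square",
               "statistic": res.chi2, "p_value": res.p_value,
               "effect_size": res.cramers_v}
        for c in names:
            counts = datasets[c][var].value_counts()
            row[c] = "; ".join(f"{lev}: {counts.get(lev, 0)}"
                               for lev in levels)
        rows.append(row)
    return pd.DataFrame(rows)
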