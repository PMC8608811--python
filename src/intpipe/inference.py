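"""ROI-level statistics.

Welch two-sample t tests (from raw vectors or printed summary statistics),
Hedges g with the small-sample correction, Bonferroni adjustment, Pearson
correlations, additive-model main effects (Type II sums of squares) and
2x2 chi-squared tests with Yates continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "welch_t",
    "hedges_g",
    "bonferroni",
    "pearson_r",
    "linear_main_effects",
    "chi2_2x2",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample (ddof=1) standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class ComparisonResult:
    """One ROI contrast: Welch t, Satterthwaite df, raw/Bonferroni p, Hedges g."""

    t: float
    df: float
    p: float
    p_bonf: float
    g: float


def _as_summary(x: GroupSummary | Sequence[float]) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    return GroupSummary.from_values(x)


def welch_t(
    a: GroupSummary | Sequence[float], b: GroupSummary | Sequence[float]
) -> tuple[float, float, float]:
    """Welch two-sample t test; returns ``(t, df, p_two_sided)``.

    ``t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b)`` with
    Welch-Satterthwaite degrees of freedom.  Raw vectors are reduced to their
    :class:`GroupSummary` first, so both input forms agree exactly.
    """
    a, b = _as_summary(a), _as_summary(b)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        raise ValueError("both groups have zero variance; t test degenerate")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def hedges_g(
    a: GroupSummary | Sequence[float], b: GroupSummary | Sequence[float]
) -> float:
    """Hedges g: pooled-SD standardized mean difference, small-sample corrected.

    ``g = J * (mean_a - mean_b) / s_pooled`` with
    ``s_pooled = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a+n_b-2))`` and
    ``J = 1 - 3 / (4 (n_a+n_b-2) - 1)``.
    """
    a, b = _as_summary(a), _as_summary(b)
    df = a.n + b.n - 2
    pooled = np.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df)
    if pooled == 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(correction * (a.mean - b.mean) / pooled)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: ``min(1, m * p)``."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return min(1.0, m * p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need >= 3 pairs, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    a: Sequence[float], b: Sequence[float], m: int = 1
) -> ComparisonResult:
    """Welch t, Hedges g and Bonferroni correction for one ROI contrast."""
    t, df, p = welch_t(a, b)
    return ComparisonResult(t=t, df=df, p=p, p_bonf=bonferroni(p, m), g=hedges_g(a, b))


def linear_main_effects(
    y: Sequence[float],
    factors: Mapping[str, Sequence],
) -> dict[str, tuple[float, float]]:
    """Per-term F tests in an additive OLS model (Type II sums of squares).

    ``factors`` maps term names to columns; non-numeric columns are treated
    as categorical.  No interactions are fitted, so the Type II F for a term
    compares the full additive model against the model with the term dropped.
    Returns ``{term: (F, p)}``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(y, dtype=float)
    data = pd.DataFrame({name: np.asarray(col) for name, col in factors.items()})
    if len(data) != y.size:
        raise ValueError("response and factor columns differ in length")
    data["_y"] = y

    terms = {}
    for name in factors:
        if pd.api.types.is_numeric_dtype(data[name]):
            terms[name] = name
        else:
            terms[name] = f"C({name})"
    formula = "_y ~ " + " + ".join(terms.values())
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient; collinear terms among {list(factors)}"
        )
    if len(data) <= model.exog.shape[1]:
        raise ValueError("need more observations than model parameters")
    fit = model.fit()
    table = anova_lm(fit, typ=2)
    out: dict[str, tuple[float, float]] = {}
    for name, term in terms.items():
        out[name] = (float(table.loc[term, "F"]), float(table.loc[term, "PR(>F)"]))
    return out


def chi2_2x2(
    table: Sequence[Sequence[float]], continuity: bool = True
) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 count table (1 df).

    Yates continuity correction is applied by default, matching the
    convention for small demographic tables.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    res = stats.chi2_contingency(arr, correction=continuity)
    if (res.expected_freq <= 0).any():
        raise ValueError("expected counts must all be positive")
    return float(res.statistic), float(res.pvalue)
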