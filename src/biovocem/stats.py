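"""Statistical procedures used around the inventory.

Finite-population sample sizing for the field campaign, Pearson correlation
of VOC concentrations with meteorological drivers, two-way fixed-effects
ANOVA with Tukey HSD for the NO₂ comparisons, and the order-3 centred
moving average used to smooth plotted series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SampleDesign",
    "CorrelationResult",
    "AnovaResult",
    "sample_size",
    "pearson",
    "moving_average",
    "two_way_anova",
]


@dataclass(frozen=True)
class SampleDesign:
    """Finite-population sampling design.

    N population size; Z the standard-normal quantile for the confidence
    level (1.96 for 95%); p/q success/failure proportions (p + q = 1);
    E the tolerated estimation error.
    """

    N: int
    Z: float = 1.96
    p: float = 0.5
    E: float = 0.05

    @property
    def q(self) -> float:
        return 1.0 - self.p

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size N must be >= 1")
        if self.Z <= 0:
            raise ValueError("Z must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if not 0 < self.E < 1:
            raise ValueError("estimation error E must be in (0, 1)")


def sample_size(design: SampleDesign) -> tuple[float, int]:
    """Finite-population sample size n = Z²pqN / (N E² + Z² p q).

    Returns the raw real value and the integer sample size (ceiling, capped
    at N — one cannot sample more units than the population holds).  As
    N → ∞ the raw value approaches the infinite-population Z²pq/E².
    """
    d = design
    zpq = d.Z ** 2 * d.p * d.q
    raw = zpq * d.N / (d.N * d.E ** 2 + zpq)
    return raw, min(math.ceil(raw), d.N)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    alpha: float

    @property
    def r_squared(self) -> float:
        return self.r ** 2

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def pearson(x, y, alpha: float = 0.01) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test (n−2 df).

    The default alpha of 0.01 corresponds to a 99% confidence level.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(x),
                             p_value=float(res.pvalue), alpha=alpha)


def moving_average(series, order: int = 3) -> np.ndarray:
    """Centred moving average; output shrinks by ``order − 1`` (no padding)."""
    arr = np.asarray(series, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if arr.size < order:
        raise ValueError(f"series of length {arr.size} shorter than order {order}")
    kernel = np.ones(order) / order
    return np.convolve(arr, kernel, mode="valid")


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA table plus Tukey HSD tables per factor."""

    table: pd.DataFrame  # sum_sq, df, F, PR(>F) per term
    tukey: dict[str, pd.DataFrame]
    ss_total: float

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def two_way_anova(values, factor_a, factor_b, alpha: float = 0.05,
                  interaction: bool = True, tukey: bool = True) -> AnovaResult:
    """Balanced fixed-effects two-way ANOVA with Tukey HSD post hoc.

    Sequential (type-I) sums of squares; on a balanced design these agree
    with the classical decomposition and sum exactly to SS_total.
    Unbalanced designs and designs with empty cells are rejected.  Tukey HSD
    is run on each factor's level means at ``alpha``; pass ``tukey=False``
    to skip the post-hoc tables (e.g. in simulation loops).
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "a": pd.Categorical(factor_a),
        "b": pd.Categorical(factor_b),
    })
    cell_counts = df.groupby(["a", "b"], observed=False).size()
    empty = cell_counts[cell_counts == 0]
    if len(empty):
        raise ValueError(f"design has empty cells: {list(empty.index)}")
    if cell_counts.nunique() != 1:
        raise ValueError("unbalanced design: per-cell counts "
                         f"{sorted(set(cell_counts))}; this procedure requires "
                         "a balanced layout")
    per_cell = int(cell_counts.iloc[0])
    use_interaction = interaction and per_cell >= 2
    formula = "value ~ C(a) + C(b)" + (" + C(a):C(b)" if use_interaction else "")
    ss_total = float(((df["value"] - df["value"].mean()) ** 2).sum())
    if ss_total == 0.0:
        # all observations identical: no variance to decompose
        terms = ["C(a)", "C(b)"] + (["C(a):C(b)"] if use_interaction else []) + ["Residual"]
        table = pd.DataFrame({"sum_sq": 0.0, "df": np.nan, "F": np.nan,
                              "PR(>F)": np.nan}, index=terms)
        return AnovaResult(table=table, tukey={}, ss_total=0.0)
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    posthoc = {}
    if tukey:
        for name, col in (("a", "a"), ("b", "b")):
            if df[col].nunique() >= 2:
                res = pairwise_tukeyhsd(df["value"], df[col].astype(str),
                                        alpha=alpha)
                posthoc[name] = pd.DataFrame(res.summary().data[1:],
                                             columns=res.summary().data[0])
    return AnovaResult(table=table, tukey=posthoc, ss_total=ss_total)
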