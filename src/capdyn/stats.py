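"""Statistical layer: normality testing, two-sample comparison, and the
nuclear-fallout correlation.

Conventions: Shapiro-Wilk for normality at alpha = 0.05; Student's (pooled)
two-sample t-test for normal data, two-sided, with Welch's correction
available by flag; significance bands *: p < 0.05, **: p < 0.005,
***: p < 0.0005. The fallout analysis reports Pearson's correlation
coefficient P, the OLS slope/intercept, and R^2 (= P^2 for simple linear
regression, asserted).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ParameterError

__all__ = ["shapiro_wilk", "t_test", "significance_stars", "correlate_fallout",
           "FalloutCorrelation", "smooth3", "benjamini_hochberg"]

SIGNIFICANCE_BANDS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise ParameterError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("sample is constant; W undefined (non-testable)")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def t_test(sample1, sample2, *, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test (Student's pooled by default, Welch optional).

    Degenerate input: if both groups have zero variance, equal means give
    (t = 0, p = 1) and unequal means are an error.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateDataError(
            "zero variance in both groups with unequal means; t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Map a p-value to the reporting bands (ns / * / ** / ***)."""
    if not np.isfinite(p) or p < 0 or p > 1:
        raise ParameterError(f"p must be in [0, 1], got {p}")
    for cut, stars in SIGNIFICANCE_BANDS:
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class FalloutCorrelation:
    predictor: str
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"predictor": self.predictor, "pearson_r": self.pearson_r,
                "r_squared": self.r_squared, "slope": self.slope,
                "intercept": self.intercept, "p_value": self.p_value, "n": self.n}


def correlate_fallout(table: pd.DataFrame, predictor: str = "expansion_rate_um2_s",
                      response: str = "fallout_rate") -> FalloutCorrelation:
    """Correlate per-condition fallout rates with a cap property.

    Pearson coefficient, OLS slope/intercept and R^2 over the condition table;
    requires at least 3 finite conditions and a non-constant predictor.
    """
    x = table[predictor].to_numpy(float)
    y = table[response].to_numpy(float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ParameterError(f"need >= 3 finite conditions, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"predictor '{predictor}' is constant")
    res = sps.linregress(x, y)
    r = float(res.rvalue)
    out = FalloutCorrelation(predictor=predictor, pearson_r=r, r_squared=r * r,
                             slope=float(res.slope), intercept=float(res.intercept),
                             p_value=float(res.pvalue), n=len(x))
    assert abs(out.r_squared - out.pearson_r ** 2) <= 1e-12
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0 or np.any((p < 0) | (p > 1)):
        raise ParameterError("p_values must be a non-empty 1D array in [0, 1]")
    res = sps.false_discovery_control(p, method="bh")
    return np.asarray(res)


def smooth3(y) -> np.ndarray:
    """3-point moving average (edges shrink), for line-profile figures."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    for i in range(len(y)):
        out[i] = y[max(0, i - 1): i + 2].mean()
    return out
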