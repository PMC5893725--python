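"""Group comparisons and regression analyses.

Group means are compared with unpaired two-tailed t-tests (Student by
default, Welch optional) under Holm–Bonferroni correction at α = 0.05;
relationships between tissue composition and conductivity are modelled
with simple and multiple ordinary least squares, goodness of fit
measured by R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


@dataclass(frozen=True)
class ComparisonResult:
    pair: Tuple[str, str]
    statistic: float
    p_value: float
    df: float
    rejected: Optional[bool] = None  # Holm-adjusted decision, if in a family


@dataclass(frozen=True)
class RegressionResult:
    slopes: Tuple[float, ...]
    intercept: float
    r_squared: float
    residual_sd: float
    n: int

    @property
    def slope(self) -> float:
        return self.slopes[0]


def ttest_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = True,
) -> ComparisonResult:
    """Unpaired two-tailed t-test (Student's by default, Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # Degenerate zero-variance samples: identical means are maximally
        # compatible (p = 1); distinct means are incompatible (p -> 0).
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
        df = a.size + b.size - 2
        return ComparisonResult(pair=("a", "b"), statistic=stat, p_value=p, df=df)
    res = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        pair=("a", "b"),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
    )


def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> List[bool]:
    """Holm's step-down rejection decisions, in the original order.

    Sort p-values ascending, reject the i-th smallest while
    p_(i) < α / (m − i + 1), and stop at the first failure.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, j in enumerate(order):
        if p[j] < alpha / (m - rank):
            reject[j] = True
        else:
            break
    return reject.tolist()


def compare_groups(
    groups: Dict[str, Sequence[float]],
    pairs: Sequence[Tuple[str, str]],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> List[ComparisonResult]:
    """t-tests for a family of group pairs with Holm-corrected decisions.

    The comparison family (e.g. each MI region vs control plus region
    pairs) is configurable via ``pairs``.
    """
    raw = []
    for g1, g2 in pairs:
        r = ttest_unpaired(groups[g1], groups[g2], equal_var=equal_var)
        raw.append(ComparisonResult(pair=(g1, g2), statistic=r.statistic,
                                    p_value=r.p_value, df=r.df))
    decisions = holm_bonferroni([r.p_value for r in raw], alpha=alpha)
    return [
        ComparisonResult(pair=r.pair, statistic=r.statistic, p_value=r.p_value,
                         df=r.df, rejected=d)
        for r, d in zip(raw, decisions)
    ]


def _ols(X: np.ndarray, y: np.ndarray) -> RegressionResult:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a constant response carries no variance to explain: report R^2 = 0
    r2 = float(model.rsquared) if ss_tot > 0 else 0.0
    return RegressionResult(
        slopes=tuple(float(c) for c in np.atleast_1d(model.params)[1:]),
        intercept=float(np.atleast_1d(model.params)[0]),
        r_squared=r2,
        residual_sd=float(np.sqrt(model.mse_resid)) if model.df_resid > 0 else 0.0,
        n=int(y.size),
    )


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple OLS of y on x; R² = 1 − SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need n > number of coefficients")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: degenerate design")
    return _ols(x[:, None], y)


def multiple_regression(
    X: Sequence[Sequence[float]],
    y: Sequence[float],
) -> RegressionResult:
    """OLS of y on several predictors (columns of X)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if y.size <= X.shape[1] + 1:
        raise ValueError("need n > number of coefficients")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant predictor column: degenerate design")
    return _ols(X, y)


def regression_study(ensemble: pd.DataFrame) -> pd.DataFrame:
    """Composition-vs-conductivity regression table for a phantom ensemble.

    ``ensemble`` needs columns V_e, V_cleft, sigma_l, sigma_t, sigma_n.
    Rows report slope and R² for each (predictor, conductivity) pair
    with predictors V_e, V_e − V_cleft and V_cleft, the multiple
    regression on (V_e − V_cleft, V_cleft) jointly, and finally the
    mutual fit of V_cleft on V_e − V_cleft.
    """
    required = {"V_e", "V_cleft", "sigma_l", "sigma_t", "sigma_n"}
    missing = required - set(ensemble.columns)
    if missing:
        raise ValueError(f"ensemble lacks columns {sorted(missing)}")
    if len(ensemble) < 10:
        raise ValueError("need an ensemble of at least 10 stacks")

    ve = ensemble["V_e"].to_numpy(float)
    vc = ensemble["V_cleft"].to_numpy(float)
    predictors = {"V_e": ve, "V_e_minus_cleft": ve - vc, "V_cleft": vc}

    rows = []
    for sig in ("sigma_l", "sigma_t", "sigma_n"):
        yv = ensemble[sig].to_numpy(float)
        for pname, xv in predictors.items():
            res = linear_regression(xv, yv)
            rows.append({"predictor": pname, "response": sig,
                         "slope": res.slope, "r_squared": res.r_squared})
        multi = multiple_regression(np.column_stack([ve - vc, vc]), yv)
        rows.append({"predictor": "V_e_minus_cleft+V_cleft", "response": sig,
                     "slope": float("nan"), "r_squared": multi.r_squared})
    mutual = linear_regression(ve - vc, vc)
    rows.append({"predictor": "V_e_minus_cleft", "response": "V_cleft",
                 "slope": mutual.slope, "r_squared": mutual.r_squared})
    return pd.DataFrame(rows)
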