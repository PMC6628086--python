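"""Statistical layer: paired condition comparison and accuracy regressions.

Two questions are asked of the cleaned subject table. First, whether the
return point differs between the 0-back and 2-back conditions: a paired
two-sided t-test on (Mapper2B - Mapper0B) is primary, with the Wilcoxon
signed-rank test reported alongside. Second, how well accuracy is explained
by reaction time alone (Model 1) versus reaction time plus the return point
(Model 2), via ordinary least squares on the percentage scale; fits report
the residual standard error RSE = sqrt(RSS / residual df), R² and the
overall F-test p-value, and Model 2 "wins" when it has both higher R² and
lower RSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "RegressionResult",
    "ModelComparison",
    "paired_condition_test",
    "fit_model",
    "compare_models",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Paired 0B-vs-2B comparison of return points."""

    mean_difference: float  # mean of (Mapper2B - Mapper0B), in samples
    t_statistic: float
    t_pvalue: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    n: int
    degenerate: bool = False  # zero-variance differences: t undefined


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary for one accuracy model in one condition."""

    model: int  # 1: Accuracy ~ MedianReactionTime; 2: + ReturnTime
    condition: str
    params: dict[str, float]
    bse: dict[str, float]
    rse: float
    r_squared: float
    f_pvalue: float
    n: int
    df_resid: int
    degenerate: bool = False  # constant response: R² undefined


@dataclass(frozen=True)
class ModelComparison:
    delta_r_squared: float  # R²(model 2) - R²(model 1)
    delta_rse: float  # RSE(model 2) - RSE(model 1)
    winner: Optional[int]  # 1, 2, or None on a split/tied criterion


def paired_condition_test(table: pd.DataFrame) -> PairedTestResult:
    """Paired tests of Mapper2B against Mapper0B on the cleaned table."""
    d = (table["Mapper2B"] - table["Mapper0B"]).to_numpy(dtype=float)
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    mean_diff = float(d.mean())
    if np.allclose(d, d[0]):
        return PairedTestResult(mean_diff, np.nan, np.nan, np.nan, np.nan, n, True)
    t_stat, t_p = sps.ttest_rel(table["Mapper2B"], table["Mapper0B"])
    nonzero = d[d != 0.0]
    if nonzero.size:
        w_stat, w_p = sps.wilcoxon(nonzero)
    else:  # pragma: no cover - all-zero handled by the degenerate branch
        w_stat, w_p = np.nan, np.nan
    return PairedTestResult(
        mean_diff, float(t_stat), float(t_p), float(w_stat), float(w_p), n
    )


def _model_columns(condition: str, model: int) -> tuple[str, list[str]]:
    if condition not in ("0B", "2B"):
        raise ValueError("condition must be '0B' or '2B'")
    response = f"{condition}Accuracy"
    predictors = [f"{condition} Median Reaction"]
    if model == 2:
        predictors.insert(0, f"Mapper{condition}")
    elif model != 1:
        raise ValueError("model must be 1 or 2")
    return response, predictors


def fit_model(table: pd.DataFrame, condition: str, model: int) -> RegressionResult:
    """OLS fit of accuracy on reaction time (Model 1) or return + reaction (Model 2)."""
    response, predictors = _model_columns(condition, model)
    y = table[response].to_numpy(dtype=float)
    x = table[predictors].to_numpy(dtype=float)
    n = y.size
    k = x.shape[1] + 1
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} subjects to fit model {model}")
    if y.std() == 0.0:
        return RegressionResult(
            model, condition, {}, {}, 0.0, np.nan, np.nan, n, n - k, degenerate=True
        )
    exog = sm.add_constant(pd.DataFrame(x, columns=predictors))
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design: collinear or constant predictors {predictors}"
        )
    fit = sm.OLS(y, exog).fit()
    rse = float(np.sqrt(fit.ssr / fit.df_resid)) if fit.df_resid > 0 else 0.0
    return RegressionResult(
        model,
        condition,
        {k_: float(v) for k_, v in fit.params.items()},
        {k_: float(v) for k_, v in fit.bse.items()},
        rse,
        float(fit.rsquared),
        float(fit.f_pvalue),
        int(fit.nobs),
        int(fit.df_resid),
    )


def compare_models(m1: RegressionResult, m2: RegressionResult) -> ModelComparison:
    """Which model wins: higher R² and lower RSE, or no winner on a split."""
    if m1.n != m2.n or m1.condition != m2.condition:
        raise ValueError("models must be fit on the same subjects and response")
    d_r2 = m2.r_squared - m1.r_squared
    d_rse = m2.rse - m1.rse
    if d_r2 > 0 and d_rse < 0:
        winner: Optional[int] = 2
    elif d_r2 < 0 and d_rse > 0:
        winner = 1
    else:
        winner = None
    return ModelComparison(float(d_r2), float(d_rse), winner)
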