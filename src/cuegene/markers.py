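"""Log-log marker models and the genome-wide correlation screen.

A marker model is an ordinary least-squares fit of ln(rate) on
ln(expression):

    ln mu   = alpha1 + beta1 * ln GT48 + eps
    ln qCO2 = alpha2 + beta2 * ln KGD  + eps

Exponentiating with eps = 0 gives the predictive power laws
mu = e^alpha1 * GT48^beta1 and qCO2 = e^alpha2 * KGD^beta2.  The screen
ranks every EC class by the Pearson correlation between its
ln-expression and the ln-transformed rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerModel",
    "CorrelationRanking",
    "fit_loglog",
    "fit_linear",
    "predict_rate",
    "zero_crossing",
    "correlation_screen",
    "marker_rank",
]


@dataclass(frozen=True)
class MarkerModel:
    """A fitted single-predictor OLS model.

    For log-log marker fits alpha/beta live on the natural-log scale.
    f_stat has (df_num, df_den) = (1, n_obs - 2) degrees of freedom;
    p_value is the upper-tail F probability.
    """

    response_label: str
    marker_label: str
    alpha: float
    beta: float
    r2: float
    residual_se: float
    f_stat: float
    df_num: int
    df_den: int
    n_obs: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "response": self.response_label,
            "marker": self.marker_label,
            "alpha": self.alpha,
            "beta": self.beta,
            "r2": self.r2,
            "residual_se": self.residual_se,
            "f_stat": self.f_stat,
            "df": [self.df_num, self.df_den],
            "n_obs": self.n_obs,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class CorrelationRanking:
    """Ranked Pearson correlations of EC classes against one response.

    table has columns ec_id, pearson_r, rank; sorted by descending signed
    r, ties broken lexicographically on ec_id, undefined correlations
    (zero variance) reported as NaN and ranked last.
    """

    response_label: str
    table: pd.DataFrame

    def rank_of(self, ec_id: str) -> int:
        sel = self.table.loc[self.table["ec_id"] == ec_id, "rank"]
        if sel.empty:
            raise KeyError(f"EC {ec_id!r} not present in ranking")
        return int(sel.iloc[0])


def _ols_simple(x: np.ndarray, y: np.ndarray, response: str, marker: str) -> MarkerModel:
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 usable observations, got {n}")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate predictor: zero variance")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    beta = sxy / sxx
    alpha = ybar - beta * xbar
    resid = y - alpha - beta * x
    sse = float((resid**2).sum())
    sst = float(((y - ybar) ** 2).sum())
    if sst == 0:
        raise ValueError("degenerate response: zero variance")
    r2 = 1.0 - sse / sst
    df_den = n - 2
    residual_se = math.sqrt(sse / df_den)
    if r2 >= 1.0:
        f_stat = math.inf
        p = 0.0
    else:
        f_stat = (r2 / (1.0 - r2)) * df_den
        p = float(stats.f.sf(f_stat, 1, df_den))
    return MarkerModel(
        response_label=response,
        marker_label=marker,
        alpha=alpha,
        beta=beta,
        r2=r2,
        residual_se=residual_se,
        f_stat=f_stat,
        df_num=1,
        df_den=df_den,
        n_obs=n,
        p_value=p,
    )


def fit_loglog(
    x,
    y,
    response_label: str = "mu",
    marker_label: str = "marker",
    pseudocount: float = 0.0,
) -> MarkerModel:
    """OLS of ln(y) on ln(x) over pairwise-positive observations.

    Pairs where either value (after adding the optional pseudocount,
    default off) is nonpositive are dropped with a warning, mirroring the
    exclusion of non-growing or non-expressing samples.
    """
    x = np.asarray(x, dtype=float) + pseudocount
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    if (~ok).any():
        warnings.warn(
            f"dropping {int((~ok).sum())} observation(s) with nonpositive or "
            "missing values before log transform",
            stacklevel=2,
        )
    return _ols_simple(np.log(x[ok]), np.log(y[ok]), response_label, marker_label)


def fit_linear(x, y, response_label: str, marker_label: str) -> MarkerModel:
    """OLS on untransformed scales (used for the index-vs-measured-CUE fit)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return _ols_simple(x[ok], y[ok], response_label, marker_label)


def predict_rate(model: MarkerModel, expression: float) -> float:
    """Power-law prediction e^alpha * expression^beta (expression > 0)."""
    if expression <= 0:
        raise ValueError("expression must be > 0")
    return math.exp(model.alpha) * expression**model.beta


def zero_crossing(model: MarkerModel) -> float:
    """ln-expression at which the predicted ln rate is zero: -alpha/beta.

    Interpreted as the basal expression level below which the predicted
    rate drops under one unit (e.g. 1 day^-1).
    """
    if model.beta == 0:
        raise ValueError("beta is zero; zero crossing undefined")
    return -model.alpha / model.beta


def correlation_screen(
    ecmat: pd.DataFrame,
    rates: pd.Series,
    response_label: str,
) -> CorrelationRanking:
    """Pearson r between ln(EC expression) and ln(rate) for every EC class.

    ecmat should already have passed the minimum-expression filter so all
    entries are positive; samples with nonpositive or missing rates are
    excluded.  ECs with zero variance get NaN and are ranked after all
    defined coefficients.
    """
    rates = rates.reindex(ecmat.columns)
    ok = rates.notna() & (rates > 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 samples with positive rates")
    sub = ecmat.loc[:, ok.to_numpy()]
    ln_expr = np.log(sub.to_numpy(dtype=float))
    ln_rate = np.log(rates[ok].to_numpy(dtype=float))

    xc = ln_expr - ln_expr.mean(axis=1, keepdims=True)
    yc = ln_rate - ln_rate.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = math.sqrt(float((yc**2).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[sx == 0] = np.nan

    table = pd.DataFrame({"ec_id": ecmat.index.to_numpy(), "pearson_r": r})
    # NaN sorts last; ec_id breaks ties deterministically
    table = table.sort_values(
        by=["pearson_r", "ec_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return CorrelationRanking(response_label=response_label, table=table)


def marker_rank(ranking: CorrelationRanking, ec_id: str) -> int:
    """1-based rank of an EC class in a correlation screen."""
    return ranking.rank_of(ec_id)
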