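"""Temporal trend analyses across breeding seasons.

The neighbour-count trend is an overdispersed-Poisson (quasi-Poisson)
regression of the raw counts on year with a log link, reported as the
data-scale overall change (prediction in the last year minus the first) and
the per-year rate, change / (n_years - 1).  Age and laying date trends are
Gaussian regressions of the annual means on year.  Frequentist confidence
intervals come from the fitted covariance; a draw-based interval from the
asymptotic normal approximation of the coefficients is used for the
nonlinear data-scale change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidArgumentError, SchemaError, UndefinedStatisticError

_RESPONSES = {"neighbours": None, "age": "age", "laying_date": "laying_date"}


def _check_years(records: pd.DataFrame) -> np.ndarray:
    if "year" not in records.columns:
        raise SchemaError("missing required column(s): ['year']")
    years = np.sort(records["year"].unique())
    if len(years) < 3:
        raise InvalidArgumentError(
            f"trend analysis needs >= 3 years of data, got {len(years)}"
        )
    return years


def annual_trend(
    records: pd.DataFrame,
    response: str = "neighbours",
    count_column: str = "neighbour_count",
    annual_means: bool = False,
    seed: int = 0,
) -> dict:
    """Temporal trend of the social trait, age or laying date.

    Returns ``slope`` (latent log-scale per year for counts, data units per
    year for Gaussian responses), ``overall_change`` (data-scale prediction
    at the last year minus the first), ``per_year_rate`` and 95% ``ci`` for
    the overall change.
    """
    if response not in _RESPONSES:
        raise InvalidArgumentError(f"unknown response: {response!r}")
    years = _check_years(records)
    span = float(years[-1] - years[0])

    if response == "neighbours":
        if annual_means:
            data = records.groupby("year")[count_column].mean().reset_index()
            yv = data[count_column].to_numpy(dtype=float)
            yrs = data["year"].to_numpy(dtype=float)
        else:
            if count_column not in records.columns:
                raise SchemaError(f"missing required column(s): ['{count_column}']")
            yv = records[count_column].to_numpy(dtype=float)
            yrs = records["year"].to_numpy(dtype=float)
        X = sm.add_constant(yrs - yrs.min())
        fit = sm.GLM(yv, X, family=sm.families.Poisson()).fit(scale="X2")
        params = np.asarray(fit.params)
        cov = np.asarray(fit.cov_params())
        rng = np.random.default_rng([seed, 811])
        draws = rng.multivariate_normal(params, cov, size=4000)
        first = np.exp(draws[:, 0])
        last = np.exp(draws[:, 0] + draws[:, 1] * span)
        change = last - first
        point = float(np.exp(params[0] + params[1] * span) - np.exp(params[0]))
        lo, hi = np.percentile(change, [2.5, 97.5])
        return {
            "slope": float(params[1]),
            "overall_change": point,
            "per_year_rate": point / span if span else np.nan,
            "ci": (float(lo), float(hi)),
        }

    col = _RESPONSES[response]
    if col not in records.columns:
        raise SchemaError(f"missing required column(s): ['{col}']")
    means = records.groupby("year")[col].mean()
    yrs = means.index.to_numpy(dtype=float)
    yv = means.to_numpy(dtype=float)
    X = sm.add_constant(yrs - yrs.min())
    fit = sm.OLS(yv, X).fit()
    slope = float(fit.params[1])
    lo, hi = fit.conf_int()[1]
    return {
        "slope": slope,
        "overall_change": slope * span,
        "per_year_rate": slope,
        "ci": (float(lo * span), float(hi * span)),
    }


def annual_mean_correlation(
    records: pd.DataFrame, col_a: str = "age", col_b: str = "laying_date"
) -> float:
    """Pearson correlation of the annual-mean series of two columns."""
    _check_years(records)
    for c in (col_a, col_b):
        if c not in records.columns:
            raise SchemaError(f"missing required column(s): ['{c}']")
    means = records.groupby("year")[[col_a, col_b]].mean()
    a = means[col_a].to_numpy(dtype=float)
    b = means[col_b].to_numpy(dtype=float)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise UndefinedStatisticError(
            "correlation undefined: an annual-mean series is constant"
        )
    return float(stats.pearsonr(a, b).statistic)
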