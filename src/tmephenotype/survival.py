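"""Survival characterization of immune subtypes.

Kaplan-Meier product-limit estimation with Greenwood variance, log-rank
comparison across groups, and Cox proportional-hazards regression (Efron
tie handling) with the two-stage enrollment rule: covariates reaching
p < 0.1 in univariate fits enter the multivariate model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import survival_table_from_events

__all__ = [
    "KMResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "median_split",
    "ENROLLMENT_P",
]

#: Univariate p-value threshold below which a covariate enters the
#: multivariate Cox model.
ENROLLMENT_P = 0.1


def _check_times(time: np.ndarray) -> None:
    if (time <= 0).any():
        raise ValueError("survival times must be positive")


@dataclass
class KMResult:
    """Kaplan-Meier estimate: survival step function S(t), Greenwood
    variance, and median survival (NaN when S never reaches 0.5)."""

    timeline: np.ndarray
    survival: pd.Series
    variance: pd.Series
    median: float

    def at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival.iloc[idx])


def km_estimate(time, event) -> KMResult:
    """Product-limit estimator of the survival function.

    Greenwood's formula gives the pointwise variance
    S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i)).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("at least one record required")
    _check_times(time)

    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    surv = kmf.survival_function_["KM_estimate"]

    table = survival_table_from_events(time, event)
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    cum = np.cumsum(terms)
    s_on_table = surv.reindex(table.index).to_numpy()
    variance = pd.Series(s_on_table**2 * cum, index=table.index, name="greenwood_var")

    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
    return KMResult(
        timeline=surv.index.to_numpy(dtype=float),
        survival=surv,
        variance=variance,
        median=median,
    )


def logrank_test(time, event, groups) -> tuple[float, float, int]:
    """Log-rank comparison of survival across >= 2 groups: the
    observed-minus-expected chi-square statistic over pooled event times.
    Returns (statistic, p, degrees of freedom)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    _check_times(time)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if event.sum() == 0:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value), len(levels) - 1


@dataclass
class CoxResult:
    """Cox regression output: per covariate the hazard ratio, 95% Wald CI
    and p-value; ``enrolled`` lists covariates entering the multivariate
    model under the p < 0.1 univariate rule."""

    table: pd.DataFrame
    mode: str
    enrolled: list[str]

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            if (t["hr"] <= 0).any():
                raise ValueError("hazard ratios must be positive")
            bad = (t["hr"] < t["ci_low"]) | (t["hr"] > t["ci_high"])
            if bad.any():
                raise ValueError("confidence interval does not bracket the hazard ratio")


def _fit_cph(df: pd.DataFrame, duration_col: str, event_col: str) -> pd.DataFrame:
    cph = CoxPHFitter()
    cph.fit(
        df, duration_col=duration_col, event_col=event_col,  # Efron ties
        fit_options={"precision": 1e-12},
    )
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    mode: str = "univariate",
    *,
    duration_col: str = "time",
    event_col: str = "event",
    enrollment_p: float = ENROLLMENT_P,
) -> CoxResult:
    """Cox proportional-hazards regression with Efron tie correction.

    ``mode="univariate"`` fits each covariate alone; ``"multivariate"``
    first runs the univariate fits and then jointly fits the covariates
    with univariate p < ``enrollment_p`` (default 0.1). Covariates must be
    numeric (dummy-code categorical factors beforehand).
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"mode must be 'univariate' or 'multivariate', got {mode!r}")
    _check_times(records[duration_col].to_numpy(dtype=float))
    n_events = int(records[event_col].sum())
    if mode == "multivariate" and n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )

    uni_rows = []
    for cov in covariates:
        sub = records[[duration_col, event_col, cov]].dropna()
        uni_rows.append(_fit_cph(sub, duration_col, event_col))
    uni = pd.concat(uni_rows)

    if mode == "univariate":
        return CoxResult(table=uni, mode=mode, enrolled=list(covariates))

    enrolled = uni.index[uni["p"] < enrollment_p].tolist()
    if not enrolled:
        return CoxResult(
            table=uni.iloc[0:0], mode=mode, enrolled=[]
        )
    sub = records[[duration_col, event_col, *enrolled]].dropna()
    table = _fit_cph(sub, duration_col, event_col)
    return CoxResult(table=table, mode=mode, enrolled=enrolled)


def median_split(scores: pd.Series) -> pd.Series:
    """Dichotomize a per-sample score at its median ('high' > median,
    'low' otherwise), the cut used for per-cell-type prognostic scans."""
    med = scores.median()
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name=scores.name
    )
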