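"""Survival association of signature genes: KM curves, log-rank tests and
Cox proportional-hazards models with backward selection.

Expression is dichotomized at the cohort median (ties to "low"), groups are
compared by the log-rank test, and multivariable Cox models are screened by
univariate significance then pruned by backward selection at a fixed removal
alpha. Estimation is delegated to lifelines (Efron tie handling); this
module owns the dichotomization, screening and selection logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .data_model import ExpressionMatrix, SampleAnnotation

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxModel",
    "dichotomize_expression",
    "km_estimate",
    "log_rank_test",
    "cox_fit",
    "cox_backward_select",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival probability at each distinct event time."""

    event_times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxModel:
    """Per-covariate log-hazards with Wald inference (Efron ties).

    ``table`` columns: beta, hr, ci_low, ci_high, p (95% CI on the hazard
    ratio via the normal approximation on the log scale).
    """

    table: pd.DataFrame
    log_likelihood: float
    ties_method: str = "efron"

    @property
    def covariates(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------


def dichotomize_expression(m: ExpressionMatrix, gene: str) -> pd.Series:
    """Split a cohort at the gene's median expression: 'high' strictly above,
    'low' at or below (median witnesses go to 'low')."""
    if gene not in m.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    vals = m.values.loc[gene]
    if vals.nunique() == 1:
        raise ValueError(f"gene {gene!r} is constant; cannot dichotomize")
    med = float(vals.median())
    return pd.Series(np.where(vals > med, "high", "low"), index=vals.index)


def _check_survival(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise ValueError("no samples with survival data")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    df = _check_survival(pd.DataFrame({"time": np.asarray(time, float), "event": np.asarray(event, int)}))
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    ev = np.sort(df.loc[df["event"] == 1, "time"].unique())
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in ev])
    at_risk = np.array([(df["time"] >= t).sum() for t in ev])
    return KMCurve(event_times=ev, survival=surv, at_risk=at_risk)


def log_rank_test(time, event, group) -> LogRankResult:
    """Log-rank comparison of survival between groups (chi-square, df = g-1)."""
    df = _check_survival(
        pd.DataFrame(
            {
                "time": np.asarray(time, float),
                "event": np.asarray(event, int),
                "group": np.asarray(group),
            }
        )
    )
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if df["event"].sum() < 1:
        raise ValueError("log-rank needs >= 1 event")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


# ---------------------------------------------------------------------------


def cox_fit(data: pd.DataFrame, covariates: Sequence[str]) -> CoxModel:
    """Cox proportional-hazards fit with Efron tie correction.

    ``data`` needs 'time' and 'event' columns plus the covariates (numeric).
    """
    covariates = list(covariates)
    df = _check_survival(data[["time", "event", *covariates]].dropna())
    for c in covariates:
        if df[c].nunique() == 1:
            raise ValueError(f"covariate {c!r} is constant")
    if df["event"].sum() < len(covariates):
        raise ValueError("fewer events than covariates")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    table = pd.DataFrame(
        {
            "beta": summ["coef"],
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "p": summ["p"],
        }
    )
    table.index = list(summ.index)
    return CoxModel(table=table, log_likelihood=float(cph.log_likelihood_))


def cox_backward_select(
    data: pd.DataFrame, covariates: Sequence[str], alpha: float = 0.05
) -> tuple[CoxModel | None, list[dict]]:
    """Univariate screen then backward selection at removal ``alpha``.

    Covariates enter the multivariable model only if their univariate Wald
    p < alpha; the covariate with the largest p is then removed and the model
    refit until all remaining p <= alpha. Returns the final model (None when
    everything is removed) and the ordered removal trace.
    """
    trace: list[dict] = []
    kept: list[str] = []
    for c in covariates:
        p = float(cox_fit(data, [c]).table.loc[c, "p"])
        include = p < alpha
        trace.append({"covariate": c, "stage": "univariate", "p": p, "kept": include})
        if include:
            kept.append(c)
    if not kept:
        return None, trace
    while kept:
        model = cox_fit(data, kept)
        worst = model.table["p"].idxmax()
        worst_p = float(model.table.loc[worst, "p"])
        if worst_p <= alpha:
            return model, trace
        trace.append({"covariate": worst, "stage": "backward", "p": worst_p, "kept": False})
        kept.remove(worst)
    return None, trace
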