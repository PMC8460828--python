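"""Kaplan-Meier estimation, log-rank comparison, and Cox proportional-hazards
fits for stratified cohorts.

Endpoints (overall, progression-free, disease-specific survival) are chosen
per cohort by configuration; times are months.  Estimation and fitting are
delegated to lifelines: product-limit Kaplan-Meier (events precede
censorings at tied times), the standard k-sample log-rank chi-squared test,
and Cox partial likelihood with Efron tie handling.  Samples with missing
time or event are excluded with a reported count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import AnalysisError
from .outcomes import TestResult


@dataclass
class KMCurve:
    """Step-function survival estimate with at-risk counts and median."""

    table: pd.DataFrame  # columns: time, survival, at_risk, events
    median: float  # months, nan when never reached


def _clean(time: pd.Series, event: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame({"time": pd.to_numeric(time, errors="coerce"),
                       "event": event})
    ok = df["time"].notna() & df["event"].notna()
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"{dropped} sample(s) with missing time/event excluded")
    df = df[ok]
    if (df["time"] < 0).any():
        raise AnalysisError("negative survival time")
    df["event"] = df["event"].astype(bool)
    return df


def km_estimate(time: pd.Series, event: pd.Series) -> KMCurve:
    """Product-limit survival estimate.

    The median is the earliest time with S <= 0.5 (nan if never reached).
    """
    df = _clean(time, event)
    if df.empty:
        raise AnalysisError("no usable samples for Kaplan-Meier estimate")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "time": ev.index.to_numpy(dtype=float),
            "survival": surv.reindex(ev.index).to_numpy(),
            "at_risk": ev["at_risk"].to_numpy(),
            "events": ev["observed"].to_numpy(),
        }
    )
    med = kmf.median_survival_time_
    return KMCurve(table=table, median=float(med) if np.isfinite(med) else float("nan"))


def logrank_test(time: pd.Series, event: pd.Series, strata: pd.Series) -> TestResult:
    """k-sample log-rank test across strata (chi-squared, k-1 df, two-sided)."""
    common = time.index.intersection(strata.index)
    df = _clean(time.loc[common], event.loc[common])
    df["stratum"] = strata.loc[df.index]
    df = df[df["stratum"].notna()]
    labels = df["stratum"].unique()
    if len(labels) < 2:
        raise AnalysisError("log-rank test needs >=2 strata")
    for lab in labels:
        if not df.loc[df["stratum"] == lab, "event"].any():
            warnings.warn(f"stratum {lab!r} has no events")
    res = multivariate_logrank_test(df["time"], df["stratum"], df["event"])
    return TestResult("logrank", float(res.test_statistic), float(res.p_value))


def pairwise_logrank(
    time: pd.Series, event: pd.Series, strata: pd.Series
) -> pd.DataFrame:
    """All pairwise log-rank comparisons between strata."""
    labels = [x for x in pd.unique(strata.dropna())]
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            mask = strata.isin([a, b])
            res = logrank_test(time, event, strata[mask])
            rows.append({"a": a, "b": b, "statistic": res.statistic, "p": res.p})
    return pd.DataFrame(rows)


def cox_fit(
    time: pd.Series, event: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Wald inference).

    Returns per-covariate hazard ratio, 95% CI, coefficient, and p.
    Requires >= 2 events and non-constant covariates.
    """
    common = time.index.intersection(covariates.index)
    df = _clean(time.loc[common], event.loc[common])
    X = covariates.loc[df.index].astype(float)
    keep = X.notna().all(axis=1)
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} sample(s) with NA covariates excluded")
    df, X = df[keep], X[keep]
    if int(df["event"].sum()) < 2:
        raise AnalysisError("Cox fit needs >=2 events")
    const = [c for c in X.columns if X[c].nunique() < 2]
    if const:
        raise AnalysisError(f"constant covariate(s): {const}")
    frame = pd.concat([df[["time", "event"]], X], axis=1)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    out.index.name = "covariate"
    return out
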