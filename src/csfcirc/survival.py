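"""Survival analysis for circRNA-defined patient groups.

Overall survival runs from the diagnosis of brain metastases to death
from any cause, censored at last follow-up. The module wraps the
product-limit (Kaplan-Meier) estimator, reverse-KM median follow-up,
the log-rank test, and Cox proportional-hazards models (Efron tie
handling, via lifelines), plus a per-circRNA survival scan over the
candidate panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError

NOT_REACHED = math.inf  # median marker when the curve never falls to 0.5


@dataclass
class KMCurve:
    """A Kaplan-Meier step function over the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    n_events: np.ndarray
    median: float  # NOT_REACHED (inf) when never below 0.5

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(durations, events) -> KMCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Individuals censored at an event time are kept at risk through that
    time (the standard convention)."""
    t = np.asarray(durations, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ValueError("need >= 1 record")
    if (t < 0).any():
        raise ValueError("negative survival time")
    event_times = np.unique(t[e == 1])
    surv, at_risk, n_events = [], [], []
    s = 1.0
    for ti in event_times:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        n_events.append(d_i)
        surv.append(s)
    surv = np.array(surv)
    median = NOT_REACHED
    below = np.nonzero(surv <= 0.5)[0]
    if below.size:
        median = float(event_times[below[0]])
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=np.array(at_risk),
        n_events=np.array(n_events),
        median=median,
    )


def reverse_km_followup(durations, events) -> float:
    """Median follow-up by reverse Kaplan-Meier (event indicator flipped)."""
    e = np.asarray(events, int)
    return km_estimate(durations, 1 - e).median


def logrank_test(durations, events, groups) -> tuple[float, float, int]:
    """Log-rank comparison of k >= 2 groups.

    Returns (chi-square statistic, p, df = k - 1)."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need >= 2 non-empty groups")
    res = multivariate_logrank_test(durations, groups, events)
    return float(res.test_statistic), float(res.p_value), int(labels.size - 1)


@dataclass
class CoxResult:
    """Tidy Cox fit: one row per covariate with HR, 95% CI and Wald p."""

    table: pd.DataFrame  # coef, hr, hr_lower, hr_upper, se, p
    n: int
    n_events: int
    log_likelihood: float

    def summary(self) -> pd.DataFrame:
        return self.table


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "os_months",
    event_col: str = "event",
    covariates: list[str] | None = None,
    univariate: bool = False,
) -> CoxResult | dict[str, CoxResult]:
    """Cox proportional-hazards fit with Efron tie handling.

    ``univariate=True`` fits each covariate alone and returns a dict of
    per-covariate results; otherwise all covariates enter jointly."""
    if covariates is None:
        covariates = [
            c for c in data.columns if c not in (duration_col, event_col)
        ]
    if not covariates:
        raise ValueError("no covariates to fit")
    if int(data[event_col].sum()) < 1:
        raise ValueError("need >= 1 event")
    for c in covariates:
        if data[c].nunique() < 2:
            raise DegenerateDataError(f"covariate {c!r} is constant")
    if univariate:
        return {c: _cox_single(data, duration_col, event_col, [c])
                for c in covariates}
    return _cox_single(data, duration_col, event_col, covariates)


def _cox_single(data, duration_col, event_col, covariates) -> CoxResult:
    cph = CoxPHFitter()
    sub = data[[duration_col, event_col] + covariates].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "hr_lower": summ["exp(coef) lower 95%"],
            "hr_upper": summ["exp(coef) upper 95%"],
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    table.index.name = "covariate"
    return CoxResult(
        table=table,
        n=int(len(sub)),
        n_events=int(sub[event_col].sum()),
        log_likelihood=float(cph.log_likelihood_),
    )


def per_circ_survival_scan(
    circ_values: pd.DataFrame,
    clinical: pd.DataFrame,
    candidates,
    by: str = "detection",
) -> pd.DataFrame:
    """Dichotomize patients per candidate circRNA and test survival.

    ``circ_values`` is a circ x patient matrix of CSF counts or FPKM;
    ``by="detection"`` splits at value > 0, ``by="median"`` at the
    per-circ median. For each candidate a log-rank test and a univariate
    Cox fit are run; degenerate splits (single group) are flagged, not
    fatal. BH q-values accompany raw p-values.
    """
    clinical = clinical.set_index("patient_id") if "patient_id" in clinical else clinical
    patients = [p for p in circ_values.columns if p in clinical.index]
    if len(patients) < 4:
        raise ValueError("need candidates quantified for >= 4 patients")
    rows = []
    for circ in candidates:
        row = {"junction_id": circ, "degenerate": False,
               "n_high": 0, "n_low": 0,
               "logrank_chi2": np.nan, "logrank_p": np.nan,
               "cox_coef": np.nan, "cox_hr": np.nan, "cox_p": np.nan}
        if circ not in circ_values.index:
            row["degenerate"] = True
            rows.append(row)
            continue
        vals = circ_values.loc[circ, patients].astype(float)
        thresh = 0.0 if by == "detection" else float(vals.median())
        high = (vals > thresh).astype(int)
        row["n_high"], row["n_low"] = int(high.sum()), int((1 - high).sum())
        if high.nunique() < 2:
            row["degenerate"] = True
            rows.append(row)
            continue
        dur = clinical.loc[patients, "os_months"].to_numpy(float)
        ev = clinical.loc[patients, "event"].to_numpy(int)
        chi2, p, _ = logrank_test(dur, ev, high.to_numpy())
        row["logrank_chi2"], row["logrank_p"] = chi2, p
        df = pd.DataFrame({"os_months": dur, "event": ev,
                           "high": high.to_numpy()})
        try:
            res = _cox_single(df, "os_months", "event", ["high"])
            row["cox_coef"] = float(res.table.loc["high", "coef"])
            row["cox_hr"] = float(res.table.loc["high", "hr"])
            row["cox_p"] = float(res.table.loc["high", "p"])
        except Exception:
            row["degenerate"] = True
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["logrank_p"].notna()
    table["logrank_q"] = np.nan
    if ok.any():
        table.loc[ok, "logrank_q"] = multipletests(
            table.loc[ok, "logrank_p"], method="fdr_bh"
        )[1]
    return table
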