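"""Core survival estimators and tests.

Thin, contract-checked wrappers around lifelines / scikit-survival:
product-limit estimation, two-group log-rank, Cox proportional hazards
(Efron ties), Harrell's concordance, IPCW time-dependent AUC, the
treatment-by-group interaction test, and point-biserial correlation.
All tests are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival estimate with right censoring."""

    times: np.ndarray            # event-time grid (sorted, unique)
    survival: np.ndarray         # S(t) at those times, nonincreasing
    at_risk: np.ndarray          # risk-set size just before each time
    censor_times: np.ndarray     # censoring marks

    def at(self, t: float) -> float:
        """S(t), right-continuous step function starting at 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Efron tie handling)."""

    terms: list[str]
    coef: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    log_likelihood: float
    cindex: float
    _fitter: object = None

    def summary_frame(self) -> pd.DataFrame:
        """Tidy (term, HR, CI low/high, p) table."""
        return pd.DataFrame({
            "term": self.terms,
            "hr": self.hr.values,
            "ci_low": self.ci_low.values,
            "ci_high": self.ci_high.values,
            "p": self.p.values,
        })


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate; an all-censored sample yields S = 1 everywhere."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if events.sum() == 0:
        logger.warning("all observations censored; survival curve is identically 1")
        return KMCurve(times=np.array([]), survival=np.array([]),
                       at_risk=np.array([]), censor_times=np.sort(times))
    kmf = KaplanMeierFitter().fit(times, events)
    ev = np.sort(np.unique(times[events == 1]))
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in ev])
    at_risk = np.array([int((times >= t).sum()) for t in ev])
    return KMCurve(times=ev, survival=surv, at_risk=at_risk,
                   censor_times=np.sort(times[events == 0]))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    from lifelines.statistics import logrank_test as ll_logrank

    times_a = np.asarray(times_a, dtype=np.float64)
    times_b = np.asarray(times_b, dtype=np.float64)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if events_a.sum() == 0 or events_b.sum() == 0:
        logger.warning("a group has zero events; log-rank statistic still computed")
    res = ll_logrank(times_a, times_b, event_observed_A=events_a,
                     event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def logrank_scan(scores, times, events, cutoffs) -> np.ndarray:
    """Two-group log-rank p-values for many score cutoffs at once.

    For each cutoff c the groups are score > c vs score <= c.  Uses the
    standard hypergeometric observed-minus-expected statistic with one
    degree of freedom, vectorized over cutoffs; agrees with
    :func:`logrank_test` applied per split.
    """
    scores = np.asarray(scores, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    cutoffs = np.asarray(cutoffs, dtype=np.float64)
    te = np.unique(times[events == 1])
    at_risk = times[None, :] >= te[:, None]          # (T, n)
    is_event = (events == 1)[None, :] & (times[None, :] == te[:, None])
    d = is_event.sum(axis=1).astype(np.float64)      # deaths at te
    n = at_risk.sum(axis=1).astype(np.float64)       # risk-set size
    low = scores[None, :] <= cutoffs[:, None]        # (C, n)
    n1 = low @ at_risk.T.astype(np.float64)          # (C, T)
    d1 = low @ is_event.T.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = d * n1 / n
        var = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / np.maximum(n - 1.0, 1.0)
    U = (d1 - expected).sum(axis=1)
    V = var.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, U * U / V, 0.0)
    return sstats.chi2.sf(chi2, 1)


class ConvergenceError(RuntimeError):
    pass


def cox_fit(covariates: pd.DataFrame, times, events, alpha: float = 0.05,
            robust: bool = False) -> CoxFit:
    """Multivariable Cox regression via partial-likelihood maximization.

    Hazard ratios with Wald confidence intervals and p-values; Harrell's C
    of the fitted linear predictor on the same data.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LLConvergenceError

    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    const = [c for c in covariates.columns
             if covariates[c].nunique(dropna=False) <= 1]
    if const:
        raise ValueError(f"constant covariates cannot enter a Cox model: {const}")
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    if events.sum() < covariates.shape[1]:
        raise ValueError(
            f"{events.sum()} events for {covariates.shape[1]} covariates; "
            "the partial likelihood is unidentifiable")
    df = covariates.copy()
    df["_time"], df["_event"] = times, events
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(df, duration_col="_time", event_col="_event", robust=robust)
    except LLConvergenceError as exc:
        raise ConvergenceError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    lp = cph.predict_partial_hazard(covariates).to_numpy()
    ci = harrell_cindex(np.log(lp), times, events)
    lo_col = [c for c in s.columns if c.startswith("exp(coef) lower")][0]
    hi_col = [c for c in s.columns if c.startswith("exp(coef) upper")][0]
    return CoxFit(
        terms=list(s.index),
        coef=s["coef"],
        hr=s["exp(coef)"],
        ci_low=s[lo_col],
        ci_high=s[hi_col],
        p=s["p"],
        log_likelihood=float(cph.log_likelihood_),
        cindex=ci,
        _fitter=cph,
    )


def harrell_cindex(scores, times, events) -> float:
    """Harrell's concordance of a risk score (higher score = higher risk).

    Censoring-aware comparable pairs; tied scores count 0.5.
    """
    from sksurv.metrics import concordance_index_censored

    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    c, _, _, _, _ = concordance_index_censored(events, times, scores)
    n_comparable = concordance_index_censored(events, times, scores)[1:3]
    if sum(n_comparable) == 0:
        raise ValueError("no comparable pairs")
    return float(c)


def td_auc(scores, times, events, horizon: float,
           ipcw_cohort: tuple | None = None) -> float:
    """Cumulative-case / dynamic-control AUC at a fixed horizon with IPCW.

    ``ipcw_cohort`` optionally supplies (times, events) used to estimate
    the censoring distribution; defaults to the evaluated cohort itself.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=bool)
    if not ((events & (times <= horizon)).any() and (times > horizon).any()):
        raise ValueError(
            f"horizon {horizon} needs events before it and survivors beyond it")
    y_test = Surv.from_arrays(events, times)
    if ipcw_cohort is None:
        y_train = y_test
    else:
        t2, e2 = ipcw_cohort
        y_train = Surv.from_arrays(np.asarray(e2, dtype=bool),
                                   np.asarray(t2, dtype=np.float64))
    auc, _ = cumulative_dynamic_auc(y_train, y_test,
                                    np.asarray(scores, dtype=np.float64),
                                    [horizon])
    return float(auc[0])


def interaction_test(treatment, group, times, events) -> dict:
    """Wald test of a treatment x risk-group product term in a Cox model.

    Returns the fit plus the interaction coefficient and its p-value.
    Raises if any of the four treatment-by-group cells is empty.
    """
    treatment = np.asarray(treatment, dtype=int)
    group = np.asarray(group, dtype=int)
    for t in (0, 1):
        for g in (0, 1):
            if not np.any((treatment == t) & (group == g)):
                raise ValueError(f"empty cell: treatment={t}, group={g}")
    X = pd.DataFrame({
        "treatment": treatment,
        "group": group,
        "treatment_x_group": treatment * group,
    })
    fit = cox_fit(X, times, events)
    return {
        "fit": fit,
        "interaction_coef": float(fit.coef["treatment_x_group"]),
        "interaction_p": float(fit.p["treatment_x_group"]),
    }


def point_biserial(values, factor) -> tuple[float, float]:
    """Point-biserial correlation (Pearson r against a 0/1 factor) and p."""
    values = np.asarray(values, dtype=np.float64)
    factor = np.asarray(factor)
    levels = np.unique(factor)
    if levels.size != 2:
        raise ValueError(f"factor must be binary, found levels {levels}")
    if np.ptp(values) == 0:
        raise ValueError("values are constant; correlation undefined")
    ind = (factor == levels[1]).astype(float)
    r, p = sstats.pointbiserialr(ind, values)
    return float(r), float(p)
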