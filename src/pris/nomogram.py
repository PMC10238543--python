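"""Integrated radiomic + clinical nomogram, calibration, and decision curves.

The nomogram is a point-scale rendering of a Cox model: each covariate's
contribution ``coef * x`` is mapped affinely to points, 0-100 spanning the
widest-effect covariate over the training cohort; total points map back to
predicted survival at fixed horizons through the baseline survival.
Decision-curve analysis quantifies clinical utility as
``net benefit = TP/N - (FP/N) * pt/(1 - pt)`` over threshold
probabilities ``pt``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from pris.survival import CoxFit, harrell_cindex, km_estimate

logger = logging.getLogger(__name__)


@dataclass
class NomogramModel:
    """Point tables and survival mapping of a fitted Cox model."""

    cox: CoxFit
    reference: pd.Series        # per-covariate reference value (training min effect)
    points_per_unit: pd.Series  # points contributed per unit of each covariate
    max_range: float            # widest covariate effect on the log-hazard scale
    horizons: tuple[float, ...]

    def total_points(self, X: pd.DataFrame) -> np.ndarray:
        """Sum of per-covariate points; affine in each Cox contribution."""
        pts = np.zeros(len(X))
        for term in self.cox.terms:
            pts += self.points_per_unit[term] * (
                X[term].to_numpy() - self.reference[term])
        return pts

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.zeros(len(X))
        for term in self.cox.terms:
            lp += float(self.cox.coef[term]) * X[term].to_numpy()
        return lp

    def predict_survival(self, X: pd.DataFrame, horizon: float) -> np.ndarray:
        """S(horizon | x) = S0(horizon)^exp(lp), step-function baseline."""
        cph = self.cox._fitter
        if cph is None:
            raise ValueError("nomogram requires the fitted Cox backend")
        base = cph.baseline_survival_
        support = float(base.index.max())
        if horizon > support:
            raise ValueError(
                f"horizon {horizon} beyond baseline support {support:.2f}")
        s0 = self._baseline_at(horizon)
        lp_centered = cph.predict_log_partial_hazard(X).to_numpy()
        return s0 ** np.exp(lp_centered)

    def _baseline_at(self, horizon: float) -> float:
        base = self.cox._fitter.baseline_survival_
        idx = np.searchsorted(base.index.to_numpy(), horizon, side="right") - 1
        return float(base.iloc[idx, 0]) if idx >= 0 else 1.0

    def survival_from_points(self, points: np.ndarray, horizon: float) -> np.ndarray:
        """Total points -> survival probability, through the baseline."""
        cph = self.cox._fitter
        lp = points * self.max_range / 100.0 + float(
            sum(self.cox.coef[t] * self.reference[t] for t in self.cox.terms))
        s0 = self._baseline_at(horizon)
        lp_mean = float(sum(self.cox.coef[t] * cph._norm_mean[t]
                            for t in self.cox.terms))
        return s0 ** np.exp(lp - lp_mean)

    def point_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.cox.terms,
            "reference": [self.reference[t] for t in self.cox.terms],
            "points_per_unit": [self.points_per_unit[t] for t in self.cox.terms],
        })


def build_nomogram(cox: CoxFit, train: pd.DataFrame,
                   horizons: tuple[float, ...] = (4.0, 5.0, 6.0)) -> NomogramModel:
    """Build the point-scale nomogram of a converged Cox fit.

    The covariate whose effect ``coef * x`` spans the widest range over
    the training cohort is assigned 0-100 points; every other covariate
    scales proportionally.
    """
    ranges, refs = {}, {}
    for term in cox.terms:
        contrib = float(cox.coef[term]) * train[term].to_numpy(dtype=np.float64)
        refs[term] = train[term].to_numpy()[int(np.argmin(contrib))]
        ranges[term] = float(contrib.max() - contrib.min())
    max_range = max(ranges.values())
    if max_range <= 0:
        raise ValueError("all covariates have zero effect range")
    ppu = {t: 100.0 * float(cox.coef[t]) / max_range for t in cox.terms}
    return NomogramModel(
        cox=cox,
        reference=pd.Series(refs),
        points_per_unit=pd.Series(ppu),
        max_range=max_range,
        horizons=tuple(horizons),
    )


def calibration(predicted_survival, times, events, horizon: float,
                bins: int = 4) -> dict:
    """Quantile-binned predicted vs Kaplan-Meier-observed survival at a
    horizon, with a Hosmer-Lemeshow-type chi-square over the bins.

    Bins without events are merged with their neighbor (logged).  Returns
    per-bin means, the chi-square, its p (df = bins - 2), and the bin
    table.
    """
    pred = np.asarray(predicted_survival, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    order = np.argsort(pred)
    edges = [order[int(round(i * len(pred) / bins)):
                   int(round((i + 1) * len(pred) / bins))] for i in range(bins)]
    edges = [e for e in edges if e.size]
    # merge event-free bins into the neighbor
    merged: list[np.ndarray] = []
    for e in edges:
        if merged and events[e].sum() == 0:
            logger.info("calibration: merging an event-free bin with its neighbor")
            merged[-1] = np.concatenate([merged[-1], e])
        else:
            merged.append(e)
    if len(merged) > 1 and events[merged[0]].sum() == 0:
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged = merged[1:]
    rows, chi2 = [], 0.0
    for e in merged:
        p_mean = float(pred[e].mean())
        km = km_estimate(times[e], events[e])
        obs = km.at(horizon)
        n_b = e.size
        exp_fail = 1.0 - p_mean
        obs_fail = 1.0 - obs
        denom = max(exp_fail * (1.0 - exp_fail), 1e-12)
        chi2 += n_b * (obs_fail - exp_fail) ** 2 / denom
        rows.append({"n": n_b, "predicted": p_mean, "observed": obs,
                     "events": int(events[e].sum())})
    df_table = pd.DataFrame(rows)
    dof = max(len(merged) - 2, 1)
    p = float(sstats.chi2.sf(chi2, dof))
    return {"table": df_table, "chi2": float(chi2), "p": p, "df": dof}


def decision_curve(predicted_risk, outcome, thresholds,
                   weights=None) -> pd.DataFrame:
    """Net-benefit curves of the model, treat-all, and treat-none.

    ``predicted_risk`` is the probability of the event by the horizon;
    ``outcome`` the (possibly IPCW-weighted) event indicator at the
    horizon.  At threshold pt a patient is treated when risk >= pt and

        NB = TP/N - (FP/N) * pt / (1 - pt)

    with N the (weighted) cohort size.  pt = 1 is excluded from the grid.
    """
    risk = np.asarray(predicted_risk, dtype=np.float64)
    y = np.asarray(outcome, dtype=np.float64)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=np.float64)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must lie in (0, 1)")
    thresholds = thresholds[thresholds < 1.0]
    n = w.sum()
    prev = float((w * y).sum() / n)
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt)
        pos = risk >= pt
        tp = float((w * y * pos).sum() / n)
        fp = float((w * (1 - y) * pos).sum() / n)
        rows.append({
            "threshold": pt,
            "nb_model": tp - fp * odds,
            "nb_all": prev - (1.0 - prev) * odds,
            "nb_none": 0.0,
        })
    return pd.DataFrame(rows)


def ipcw_outcomes(times, events, horizon: float):
    """Event-by-horizon indicator with inverse-probability-of-censoring weights.

    Patients censored before the horizon carry weight 0; events before the
    horizon weigh 1/G(T-), survivors 1/G(horizon), where G is the
    Kaplan-Meier estimate of the censoring distribution.
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    cens_km = km_estimate(times, 1 - events)

    def G(t):
        return max(cens_km.at(t), 1e-12)

    y = np.zeros(times.size)
    w = np.zeros(times.size)
    for i, (t, e) in enumerate(zip(times, events)):
        if e == 1 and t <= horizon:
            y[i], w[i] = 1.0, 1.0 / G(min(t, horizon) - 1e-9)
        elif t > horizon:
            y[i], w[i] = 0.0, 1.0 / G(horizon)
        # censored before the horizon: weight stays 0
    return y, w


def compare_models(scores_a, scores_b, times, events, n_boot: int = 2000,
                   seed: int = 0) -> dict:
    """Paired Harrell-C comparison by patient-level bootstrap.

    Returns both C-indices, their difference (a - b), and a two-sided
    bootstrap p-value for the difference.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    if not (scores_a.size == scores_b.size == times.size):
        raise ValueError("both models must be scored on the same patients")
    ca = harrell_cindex(scores_a, times, events)
    cb = harrell_cindex(scores_b, times, events)
    if np.allclose(scores_a, scores_b):
        return {"c_a": ca, "c_b": cb, "difference": 0.0, "p": 1.0}
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    n = times.size
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if events[idx].sum() == 0:
            diffs[b] = 0.0
            continue
        try:
            diffs[b] = (harrell_cindex(scores_a[idx], times[idx], events[idx])
                        - harrell_cindex(scores_b[idx], times[idx], events[idx]))
        except ValueError:
            diffs[b] = 0.0
    p = 2.0 * min(float(np.mean(diffs <= 0)), float(np.mean(diffs >= 0)))
    return {"c_a": ca, "c_b": cb, "difference": ca - cb, "p": min(p, 1.0)}
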