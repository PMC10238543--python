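"""The radiomic risk signature (pRiS): LASSO-Cox selection and scoring.

Feature selection runs an L1-penalized Cox model over a 100-value penalty
path log-spaced from the data-determined maximum down to 1% of it.
K-fold cross-validated partial-likelihood deviance nominates a penalty;
the returned model is the path point nearest that nominee whose number of
nonzero coefficients equals the configured target (default 7), so the
signature size is locked down exactly.  The score of a patient is the
inner product of the coefficients with the (training-standardized)
feature values; patients are dichotomized at the training median or at
the minimum-log-rank-p ("X-tile") cutoff.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pris.survival import logrank_scan, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class SignatureModel:
    """Selected features, their Cox-LASSO coefficients, and cutoffs."""

    features: list[str]
    coefficients: pd.Series
    penalty: float
    cutoff_median: float | None = None
    cutoff_xtile: float | None = None

    def to_json(self) -> str:
        return json.dumps({
            "features": self.features,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "penalty": self.penalty,
            "cutoff_median": self.cutoff_median,
            "cutoff_xtile": self.cutoff_xtile,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        return cls(
            features=list(d["features"]),
            coefficients=pd.Series(d["coefficients"]),
            penalty=float(d["penalty"]),
            cutoff_median=d.get("cutoff_median"),
            cutoff_xtile=d.get("cutoff_xtile"),
        )


def _breslow_loglik(X: np.ndarray, times: np.ndarray, events: np.ndarray,
                    coef: np.ndarray) -> float:
    """Breslow log partial likelihood of fixed coefficients."""
    eta = X @ coef
    order = np.argsort(-times)  # decreasing time
    eta_o = eta[order]
    t_o = times[order]
    e_o = events[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    # risk set of t_i: all with t_j >= t_i -> with decreasing sort, prefix;
    # ties share the largest prefix covering the tied block
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        denom = log_cum[j]
        for k in range(i, j + 1):
            if e_o[k]:
                ll += eta_o[k] - denom
        i = j + 1
    return float(ll)


def fit_lasso_cox(
    features: pd.DataFrame,
    times,
    events,
    n_features: int = 7,
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
) -> SignatureModel:
    """Fit the LASSO-Cox signature with an exact selected-feature count.

    Parameters
    ----------
    features
        Standardized feature matrix (patients x features).
    n_features
        Exact number of nonzero coefficients of the returned model.
    folds
        Cross-validation folds for the penalty search.

    Raises
    ------
    ValueError
        If no path point attains exactly ``n_features`` nonzero
        coefficients (the attainable counts are listed).
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if n_features <= 0:
        raise ValueError(f"n_features must be positive, got {n_features}")
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    if events.sum() < folds:
        raise ValueError(f"{events.sum()} events for {folds}-fold CV")
    X = features.to_numpy(dtype=np.float64)
    y = Surv.from_arrays(events.astype(bool), times)

    full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=alpha_min_ratio)
    full.fit(X, y)
    path = np.asarray(full.alphas_)

    # CV partial-likelihood deviance over the fixed path
    cv_dev = np.zeros((folds, path.size))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(kf.split(X)):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=path)
        m.fit(X[tr], y[tr])
        fold_alphas = np.asarray(m.alphas_)
        for a_idx, alpha in enumerate(path):
            j = int(np.argmin(np.abs(np.log(fold_alphas) - np.log(alpha))))
            coef = m.coef_[:, j]
            cv_dev[f, a_idx] = -2.0 * _breslow_loglik(X[te], times[te],
                                                      events[te], coef)
    mean_dev = cv_dev.mean(axis=0)
    best_idx = int(np.argmin(mean_dev))

    nnz = (np.abs(full.coef_) > 1e-12).sum(axis=0)
    candidates = np.nonzero(nnz == n_features)[0]
    if candidates.size > 0:
        chosen = candidates[np.argmin(np.abs(candidates - best_idx))]
        alpha_sel = float(path[chosen])
        coef = full.coef_[:, chosen]
    else:
        # the discrete path skipped the count; refine between bracketing
        # penalties by bisection in log-alpha
        alpha_sel, coef = _refine_exact_count(X, y, path, nnz, n_features, best_idx)
    sel = np.nonzero(np.abs(coef) > 1e-12)[0]
    names = [features.columns[i] for i in sel]
    logger.info("lasso-cox: CV penalty %.4g, locked to %.4g with %d features",
                path[best_idx], alpha_sel, len(names))
    return SignatureModel(
        features=names,
        coefficients=pd.Series(coef[sel], index=names),
        penalty=alpha_sel,
    )


def _refine_exact_count(X, y, path, nnz, n_features, best_idx, max_iter=60):
    """Bisect log-alpha between path points bracketing the target count."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    def count_and_coef(alpha):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha])
        m.fit(X, y)
        c = m.coef_[:, 0]
        return int((np.abs(c) > 1e-12).sum()), c

    # path alphas are decreasing, nnz (weakly) increasing
    brackets = [i for i in range(len(path) - 1)
                if nnz[i] < n_features < nnz[i + 1]]
    if not brackets:
        raise ValueError(
            f"no penalty on the path selects exactly {n_features} features; "
            f"attainable counts: {sorted(set(int(k) for k in nnz))}")
    brackets.sort(key=lambda i: abs(i - best_idx))
    for i in brackets:
        lo, hi = np.log(path[i + 1]), np.log(path[i])  # lo: more features
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            k, coef = count_and_coef(float(np.exp(mid)))
            if k == n_features:
                return float(np.exp(mid)), coef
            if k > n_features:
                lo = mid
            else:
                hi = mid
    raise ValueError(
        f"no penalty attains exactly {n_features} features even after "
        f"refinement; attainable counts: {sorted(set(int(k) for k in nnz))}")


def compute_pris(model: SignatureModel, features: pd.DataFrame | pd.Series):
    """pRiS score: inner product of signature coefficients with normalized
    feature values.  Accepts one patient (Series) or a cohort (DataFrame)."""
    if isinstance(features, pd.Series):
        missing = [f for f in model.features if f not in features.index]
        if missing:
            raise KeyError(f"missing signature features: {missing}")
        return float(sum(model.coefficients[f] * features[f] for f in model.features))
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise KeyError(f"missing signature features: {missing}")
    return features[model.features].to_numpy() @ model.coefficients.to_numpy()


def median_cutoff(train_scores) -> float:
    """Sample median of training scores (even n: mean of the central pair)."""
    scores = np.asarray(train_scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    return float(np.median(scores))


def xtile_cutoff(train_scores, times, events, min_group_frac: float = 0.10) -> float:
    """Minimum-log-rank-p cutoff over all candidate splits of the training set.

    Every unique score value is a candidate; a candidate is admissible
    when both induced groups (high: score > c) hold at least
    ``min_group_frac`` of patients.  Returns the admissible cutoff with
    the smallest two-group log-rank p (ties: the smaller cutoff).

    Note the minimum-p scan is optimistic under the null: its p-values are
    not valid significance levels without correction.
    """
    scores = np.asarray(train_scores, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    n = scores.size
    min_n = max(1, min_group_frac * n)
    admissible = []
    for c in np.unique(scores):
        high = scores > c
        n_high = int(high.sum())
        if n_high < min_n or (n - n_high) < min_n:
            continue
        if events[high].sum() < 2 or events[~high].sum() < 2:
            continue
        admissible.append(float(c))
    if not admissible:
        raise ValueError("no admissible cutoff under the group-size constraints")
    pvals = logrank_scan(scores, times, events, np.asarray(admissible))
    # candidates are sorted ascending; argmin takes the first (smallest)
    # cutoff among exact ties
    best = int(np.argmin(pvals))
    return admissible[best]


def assign_risk_groups(scores, cutoff: float, source: str = "median") -> pd.Series:
    """Dichotomize scores: high ⇔ score > cutoff."""
    scores = pd.Series(np.asarray(scores, dtype=np.float64))
    groups = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index)
    groups.attrs["cutoff"] = float(cutoff)
    groups.attrs["source"] = source
    return groups
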