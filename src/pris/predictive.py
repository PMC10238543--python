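"""Chemotherapy-benefit evaluation: stratified comparisons and subgroups.

Mirrors the figure-level analyses of the signature validation: within each
treatment arm, high- vs low-risk survival; within each risk group,
chemoradiation vs radiotherapy alone (radiation is the reference); an
overall treatment-by-group interaction; and the same battery restricted to
one AJCC stage.  Comparisons are unadjusted univariate Cox fits plus the
two-group log-rank test, matching how such stratified results are read
off Kaplan-Meier panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pris.survival import cox_fit, interaction_test, logrank_test

logger = logging.getLogger(__name__)

ARM_NAMES = {0: "radiation", 1: "chemoradiation"}


@dataclass
class StratifiedResult:
    """All HRs/CIs/p-values of one stratified chemotherapy-benefit run."""

    within_arm: dict       # arm -> {hr, ci, p_wald, p_logrank, n, events}
    within_group: dict     # group -> {hr, ci, p_wald, p_logrank, n, events}
    interaction_p: float
    interaction_coef: float
    cell_sizes: dict       # (arm, group) -> n
    cutoff_source: str = "median"
    underpowered: bool = False
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, r in self.within_arm.items():
            rows.append({"analysis": f"high_vs_low_in_{arm}", **r})
        for grp, r in self.within_group.items():
            rows.append({"analysis": f"chemo_vs_radiation_in_{grp}", **r})
        rows.append({"analysis": "interaction", "p_wald": self.interaction_p})
        return pd.DataFrame(rows)


def _univariate(indicator: np.ndarray, times, events) -> dict:
    X = pd.DataFrame({"x": np.asarray(indicator, dtype=int)})
    fit = cox_fit(X, times, events)
    a = indicator == 1
    _, p_lr = logrank_test(np.asarray(times)[a], np.asarray(events)[a],
                           np.asarray(times)[~a], np.asarray(events)[~a])
    return {
        "hr": float(fit.hr.iloc[0]),
        "ci_low": float(fit.ci_low.iloc[0]),
        "ci_high": float(fit.ci_high.iloc[0]),
        "p_wald": float(fit.p.iloc[0]),
        "p_logrank": float(p_lr),
        "n": int(len(times)),
        "events": int(np.asarray(events).sum()),
    }


def within_arm_comparison(cohort: pd.DataFrame, groups: pd.Series, arm: int,
                          time_col: str = "time", event_col: str = "event") -> dict:
    """High- vs low-risk survival within one treatment arm.

    HR > 1 means high-risk patients fare worse in this arm.
    """
    sub = cohort[cohort["treatment"] == arm]
    g = groups.loc[sub.index]
    if (g == "high").sum() == 0 or (g == "low").sum() == 0:
        raise ValueError(
            f"arm {ARM_NAMES.get(arm, arm)} lacks one of the risk groups")
    return _univariate((g == "high").to_numpy(), sub[time_col].to_numpy(),
                       sub[event_col].to_numpy())


def within_group_treatment_effect(cohort: pd.DataFrame, groups: pd.Series,
                                  group: str, time_col: str = "time",
                                  event_col: str = "event") -> dict:
    """Chemoradiation vs radiotherapy alone within one risk group.

    Radiation is the reference: HR < 1 means chemotherapy is associated
    with longer survival in this group.
    """
    sub = cohort[groups.loc[cohort.index] == group]
    if (sub["treatment"] == 0).sum() == 0 or (sub["treatment"] == 1).sum() == 0:
        raise ValueError(f"risk group {group!r} lacks one of the treatment arms")
    return _univariate((sub["treatment"] == 1).to_numpy(),
                       sub[time_col].to_numpy(), sub[event_col].to_numpy())


def stratified_analysis(cohort: pd.DataFrame, groups: pd.Series,
                        cutoff_source: str = "median",
                        time_col: str = "time",
                        event_col: str = "event",
                        min_events: int = 10) -> StratifiedResult:
    """The full chemotherapy-benefit battery on one cohort.

    The four (arm x group) cells partition the cohort; every reported
    number is recomputed from the given assignment, nothing is cached
    across cutoff choices.
    """
    g = groups.loc[cohort.index]
    cells = {}
    for arm in (0, 1):
        for grp in ("high", "low"):
            cells[(ARM_NAMES[arm], grp)] = int(
                ((cohort["treatment"] == arm) & (g == grp)).sum())
    within_arm = {
        ARM_NAMES[arm]: within_arm_comparison(cohort, g, arm, time_col, event_col)
        for arm in (0, 1)
    }
    within_group = {
        grp: within_group_treatment_effect(cohort, g, grp, time_col, event_col)
        for grp in ("high", "low")
    }
    it = interaction_test(cohort["treatment"].to_numpy(),
                          (g == "high").astype(int).to_numpy(),
                          cohort[time_col].to_numpy(),
                          cohort[event_col].to_numpy())
    n_events = int(cohort[event_col].sum())
    underpowered = n_events < min_events
    if underpowered:
        logger.warning("only %d events; stratified results flagged underpowered",
                       n_events)
    return StratifiedResult(
        within_arm=within_arm,
        within_group=within_group,
        interaction_p=it["interaction_p"],
        interaction_coef=it["interaction_coef"],
        cell_sizes=cells,
        cutoff_source=cutoff_source,
        underpowered=underpowered,
        note=f"{n_events} events" if underpowered else "",
    )


def subgroup_by_stage(cohort: pd.DataFrame, groups: pd.Series, stage: str,
                      cutoff_source: str = "median",
                      time_col: str = "time",
                      event_col: str = "event") -> StratifiedResult:
    """The stratified battery restricted to one AJCC stage (I or II).

    Underpowered subgroups are flagged, never suppressed.
    """
    if "ajcc_stage" not in cohort.columns:
        raise ValueError("cohort lacks an 'ajcc_stage' column")
    sub = cohort[cohort["ajcc_stage"] == stage]
    if len(sub) == 0:
        raise ValueError(f"no patients with stage {stage!r}")
    return stratified_analysis(sub, groups.loc[sub.index], cutoff_source,
                               time_col, event_col)
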