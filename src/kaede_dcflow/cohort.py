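"""Signature-stratified survival analysis of bulk cohorts.

Samples are scored for a gene signature by ssGSEA, scores are scaled to
[0, 1] across the cohort, the cohort is split at the median score into
'high' and 'low' groups (ties to 'low'), and the groups' overall survival
is compared with Kaplan-Meier curves and the two-group log-rank test
(lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .gsea import normalize_01, ssgsea_matrix


@dataclass
class SurvivalCohort:
    """Sample x gene expression with overall survival (months) and event
    indicator (1 = event, 0 = censored)."""

    expression: pd.DataFrame
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.expression) != len(self.time) or len(self.time) != len(self.event):
            raise ValueError("expression, time and event lengths differ")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be binary")

    @classmethod
    def from_csv(cls, path: str):
        df = pd.read_csv(path, index_col=0)
        time = df.pop("time_months").to_numpy()
        event = df.pop("event").to_numpy()
        return cls(df, time, event)

    def to_csv(self, path: str):
        df = self.expression.copy()
        df["time_months"] = self.time
        df["event"] = self.event
        df.to_csv(path, float_format="%.10g")


def stratify_median(scores) -> np.ndarray:
    """'high' for score > median, 'low' otherwise (ties at the median go to
    'low')."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 samples to stratify")
    med = np.median(x)
    if np.all(x == x[0]):
        raise ValueError("all scores identical: no stratification possible")
    return np.where(x > med, "high", "low")


def km_estimate(time, event, group) -> pd.DataFrame:
    """Product-limit survival estimate per group (long format: group, time,
    survival)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    frames = []
    for g in pd.unique(group):
        m = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m])
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"group": g, "time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


def logrank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2 or any((group == g).sum() == 0 for g in levels):
        raise ValueError("log-rank requires exactly two non-empty groups")
    if event.sum() < 1:
        raise ValueError("log-rank requires at least one event")
    m = group == levels[0]
    res = logrank_test(time[m], time[~m], event_observed_A=event[m], event_observed_B=event[~m])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalReport:
    scores: pd.Series
    normalized_scores: pd.Series
    groups: pd.Series
    curves: pd.DataFrame
    statistic: float
    pval: float
    median_survival: dict


def signature_survival(
    cohort: SurvivalCohort, signature_genes, exponent: float = 0.25
) -> SurvivalReport:
    """ssGSEA score -> 0-1 scaling -> median split -> KM + log-rank."""
    present = [g for g in signature_genes if g in cohort.expression.columns]
    if not present:
        raise ValueError("no signature gene present in the cohort")
    raw = ssgsea_matrix(cohort.expression, present, exponent=exponent)
    norm = pd.Series(normalize_01(raw.to_numpy()), index=raw.index, name="score01")
    groups = pd.Series(stratify_median(norm.to_numpy()), index=raw.index, name="group")
    curves = km_estimate(cohort.time, cohort.event, groups.to_numpy())
    stat, p = logrank(cohort.time, cohort.event, groups.to_numpy())
    med = {}
    for g in ("high", "low"):
        m = groups.to_numpy() == g
        kmf = KaplanMeierFitter().fit(cohort.time[m], cohort.event[m])
        med[g] = float(kmf.median_survival_time_)
    return SurvivalReport(raw, norm, groups, curves, stat, p, med)
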