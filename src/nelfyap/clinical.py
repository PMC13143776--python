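"""Composite IHC scoring, ROC dichotomization, survival and contingency tests.

Percent-positive staining is binned (0% -> 0, 1-10% -> 1, 11-50% -> 2,
51-100% -> 3) and multiplied by a 0-3 intensity score, giving a composite
score in {0..9}.  The high/low cutoff maximizes Youden's J on the ROC of the
composite score against the disease-free-survival event indicator.  Survival
comparisons use the Kaplan-Meier product-limit estimator and the Mantel-Cox
log-rank test; categorical associations use the uncorrected Pearson
chi-square contingency test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .dataio import ClinicalRecord

JOINT_GROUPS = (
    "HighYAP_HighNELFA",
    "HighYAP_LowNELFA",
    "LowYAP_HighNELFA",
    "LowYAP_LowNELFA",
)


# ---------------------------------------------------------------------------
# Composite scoring and dichotomization
# ---------------------------------------------------------------------------


def percent_bin(percent: float) -> int:
    """Bin percent-positive staining: 0 -> 0, (0,10] -> 1, (10,50] -> 2, else 3."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent outside [0,100]: {percent}")
    if percent == 0:
        return 0
    if percent <= 10:
        return 1
    if percent <= 50:
        return 2
    return 3


def composite_score(percent: float, intensity: int) -> int:
    """Binned percent multiplied by staining intensity (0-3), range {0..9}."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity outside {{0..3}}: {intensity}")
    return percent_bin(percent) * intensity


def roc_cutoff(scores: Sequence[float], outcome: Sequence[int]) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J for 'score >= cutoff predicts event'.

    Candidate cutoffs are midpoints between consecutive distinct scores; ties
    in J are broken toward the smaller cutoff.  Returns (cutoff, sensitivity,
    specificity) at the optimum.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if len(s) != len(y) or len(s) == 0:
        raise ValueError("scores and outcome must be same-length and non-empty")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined: single-class outcome")
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("ROC undefined: all scores identical (J = 0)")
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for cut in midpoints:
        pred = s >= cut
        sens = np.mean(pred[y == 1])
        spec = np.mean(~pred[y == 0])
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, cut, sens, spec)
    assert best is not None
    return best[1], best[2], best[3]


def median_split(values: Sequence[float]) -> tuple[float, list[str]]:
    """Dichotomize at the sample median: value > median is high, else low.

    Values exactly at the median are low.  Requires n >= 4 and at least two
    distinct values.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("median split needs at least 4 values")
    if np.all(v == v[0]):
        raise ValueError("degenerate split: all values identical")
    cutoff = float(np.median(v))
    return cutoff, ["high" if x > cutoff else "low" for x in v]


# ---------------------------------------------------------------------------
# Grouping and survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalGrouping:
    """Per-patient group label with one endpoint's time and event flag."""

    table: pd.DataFrame  # columns: patient_id, group, time, event

    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def subset(self, group: str) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise ValueError(f"empty group: {group}")
        return sub


def marker_scores(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Composite YAP and NELFA scores for every patient."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "yap_score": [composite_score(r.yap_percent, r.yap_intensity) for r in records],
            "nelfa_score": [
                composite_score(r.nelfa_percent, r.nelfa_intensity) for r in records
            ],
        }
    ).set_index("patient_id")


def stratify(
    records: Sequence[ClinicalRecord],
    mode: str = "joint",
    cutoffs: dict[str, float] | None = None,
    marker: str = "YAP",
    endpoint: str = "OS",
) -> SurvivalGrouping:
    """Assign each patient to a marker-high/low group and attach an endpoint.

    ``single_marker`` mode labels high/low for ``marker``; ``joint`` mode
    gives the four YAP x NELFA groups.  "High" means composite score >=
    cutoff.  ``cutoffs`` maps marker name ("YAP"/"NELFA") to its cutoff.
    """
    if cutoffs is None or not cutoffs:
        raise ValueError("cutoffs are required (from roc_cutoff or median_split)")
    if endpoint not in ("OS", "DFS"):
        raise ValueError("endpoint must be OS or DFS")
    scores = marker_scores(records)
    rows = []
    for r in records:
        high = {}
        for m, col in (("YAP", "yap_score"), ("NELFA", "nelfa_score")):
            if m in cutoffs:
                high[m] = scores.loc[r.patient_id, col] >= cutoffs[m]
        if mode == "single_marker":
            if marker not in high:
                raise ValueError(f"missing marker cutoff: {marker}")
            group = "high" if high[marker] else "low"
        elif mode == "joint":
            if "YAP" not in high or "NELFA" not in high:
                raise ValueError("joint mode needs YAP and NELFA cutoffs")
            group = (
                f"{'High' if high['YAP'] else 'Low'}YAP_"
                f"{'High' if high['NELFA'] else 'Low'}NELFA"
            )
        else:
            raise ValueError(f"unknown mode: {mode}")
        time = r.os_months if endpoint == "OS" else r.dfs_months
        event = r.os_event if endpoint == "OS" else r.dfs_event
        rows.append(
            {"patient_id": r.patient_id, "group": group, "time": time, "event": event}
        )
    return SurvivalGrouping(pd.DataFrame(rows))


def km_curve(g: SurvivalGrouping, group: str) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate for one group.

    Returns a table of event/censoring times with at-risk counts, event
    counts and the survival estimate.
    """
    sub = g.subset(group)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": et.index,
            "at_risk": et["at_risk"].to_numpy(),
            "events": et["observed"].to_numpy(),
            "survival": surv.reindex(et.index).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def km_at(g: SurvivalGrouping, group: str, time: float) -> float:
    """Survival probability of a group at a given time."""
    sub = g.subset(group)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    return float(kmf.predict(time))


def logrank_test(g: SurvivalGrouping) -> tuple[float, int, float]:
    """Mantel-Cox log-rank test across all groups: (chi2, df, p)."""
    groups = g.groups()
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    if g.table["event"].sum() < 1:
        raise ValueError("no events")
    res = multivariate_logrank_test(g.table["time"], g.table["group"], g.table["event"])
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


# ---------------------------------------------------------------------------
# Contingency
# ---------------------------------------------------------------------------


@dataclass
class ContingencyResult:
    observed: np.ndarray
    statistic: float
    df: int
    p: float


def chi2_contingency(table: Sequence[Sequence[float]]) -> ContingencyResult:
    """Uncorrected Pearson chi-square test of independence on an r x c table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise ValueError("table must be a 2-D array of non-negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(observed=obs, statistic=float(stat), df=int(df), p=float(p))
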