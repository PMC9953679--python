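"""Median-split expression survival screening.

For each gene, samples are split at the median expression (ties at the
median go to the high group), Kaplan-Meier curves are estimated per group,
and the groups are compared with a log-rank test.  Genes with p below a
significance threshold are flagged, with the protective direction (which
expression group shows higher end-of-follow-up survival) recorded; genes
below a looser threshold are flagged as trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "KMCurve",
    "median_split",
    "kaplan_meier",
    "log_rank",
    "survival_screen",
]


def median_split(values, ties: str = "high") -> pd.Series:
    """Label samples 'high' (>= median) or 'low' (< median).

    Ties at the median are assigned to the high group by default
    (``ties='low'`` flips this).  Requires >= 4 samples and a non-constant
    vector so both groups are non-empty.
    """
    v = pd.Series(values, dtype=float)
    if len(v) < 4:
        raise ValueError("median split needs >= 4 samples")
    if v.nunique() == 1:
        raise ValueError("constant expression vector cannot be median-split")
    med = float(np.median(v))
    if ties == "high":
        labels = np.where(v >= med, "high", "low")
    elif ties == "low":
        labels = np.where(v > med, "high", "low")
    else:
        raise ValueError(f"unknown ties rule {ties!r}")
    labels = pd.Series(labels, index=v.index, name="group")
    if (labels == "high").all() or (labels == "low").all():
        # pathological tie structure: fall back to a strict split
        labels = pd.Series(np.where(v > med, "high", "low"), index=v.index, name="group")
        if (labels == "high").all() or (labels == "low").all():
            raise ValueError("cannot split values into two non-empty groups")
    return labels


@dataclass
class KMCurve:
    """Product-limit survival estimate at each distinct event time."""

    event_times: np.ndarray  # distinct times with >= 1 death
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time

    def at(self, t: float) -> float:
        """S(t): survival probability at time t."""
        past = self.event_times <= t
        return float(self.survival[past][-1]) if past.any() else 1.0

    @property
    def final(self) -> float:
        return float(self.survival[-1]) if self.survival.size else 1.0


def kaplan_meier(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator from (time_days, event) records.

    Censored-only times reduce the at-risk count without producing steps.
    """
    if records.empty:
        raise ValueError("no survival records")
    t = records["time_days"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival time")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    has_event = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[has_event]
    at_risk = table["at_risk"].to_numpy(dtype=float)[has_event]
    surv = np.array(
        [float(kmf.predict(tt)) for tt in event_times], dtype=float
    )
    return KMCurve(event_times=event_times, survival=surv, at_risk=at_risk)


def log_rank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Log-rank test between two sets of (time_days, event) records.

    Returns ``(chi_square, p_value)`` with 1 degree of freedom.  With no
    events anywhere the test is undefined; (0, 1) is returned with a
    warning.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be non-empty")
    if group_a["event"].sum() + group_b["event"].sum() == 0:
        warnings.warn("no events in either group; log-rank undefined", UserWarning,
                      stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(
        group_a["time_days"], group_b["time_days"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def survival_screen(
    matrix: pd.DataFrame,
    records: pd.DataFrame,
    alpha: float = 0.05,
    trend_alpha: float = 0.10,
    ties: str = "high",
) -> pd.DataFrame:
    """Median-split log-rank screen over every gene in the matrix.

    ``records`` must contain ``time_days`` and ``event`` indexed by sample,
    aligned with the matrix columns.  Returns a per-gene table with the
    log-rank ``p_value``, ``direction`` ('high_protective' or
    'low_protective': which expression group has the higher Kaplan-Meier
    survival at end of follow-up), and ``tier`` ('significant' for
    p < alpha, 'trend' for p < trend_alpha, else 'ns').
    """
    missing = matrix.columns.difference(records.index)
    if len(missing):
        raise ValueError(f"records missing for samples: {list(missing[:5])}")
    rec = records.loc[matrix.columns, ["time_days", "event"]]

    rows = []
    for gene in matrix.index:
        labels = median_split(matrix.loc[gene], ties=ties)
        high = rec.loc[labels[labels == "high"].index]
        low = rec.loc[labels[labels == "low"].index]
        stat, p = log_rank(high, low)
        s_high = kaplan_meier(high).final
        s_low = kaplan_meier(low).final
        direction = "high_protective" if s_high >= s_low else "low_protective"
        tier = "significant" if p < alpha else ("trend" if p < trend_alpha else "ns")
        rows.append(
            {"gene": gene, "chi2": stat, "p_value": p,
             "direction": direction, "tier": tier}
        )
    out = pd.DataFrame(rows, columns=["gene", "chi2", "p_value", "direction", "tier"])
    return out.set_index("gene")
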