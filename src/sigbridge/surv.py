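"""Progression-free survival: Kaplan-Meier curves and log-rank comparison.

The product-limit estimator and the k-group log-rank test are delegated to
lifelines; this module fixes the conventions the pipeline relies on — median
survival as the smallest time with S(t) <= 0.5 (undefined when the curve
never reaches 0.5), censoring at an event time processed after the events,
and a chi-square reference with k-1 degrees of freedom for the k-group test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from sigbridge.genesets import bh_adjust


def _validate(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("time_months", "event", "group"):
        if col not in data.columns:
            raise ValueError(f"survival data must have a {col!r} column")
    t = data["time_months"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("times must be finite and non-negative")
    if not data["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return data


@dataclass
class KmCurve:
    """One Kaplan-Meier curve: S(t) after each distinct event time."""

    group: str
    event_times: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    median: float  # nan when the curve never reaches 0.5
    n: int
    n_events: int

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)


def km_estimate(data: pd.DataFrame, group: str | None = None) -> KmCurve:
    """Product-limit estimate for one group (or the whole frame).

    With no censoring the curve equals 1 minus the empirical CDF of event
    times.  The median is the smallest time with S(t) <= 0.5 and is flagged
    undefined (NaN) when every subject is censored before the curve falls
    that far.
    """
    data = _validate(data)
    if group is not None:
        data = data[data["group"] == group]
        if data.empty:
            raise ValueError(f"group {group!r} has no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(data["time_months"], data["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    surv = np.array([float(sf.loc[t]) for t in times])
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    if not np.isfinite(med):
        med = float("nan")
    return KmCurve(
        group=group if group is not None else "all",
        event_times=times,
        survival=surv,
        at_risk=at_risk,
        median=med,
        n=int(len(data)),
        n_events=int(data["event"].sum()),
    )


def km_by_group(data: pd.DataFrame) -> dict[str, KmCurve]:
    """Kaplan-Meier curves for every group in the frame."""
    data = _validate(data)
    return {g: km_estimate(data, g) for g in sorted(data["group"].unique())}


def logrank_test(data: pd.DataFrame, groups: list[str] | None = None) -> dict:
    """k-group log-rank test over shared risk sets.

    Returns the chi-square statistic, degrees of freedom, and two-sided p.
    """
    data = _validate(data)
    if groups is not None:
        for g in groups:
            if (data["group"] == g).sum() == 0:
                raise ValueError(f"group {g!r} has no subjects")
        data = data[data["group"].isin(groups)]
    k = data["group"].nunique()
    if k < 2:
        raise ValueError("log-rank needs at least 2 groups")
    if data["event"].sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(data["time_months"], data["group"], data["event"])
    return {
        "statistic": float(res.test_statistic),
        "df": int(k - 1),
        "p": float(res.p_value),
        "n": int(len(data)),
    }


def pairwise_logrank(data: pd.DataFrame, adjust: bool = True) -> pd.DataFrame:
    """All pairwise two-group log-rank tests, optionally BH-adjusted."""
    data = _validate(data)
    levels = sorted(data["group"].unique())
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            res = logrank_test(data, groups=[a, b])
            rows.append((a, b, res["statistic"], res["p"]))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    if adjust and len(df):
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
    return df
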