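"""Kaplan-Meier estimation and log-rank comparison for patient outcomes.

Thin, typed surface over lifelines: the product-limit estimator with
Greenwood variance and log(-log S) 95% confidence bands, and the k-group
log-rank test.  Deaths and censorings tied at the same time follow the
standard convention (deaths processed first).  Time units are whatever the
records carry; the module is unit-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["SurvivalRecord", "KMCurve", "km_estimate", "logrank", "read_survival", "write_survival"]


@dataclass(frozen=True)
class SurvivalRecord:
    time: float
    event: bool  # True = death observed, False = censored
    group: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


@dataclass(frozen=True)
class KMCurve:
    """Stepwise product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood variance of S(t)
    ci_lower: np.ndarray  # 95% band on the log(-log S) scale
    ci_upper: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_time(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate with Greenwood variance.

    The Greenwood sum is accumulated from the risk table; confidence bands
    are lifelines' default log(-log S) ("exponential Greenwood") bands, which
    stay inside [0, 1].
    """
    if not records:
        raise ValueError("need at least one survival record")
    times = np.array([r.time for r in records], float)
    events = np.array([r.event for r in records], bool)
    if not events.any():
        warnings.warn("no events observed; survival curve is identically 1", stacklevel=2)

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table  # indexed by time, deaths processed before censorings
    event_rows = table[table["observed"] > 0]
    t = event_rows.index.to_numpy(float)
    d = event_rows["observed"].to_numpy(float)
    n_at_risk = event_rows["at_risk"].to_numpy(float)

    surv = np.cumprod(1.0 - d / n_at_risk)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
    greenwood = surv**2 * np.cumsum(increments)
    greenwood = np.where(surv == 0.0, 0.0, greenwood)

    ci = kmf.confidence_interval_survival_function_
    ci_at_events = ci.reindex(t, method="ffill")
    return KMCurve(
        times=t,
        survival=surv,
        variance=greenwood,
        ci_lower=ci_at_events.iloc[:, 0].to_numpy(float),
        ci_upper=ci_at_events.iloc[:, 1].to_numpy(float),
        at_risk=n_at_risk,
        n=len(records),
    )


def logrank(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, upper-tail p).

    Degrees of freedom are k-1.  Requires at least two non-empty groups.
    """
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "group": [r.group for r in records],
        }
    )
    result = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(result.test_statistic), float(result.p_value)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    return [
        SurvivalRecord(
            time=float(row["time"]),
            event=bool(int(row["event"])),
            group=str(row["group"]),
            subject_id=str(row.get("subject_id", "")),
        )
        for _, row in df.iterrows()
    ]


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> Path:
    path = Path(path)
    records = list(records)
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "group": [r.group for r in records],
        }
    ).to_csv(path, index=False)
    return path
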